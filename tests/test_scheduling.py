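import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wavedist import (
    SchedulePlan,
    cyclic_row_assignment,
    dv_length,
    fine_grain_cell_counts,
    imbalance_ratio,
    make_splits,
    run_plan,
)
from wavedist.pipeline import compute_distance_vector


class TestMakeSplits:
    @pytest.mark.parametrize(
        "t, m, sizes",
        [
            (6, 2, [3, 3]),   # 4 sequences over 2 nodes
            (7, 2, [4, 3]),
            (5, 3, [2, 2, 1]),
            (10, 1, [10]),
        ],
    )
    def test_sizes(self, t, m, sizes):
        assert [len(s) for s in make_splits(t, m)] == sizes

    def test_blocks_are_contiguous_in_h_order(self):
        splits = make_splits(10, 3)
        flat = [h for s in splits for h in s]
        assert flat == list(range(10))

    def test_more_nodes_than_pairs_warns_with_empty_splits(self):
        with pytest.warns(UserWarning, match="empty"):
            splits = make_splits(2, 4)
        assert [len(s) for s in splits] == [1, 1, 0, 0]

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 300), st.integers(1, 20))
    def test_partition_property(self, t, m):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            splits = make_splits(t, m)
        sizes = [len(s) for s in splits]
        assert sorted(h for s in splits for h in s) == list(range(t))
        assert max(sizes) - min(sizes) <= 1
        assert max(sizes) == -(-t // m)


class TestFineGrainCounts:
    @pytest.mark.parametrize(
        "d, p, counts",
        [
            (6, 4, [2, 2, 1, 1]),  # two cores do double work on a 6-cell diagonal
            (4, 4, [1, 1, 1, 1]),
            (9, 4, [3, 2, 2, 2]),
            (1, 4, [1, 0, 0, 0]),
        ],
    )
    def test_block_rule(self, d, p, counts):
        assert fine_grain_cell_counts(d, p) == counts

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(1, 60), st.integers(1, 60), st.integers(1, 8))
    def test_cumulative_cells_cover_the_grid(self, li, lj, p):
        total = 0
        for x in range(1, li + lj):
            d = min(x, li, lj, li + lj - x)
            total += sum(fine_grain_cell_counts(d, p))
        assert total == li * lj


class TestCyclicRows:
    def test_two_batches_of_four(self):
        assert cyclic_row_assignment(8, 4) == [1, 2, 3, 4, 1, 2, 3, 4]

    def test_single_core_takes_all_rows(self):
        assert cyclic_row_assignment(3, 1) == [1, 1, 1]

    def test_uneven_final_batch(self):
        loads = np.bincount(cyclic_row_assignment(5, 4))[1:]
        assert loads.tolist() == [2, 1, 1, 1]


class TestImbalanceRatio:
    @pytest.mark.parametrize(
        "counts, ratio",
        [([2, 2, 1, 1], 4 / 3), ([1, 1, 1, 1], 1.0), ([4, 0, 0, 0], 4.0)],
    )
    def test_values(self, counts, ratio):
        assert imbalance_ratio(counts) == pytest.approx(ratio)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            imbalance_ratio([0, 0])

    @settings(max_examples=80, derandomize=True)
    @given(st.integers(1, 200), st.integers(1, 8))
    def test_divisible_diagonals_balance_perfectly(self, q, p):
        counts = fine_grain_cell_counts(q * p, p)
        assert imbalance_ratio(counts) == 1.0

    @settings(max_examples=80, derandomize=True)
    @given(st.integers(1, 200), st.integers(1, 8))
    def test_ratio_bounded_by_ceiling_rule(self, d, p):
        counts = fine_grain_cell_counts(d, p)
        assert imbalance_ratio(counts) <= (-(-d // p)) / (d / p) + 1e-12


class TestSchedulePlan:
    def test_splits_must_partition(self):
        with pytest.raises(ValueError, match="partition"):
            SchedulePlan(m=2, p=1, t=4, splits=[[0, 1], [1, 2]])

    def test_n_split_is_ceiling(self):
        assert SchedulePlan.for_pairs(7, m=2).n_split == 4


class TestRunPlan:
    def test_all_schedules_give_identical_dv(self, dna_identity, small_set):
        t = dv_length(len(small_set))
        serial = compute_distance_vector(small_set, dna_identity)
        for m, p in itertools.product([1, 2, 3], repeat=2):
            dv = run_plan(small_set, dna_identity, SchedulePlan.for_pairs(t, m=m, p=p))
            assert np.array_equal(dv.values, serial.values), (m, p)

    def test_plan_size_mismatch_rejected(self, dna_identity, small_set):
        with pytest.raises(ValueError, match="plan"):
            run_plan(small_set, dna_identity, SchedulePlan.for_pairs(3, m=1))

    def test_logs_per_split_records(self, dna_identity, small_set, caplog):
        t = dv_length(len(small_set))
        with caplog.at_level("INFO", logger="wavedist.scheduling"):
            run_plan(small_set, dna_identity, SchedulePlan.for_pairs(t, m=2, p=2))
        split_lines = [r for r in caplog.records if "split=" in r.getMessage()]
        assert len(split_lines) == 2
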