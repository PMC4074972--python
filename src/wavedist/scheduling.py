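"""Two-level workload decomposition for the all-pairs distance computation.

Coarse grain: the condensed pair list of T = N(N-1)/2 alignments is cut
into M contiguous splits of near-equal size (ceil(T/M) or floor(T/M)) and
each split goes to one emulated node.  Fine grain: within one alignment
the cells of each antidiagonal are spread over P emulated cores, either by
the most-even block rule or cyclically by row.  "Nodes" and "cores" are
emulated with local worker pools; the arithmetic of the decomposition is
what matters here, and the contract is that no choice of M, P or worker
pool ever changes the computed distances.
"""

from __future__ import annotations

import dataclasses
import logging
import time
import warnings
from concurrent.futures import Executor, ThreadPoolExecutor
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SchedulePlan",
    "make_splits",
    "fine_grain_cell_counts",
    "cyclic_row_assignment",
    "imbalance_ratio",
    "run_plan",
]


def make_splits(t: int, m: int) -> list[list[int]]:
    """Partition pair indices 0..t-1 into m contiguous near-equal blocks.

    The first ``t mod m`` splits get ceil(t/m) pairs, the rest floor(t/m);
    sizes never differ by more than one.  With more nodes than pairs the
    surplus splits are empty (warned, not an error).
    """
    if t < 1:
        raise ValueError(f"pair count must be >= 1, got {t}")
    if m < 1:
        raise ValueError(f"node count must be >= 1, got {m}")
    if m > t:
        warnings.warn(f"more nodes ({m}) than pairs ({t}): some splits are empty", stacklevel=2)
    base, extra = divmod(t, m)
    splits: list[list[int]] = []
    start = 0
    for node in range(m):
        size = base + (1 if node < extra else 0)
        splits.append(list(range(start, start + size)))
        start += size
    return splits


def fine_grain_cell_counts(diag_size: int, p: int) -> list[int]:
    """Most-even block distribution of one antidiagonal over p cores.

    The first ``diag_size mod p`` cores get ceil(diag_size/p) cells, the
    rest floor(diag_size/p) — possibly zero (idle cores).
    """
    if diag_size < 1:
        raise ValueError(f"antidiagonal size must be >= 1, got {diag_size}")
    if p < 1:
        raise ValueError(f"core count must be >= 1, got {p}")
    base, extra = divmod(diag_size, p)
    return [base + (1 if core < extra else 0) for core in range(p)]


def cyclic_row_assignment(li: int, p: int) -> list[int]:
    """Map each DP row (1-based) to a core by row index modulo p.

    Returns a list of length `li` whose r-th entry (0-based r-1) is the
    1-based core handling row r; rows are processed in batches of p
    consecutive rows, with wavefront dependencies respected inside the
    engine.
    """
    if li < 1:
        raise ValueError(f"row count must be >= 1, got {li}")
    if p < 1:
        raise ValueError(f"core count must be >= 1, got {p}")
    return [((r - 1) % p) + 1 for r in range(1, li + 1)]


def imbalance_ratio(counts: Sequence[int]) -> float:
    """max(counts) / mean(counts); 1.0 means perfectly balanced."""
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0:
        raise ValueError("empty count list")
    if np.any(arr < 0):
        raise ValueError("cell counts must be non-negative")
    if not np.any(arr):
        raise ValueError("all-zero cell counts: no work to balance")
    return float(arr.max() / arr.mean())


@dataclasses.dataclass
class SchedulePlan:
    """Assignment of the condensed pair list to M nodes with P cores each.

    `splits[m]` is the list of condensed pair indices h handled by node m;
    together the splits partition {0, ..., T-1}.  `n_split` is the target
    split size ceil(T/M).
    """

    m: int
    p: int
    t: int
    splits: list[list[int]] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValueError(f"core count must be >= 1, got {self.p}")
        if not self.splits:
            self.splits = make_splits(self.t, self.m)
        covered = sorted(h for split in self.splits for h in split)
        if covered != list(range(self.t)):
            raise ValueError("splits must partition the pair indices exactly once")

    @property
    def n_split(self) -> int:
        return -(-self.t // self.m)  # ceil(T/M)

    @property
    def split_sizes(self) -> list[int]:
        return [len(s) for s in self.splits]

    @classmethod
    def for_pairs(cls, t: int, m: int = 1, p: int = 1) -> "SchedulePlan":
        return cls(m=m, p=p, t=t)


def run_plan(seqs, sbt, plan: SchedulePlan, workers: Executor | None = None):
    """Dispatch each split to a worker and assemble the distance vector.

    Results are gathered by split index, so the output is identical to a
    serial run regardless of M, P or the executor used.  A structured log
    line per split records its pair count, DP cell count and elapsed time.
    """
    from .pipeline import dv_length, compute_split_distances, DistanceVector

    n = len(seqs)
    t = dv_length(n)
    if plan.t != t:
        raise ValueError(f"plan is for {plan.t} pairs but {n} sequences give {t}")

    def _one_split(split_id: int):
        start = time.perf_counter()
        try:
            values, stats = compute_split_distances(seqs, sbt, plan.splits[split_id], plan.p)
        except Exception as exc:
            raise RuntimeError(f"worker for split {split_id} failed: {exc}") from exc
        elapsed = time.perf_counter() - start
        logger.info(
            "split=%d pairs=%d cells=%d elapsed=%.4fs core_cells=%s",
            split_id, len(plan.splits[split_id]), stats.total_cells, elapsed,
            stats.core_cell_counts,
        )
        return values

    if workers is None:
        with ThreadPoolExecutor(max_workers=plan.m) as pool:
            parts = list(pool.map(_one_split, range(plan.m)))
    else:
        parts = list(workers.map(_one_split, range(plan.m)))

    values = np.empty(t, dtype=float)
    for split, part in zip(plan.splits, parts):
        values[split] = part
    return DistanceVector(values, n)
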