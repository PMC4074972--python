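"""Condensed distance-vector assembly and storage accounting.

The N x N distance matrix is symmetric with a zero diagonal, so only its
upper triangle is ever stored: a flat distance vector DV of length
T = N(N-1)/2, indexed by h in the row-major upper-triangle convention
(the same ordering scipy's `squareform` uses).  This module owns the
h <-> (i, j) bookkeeping, builds DV with either engine under a schedule
plan, and reproduces the storage arithmetic that motivates the layout:
DV halves the N^2 matrix, and the six-vector engine replaces the two
(L+1)^2 per-pair matrices by 6L cells.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.spatial.distance import squareform

from .io_formats import SequenceSet, SubstitutionMatrix
from .oracle import oracle_distance
from .scheduling import SchedulePlan

__all__ = [
    "DistanceVector",
    "pair_to_index",
    "index_to_pair",
    "dv_length",
    "storage_megawords",
    "compute_distance_vector",
    "compute_split_distances",
]

#: Storage cost of each layout, in words (one word per stored cell).
#: ``size`` is N (sequence count) for the distance layouts and L
#: (sequence length) for the per-pair alignment layouts.
_STORAGE_WORDS = {
    "full_matrix_dm": lambda n: n * n,
    "distance_vector": lambda n: n * (n - 1) // 2,
    "pair_matrices": lambda l: 2 * (l + 1) ** 2,
    "pair_vectors": lambda l: 6 * l,
}


def dv_length(n: int) -> int:
    """Number of pairwise distances for n sequences: n(n-1)/2."""
    if n < 2:
        raise ValueError(f"need at least 2 sequences, got {n}")
    return n * (n - 1) // 2


def pair_to_index(i: int, j: int, n: int) -> int:
    """Condensed index h of pair (i, j), 0 <= i < j < n, row-major."""
    if not 0 <= i < j < n:
        raise ValueError(f"need 0 <= i < j < n, got i={i}, j={j}, n={n}")
    return i * n - i * (i + 1) // 2 + (j - i - 1)


def index_to_pair(h: int, n: int) -> tuple[int, int]:
    """Inverse of :func:`pair_to_index`."""
    t = dv_length(n)
    if not 0 <= h < t:
        raise ValueError(f"condensed index {h} outside 0..{t - 1} for n={n}")
    # row i is the largest i with i*n - i(i+1)/2 <= h
    i = int((2 * n - 1 - math.sqrt((2 * n - 1) ** 2 - 8 * h)) / 2)
    while pair_to_index(i, i + 1, n) > h:  # guard float round-off
        i -= 1
    while i + 1 < n - 1 and pair_to_index(i + 1, i + 2, n) <= h:
        i += 1
    j = h - (i * n - i * (i + 1) // 2) + i + 1
    return i, j


def storage_megawords(method: str, size: int) -> float:
    """Storage of one layout in mega-words (10^6 words, one word per cell).

    Methods: ``full_matrix_dm`` (N^2), ``distance_vector`` (N(N-1)/2),
    ``pair_matrices`` (2(L+1)^2, the two full alignment tables),
    ``pair_vectors`` (6L, the six wavefront buffers).
    """
    try:
        words = _STORAGE_WORDS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; expected one of {sorted(_STORAGE_WORDS)}"
        ) from None
    if size < 1:
        raise ValueError(f"size must be >= 1, got {size}")
    return words(size) / 1e6


@dataclasses.dataclass(frozen=True)
class DistanceVector:
    """Length-N(N-1)/2 condensed distances in row-major upper-triangle order."""

    values: np.ndarray
    n: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size != dv_length(self.n):
            raise ValueError(
                f"distance vector for n={self.n} must have length {dv_length(self.n)}, "
                f"got {values.size}"
            )
        if values.size and (values.min() < 0.0 or values.max() > 1.0):
            raise ValueError("distances must lie in [0, 1]")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    def __getitem__(self, h: int) -> float:
        return float(self.values[h])

    def get(self, i: int, j: int) -> float:
        """Distance between sequences i and j (order-free; 0 on the diagonal)."""
        if i == j:
            return 0.0
        i, j = min(i, j), max(i, j)
        return float(self.values[pair_to_index(i, j, self.n)])

    def to_square(self) -> np.ndarray:
        """Expand to the full symmetric N x N matrix with zero diagonal."""
        return squareform(self.values)


def compute_split_distances(
    seqs: SequenceSet,
    sbt: SubstitutionMatrix,
    pair_indices: list[int],
    cores: int = 1,
    engine: str = "vectorized",
):
    """Distances for one split of condensed pair indices.

    Returns ``(values, stats)`` where `stats` aggregates the engine's
    instrumentation (DP cell totals and the emulated per-core ledger)
    over the split.
    """
    from .engine import EngineStats, vectorized_distance

    n = len(seqs)
    stats = EngineStats(cores=cores)
    values = np.empty(len(pair_indices), dtype=float)
    for out_pos, h in enumerate(pair_indices):
        i, j = index_to_pair(h, n)
        id_i, s_i = seqs[i]
        id_j, s_j = seqs[j]
        if not s_i or not s_j:
            raise ValueError(f"pair ({id_i}, {id_j}) has an empty sequence")
        if engine == "vectorized":
            res = vectorized_distance(s_i, s_j, sbt, stats=stats)
        elif engine == "oracle":
            res = oracle_distance(s_i, s_j, sbt)
            stats.total_cells += len(s_i) * len(s_j)
        else:
            raise ValueError(f"unknown engine {engine!r}; expected 'oracle' or 'vectorized'")
        values[out_pos] = res.distance
    return values, stats


def compute_distance_vector(
    seqs: SequenceSet,
    sbt: SubstitutionMatrix,
    plan: SchedulePlan | None = None,
    engine: str = "vectorized",
) -> DistanceVector:
    """Assemble the full condensed distance vector over all pairs.

    The result is deterministic: identical for any schedule plan (M, P)
    and for either engine, because both engines agree exactly and results
    are gathered by condensed index.
    """
    n = len(seqs)
    t = dv_length(n)
    if plan is None:
        plan = SchedulePlan.for_pairs(t)
    if plan.t != t:
        raise ValueError(f"plan is for {plan.t} pairs but {n} sequences give {t}")
    values = np.empty(t, dtype=float)
    for split in plan.splits:
        part, _ = compute_split_distances(seqs, sbt, split, plan.p, engine=engine)
        values[split] = part
    return DistanceVector(values, n)
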