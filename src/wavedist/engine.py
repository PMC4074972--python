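"""Antidiagonal wavefront engine: the distance from six rolling vectors.

Every cell (r, c) of the alignment tables depends only on three neighbours
— (r-1, c-1) two antidiagonals back, and (r, c-1), (r-1, c) one back — so
the full (L_i+1)x(L_j+1) score and match-count matrices never need to be
held.  The engine sweeps antidiagonals x = r + c - 1 from 1 to
L_i + L_j - 1, keeping a current score vector V with buffers V1 (diagonal
x-2) and V2 (diagonal x-1), and three companion match-count vectors Nv,
N1, N2.  Live storage is at most 6 * max(L_i, L_j) cells versus
2 (L_i+1)(L_j+1) for the full-matrix method.

The running optimum is updated in sweep order (x ascending, then row
ascending), which is exactly the tie-break order of the full-matrix
oracle, so results agree exactly — score, match count and distance.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import SubstitutionMatrix
from .oracle import DistanceResult
from .scheduling import fine_grain_cell_counts

__all__ = [
    "EngineStats",
    "antidiagonal_cells",
    "vectorized_distance",
    "buffer_footprint",
]


@dataclasses.dataclass
class EngineStats:
    """Instrumentation collected during a wavefront sweep.

    `peak_live_cells` counts the maximum number of buffer cells alive at
    once across all six vectors.  `core_cell_counts[p]` accumulates how
    many cells the most-even per-antidiagonal block distribution would
    hand to emulated core p.
    """

    cores: int = 1
    peak_live_cells: int = 0
    core_cell_counts: list[int] = dataclasses.field(default_factory=list)
    total_cells: int = 0

    def __post_init__(self) -> None:
        if not self.core_cell_counts:
            self.core_cell_counts = [0] * self.cores


def antidiagonal_cells(x: int, li: int, lj: int) -> list[tuple[int, int]]:
    """The 1-based cells (r, c) with r + c - 1 = x, in row-ascending order.

    The count equals min(x, li, lj, li + lj - x).
    """
    if not 1 <= x <= li + lj - 1:
        raise ValueError(f"antidiagonal index {x} outside 1..{li + lj - 1}")
    r_lo = max(1, x - lj + 1)
    r_hi = min(li, x)
    return [(r, x - r + 1) for r in range(r_lo, r_hi + 1)]


def buffer_footprint(li: int, lj: int) -> int:
    """Worst-case live cells across the six wavefront buffers: 6*max(li, lj)."""
    if li < 1 or lj < 1:
        raise ValueError("sequence lengths must be positive")
    return 6 * max(li, lj)


def _gather(vals: np.ndarray, r_lo_prev: int, rows: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Neighbour values for the given rows of a previous antidiagonal.

    Invalid positions (neighbour on the zero boundary) yield 0.
    """
    if vals.size == 0:
        return np.zeros(rows.shape, dtype=np.int64)
    idx = np.clip(rows - r_lo_prev, 0, vals.size - 1)
    return np.where(valid, vals[idx], 0)


def vectorized_distance(
    s1: str,
    s2: str,
    sbt: SubstitutionMatrix,
    stats: EngineStats | None = None,
) -> DistanceResult:
    """Compute the match-counting local-alignment distance with six buffers.

    Returns the same score, match count and distance as the full-matrix
    oracle for every input.  Pass an :class:`EngineStats` (whose `cores`
    field sets the emulated fine-grain core count) to collect the live-cell
    peak and the per-core load ledger; instrumentation never changes the
    result.
    """
    if not s1 or not s2:
        raise ValueError("empty sequence: min(L_i, L_j) = 0 makes the distance undefined")
    c1 = sbt.encode(s1)
    c2 = sbt.encode(s2)
    li, lj = len(s1), len(s2)
    g = sbt.gap
    table = sbt.scores

    # (values, first row) of antidiagonals x-1 and x-2
    v2 = np.zeros(0, dtype=np.int64)  # scores, diagonal x-1
    v1 = np.zeros(0, dtype=np.int64)  # scores, diagonal x-2
    n2 = np.zeros(0, dtype=np.int64)  # match counts, diagonal x-1
    n1 = np.zeros(0, dtype=np.int64)  # match counts, diagonal x-2
    r_lo_prev = 1
    r_lo_prev2 = 1

    best_score = 0
    best_count = 0

    for x in range(1, li + lj):
        r_lo = max(1, x - lj + 1)
        r_hi = min(li, x)
        rows = np.arange(r_lo, r_hi + 1)
        cols = x - rows + 1

        sub = table[c1[rows - 1], c2[cols - 1]]
        match = (c1[rows - 1] == c2[cols - 1]).astype(np.int64)

        diag_ok = (rows >= 2) & (cols >= 2)
        left_ok = cols >= 2
        up_ok = rows >= 2

        h_diag = _gather(v1, r_lo_prev2, rows - 1, diag_ok) + sub
        h_left = _gather(v2, r_lo_prev, rows, left_ok) + g
        h_up = _gather(v2, r_lo_prev, rows - 1, up_ok) + g

        v = np.maximum(0, np.maximum(h_diag, np.maximum(h_left, h_up)))

        n_diag = _gather(n1, r_lo_prev2, rows - 1, diag_ok) + match
        n_left = _gather(n2, r_lo_prev, rows, left_ok)
        n_up = _gather(n2, r_lo_prev, rows - 1, up_ok)
        # fixed case precedence: zero, diagonal, left, up
        nv = np.select(
            [v == 0, v == h_diag, v == h_left, v == h_up],
            [np.zeros_like(v), n_diag, n_left, n_up],
        )

        # running optimum in sweep order: strictly-greater across diagonals,
        # first occurrence (smallest row) within one
        vmax = int(v.max())
        if vmax > best_score:
            i = int(np.argmax(v))
            best_score = vmax
            best_count = int(nv[i])

        if stats is not None:
            live = 2 * (v.size + v2.size + v1.size)
            stats.peak_live_cells = max(stats.peak_live_cells, live)
            stats.total_cells += v.size
            for p, cnt in enumerate(fine_grain_cell_counts(v.size, stats.cores)):
                stats.core_cell_counts[p] += cnt

        v1, n1, r_lo_prev2 = v2, n2, r_lo_prev
        v2, n2, r_lo_prev = v, nv, r_lo

    distance = 1.0 - best_count / min(li, lj)
    return DistanceResult(best_score, best_count, distance)
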