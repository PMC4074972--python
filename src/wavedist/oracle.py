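"""Full-matrix reference recurrence for the match-counting local alignment.

This is the quadratic-memory definition of the distance: a Smith-Waterman
score matrix H with linear gap scores, together with a companion matrix Nc
that carries the number of exactly matching residue pairs along the optimal
path ending at each cell — so the match count at the score optimum is known
without any traceback.  The normalized distance between sequences of lengths
L_i and L_j is

    d = 1 - k_max / min(L_i, L_j)

where k_max is the match count at the optimal cell.  This module is the
correctness oracle for the antidiagonal engine, which must reproduce it
bit for bit.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import SubstitutionMatrix

__all__ = ["AlignmentMatrices", "DistanceResult", "sw_match_count_full", "oracle_distance"]


@dataclasses.dataclass(frozen=True)
class AlignmentMatrices:
    """The (L_i+1) x (L_j+1) score and match-count tables.

    Row/column 0 is the zero boundary; cell indices in `argmax` are
    1-based matrix coordinates.  `argmax` is the optimal cell selected in
    antidiagonal sweep order (smaller r+c first, then smaller row), the
    same order in which the wavefront engine visits cells.
    """

    H: np.ndarray
    Nc: np.ndarray
    argmax: tuple[int, int]

    @property
    def score(self) -> int:
        return int(self.H[self.argmax])

    @property
    def kmax(self) -> int:
        return int(self.Nc[self.argmax])


@dataclasses.dataclass(frozen=True)
class DistanceResult:
    """Best local score, exact-match count at the optimum, and distance."""

    score: int
    kmax: int
    distance: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.distance <= 1.0:
            raise ValueError(f"distance {self.distance} outside [0, 1]")


def sw_match_count_full(s1: str, s2: str, sbt: SubstitutionMatrix) -> AlignmentMatrices:
    """Fill the H and Nc tables by the full-matrix recurrence.

    H follows the local-alignment recurrence with linear gap score g:

        H(x,y) = max(0,
                     H(x-1,y-1) + sbt(S_i(x), S_j(y)),
                     H(x-1,y) + g,
                     H(x,y-1) + g)

    Nc follows H's case analysis with fixed precedence — zero, then
    diagonal (add 1 when the residues are equal), then left (gap in S_i),
    then up (gap in S_j); the first satisfied case wins.  Ties between
    cells attaining the maximal H are broken by first occurrence in
    antidiagonal sweep order.
    """
    if not s1 or not s2:
        raise ValueError("empty sequence: min(L_i, L_j) = 0 makes the distance undefined")
    c1 = sbt.encode(s1)
    c2 = sbt.encode(s2)
    li, lj = len(s1), len(s2)
    g = sbt.gap
    table = sbt.scores
    H = np.zeros((li + 1, lj + 1), dtype=np.int64)
    Nc = np.zeros((li + 1, lj + 1), dtype=np.int64)
    for x in range(1, li + 1):
        for y in range(1, lj + 1):
            sub = int(table[c1[x - 1], c2[y - 1]])
            diag = int(H[x - 1, y - 1]) + sub
            left = int(H[x, y - 1]) + g
            up = int(H[x - 1, y]) + g
            h = max(0, diag, left, up)
            H[x, y] = h
            if h == 0:
                continue  # Nc stays 0
            if h == diag:
                Nc[x, y] = Nc[x - 1, y - 1] + (1 if s1[x - 1] == s2[y - 1] else 0)
            elif h == left:
                Nc[x, y] = Nc[x, y - 1]
            else:  # h == up
                Nc[x, y] = Nc[x - 1, y]
    return AlignmentMatrices(H, Nc, _sweep_argmax(H, li, lj))


def _sweep_argmax(H: np.ndarray, li: int, lj: int) -> tuple[int, int]:
    """First maximal cell in antidiagonal order (r+c ascending, then r)."""
    best = (1, 1)
    best_score = -1
    for x in range(1, li + lj):  # antidiagonal index, r + c - 1 = x
        r_lo = max(1, x - lj + 1)
        r_hi = min(li, x)
        for r in range(r_lo, r_hi + 1):
            c = x - r + 1
            if H[r, c] > best_score:
                best_score = int(H[r, c])
                best = (r, c)
    return best


def oracle_distance(s1: str, s2: str, sbt: SubstitutionMatrix) -> DistanceResult:
    """Distance ``1 - kmax / min(L_i, L_j)`` from the full-matrix tables."""
    mats = sw_match_count_full(s1, s2, sbt)
    kmax = mats.kmax
    return DistanceResult(mats.score, kmax, 1.0 - kmax / min(len(s1), len(s2)))
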