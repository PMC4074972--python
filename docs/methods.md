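# Methods

## The distance model

`wavedist` computes a dissimilarity between two sequences from the
optimal *local* alignment under a linear gap model, without ever
reconstructing the alignment itself. Two recurrences run in lockstep
over the (L_i+1) × (L_j+1) grid (zero boundary row and column, 1-based
interior):

- the Smith–Waterman score `H(x,y) = max{0, diag + sbt, up + g, left + g}`
  with substitution scores `sbt(a,b)` and a non-positive additive gap
  score `g` per inserted/deleted residue (no separate gap-open cost);
- a match counter `N(x,y)` that copies the counter of whichever
  neighbour realised `H(x,y)`, adding 1 on a diagonal step whose
  residues are exactly equal.

With `k_max` the counter value at the score optimum, the distance is
`1 − k_max / min(L_i, L_j)`. It lies in [0, 1]: 0 for identical
sequences (every aligned pair matches), 1 when no local alignment scores
above zero. Normalising by the shorter length means a short sequence
fully contained in a longer one is at distance 0 — the statistic
measures divergence of the best-conserved region, not global identity.

### Tie-breaking, exactly specified

Two ambiguities in the recurrences are fixed so that the two
implementations agree bit-for-bit:

- **Case precedence in N.** When several neighbours realise the same
  `H(x,y)`, the counter follows the first satisfied case in the fixed
  order *zero, diagonal, left (gap in S_i), up (gap in S_j)*.
- **Optimum ties.** When several cells attain the maximal `H`, the
  winner is the first in antidiagonal sweep order: smaller x = r + c − 1
  first, then smaller row. The full-matrix oracle uses the same order,
  so the reported `k_max` is identical whichever implementation runs.
  (Row-major scanning would be an equally valid convention, but it can
  disagree with sweep order when tied optima sit on different
  diagonals; one order had to be chosen for both.)

Scores and counters are exact integer arithmetic throughout; the only
floating-point step is the final division.

## The six-vector engine

Cell (r, c) depends on (r−1, c−1) — two antidiagonals back — and on
(r, c−1), (r−1, c) — one back. The engine therefore sweeps x from 1 to
L_i + L_j − 1 keeping six vectors: the current score diagonal V with
buffers V2 (x−1) and V1 (x−2), and the matching counter diagonals Nv,
N2, N1. Each diagonal holds the cells r ∈ [max(1, x−L_j+1), min(L_i, x)]
in row-ascending order; index alignment between consecutive diagonals is
derived from each diagonal's first row (the shift is 0 or 1 depending on
the growing/plateau/shrinking phase), never hard-coded, so unequal
lengths are handled uniformly. Neighbours that fall on the zero boundary
contribute 0. Whole diagonals are evaluated as numpy vector operations;
the case analysis for the counter is a masked `select` in the fixed
precedence order.

Live storage is at most six vectors of min(L_i, L_j) cells — bounded by
`buffer_footprint(L_i, L_j) = 6·max(L_i, L_j)`, the 6L figure for square
problems — versus 2(L_i+1)(L_j+1) for the two full matrices. An
instrumented counter (`EngineStats.peak_live_cells`) measures the actual
peak during every sweep, and the tests assert it never exceeds the
bound. The running optimum is updated once per diagonal (strict
improvement across diagonals, first index within one), which is exactly
the sweep-order tie-break above.

The full-matrix oracle (`wavedist.oracle`) is deliberately written as a
plain nested loop over cells — the most direct transcription of the
recurrence — and serves as the engine's correctness reference; the
equivalence suite compares score, `k_max`, and distance exactly on
thousands of seeded random pairs under both scoring schemes.

## Condensed storage and its arithmetic

The distance matrix is symmetric with zero diagonal, so only the upper
triangle is stored: a flat vector of T = N(N−1)/2 values in row-major
upper-triangle order, `h = i·N − i(i+1)/2 + (j − i − 1)` for
0 ≤ i < j < N — the same convention as scipy's condensed form, which is
what `DistanceVector.to_square` uses for expansion. Storage accounting
(`storage_megawords`) prices each layout at one machine word per cell in
units of 10⁶ words: N² for the square matrix versus N(N−1)/2 condensed;
2(L+1)² for the per-pair matrices versus 6L for the wavefront buffers.
At N = 100,000 the condensed layout is what makes the problem storable
at all: ~5·10⁹ distances instead of 10¹⁰ matrix cells (40 GB at 4-byte
words).

## Scheduling

The workload decomposes at two levels, emulated with local worker pools
(thread pools stand in for cluster nodes; the arithmetic of the
decomposition is the object of interest, not message passing):

- **Coarse grain.** The T condensed pair indices are cut into M
  contiguous blocks; the first T mod M blocks get ⌈T/M⌉ pairs, the rest
  ⌊T/M⌋, so sizes never differ by more than one. Remainder pairs go to
  the lowest-index splits. Six pairs over two nodes → two splits of
  three.
- **Fine grain.** Within one alignment, the cells of each antidiagonal
  spread over P cores by the most-even block rule (⌈d/P⌉ or ⌊d/P⌋ each,
  zero allowed — idle cores on short diagonals). A six-cell diagonal
  over four cores loads them [2, 2, 1, 1], an imbalance ratio
  (max/mean) of 4/3; the alternative cyclic row assignment maps row r to
  core (r−1) mod P + 1 in batches of P consecutive rows.

Correctness is defined purely by the determinism contract: results are
gathered by condensed index, so any (M, P) and any executor produce a
distance vector identical to the serial run. Per-split log lines record
pair counts, DP cell counts, and elapsed time for load-balance
inspection.

## Inputs and defaults

FASTA reading uses Biopython; record ids are the first
whitespace-delimited token, residues are upper-cased, and symbols
outside the declared alphabet (default: the 20 standard amino acids,
which covers unambiguous DNA; `*` and `-` never accepted) are a hard
error naming the record — scoring unknown symbols silently would
corrupt distances. Scoring matrices come from Biopython's published
tables (`blosum62`) or any whitespace-delimited scoring-matrix file;
tables must be symmetric, and the gap score is stored non-positive (the
CLI takes a positive penalty and negates it). The CLI defaults —
BLOSUM62 with gap penalty 10 for protein input, +1/−1 identity with gap
penalty 2 for nucleotide — are ordinary practice for these alphabets,
chosen once as conventions and flagged as such in `--help`; the
distance definition itself is agnostic to the scheme.

## Synthetic data

Two seeded generators cover testing without external data.
`random_sequences` draws i.i.d. uniform residues with fixed or uniformly
sampled lengths. `mutated_family` draws one uniform ancestor and n−1
descendants carrying independent per-site substitutions at a given rate
(a mutated site is redrawn from the other symbols, so it always
changes). No indels are generated: the recurrences handle gaps, but
substitution-only families keep the expected divergence–distance
relationship clean, and the tests assert it only as a seed-averaged
trend (mean distance at rate 0.30 exceeds that at 0.05), not per seed.
Real sequence families additionally have indels, composition bias, and
rate heterogeneity, so passing tests demonstrate correctness of the
computation, not realism of the simulated evolution.

## Problem sizes and numerical choices

The equivalence suites run on random pairs of length 1–80 (1,000 pairs
in the acceptance checks, plus property-based sweeps), chosen so the
quadratic reference oracle stays fast while still covering all buffer
phases — growing, plateau, shrinking — and both scoring schemes; the
engine itself has no length assumptions and is exercised identically at
any scale. Distance values are stored at full double precision; the
PHYLIP writer rounds to six decimals (ids padded/truncated to ten
characters), and the TSV writer emits one `h, id_i, id_j, distance` row
per pair in condensed order.

## Known limitations

- Linear gap scores only; no affine gap-open/extend model.
- No alignment traceback — the method's point is to avoid it — so no
  alignment output formats.
- Node/core parallelism is emulated in one process; wall-clock speedup
  is out of scope, determinism and the decomposition arithmetic are the
  tested contracts.
- No guide-tree construction downstream of the distance vector.
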