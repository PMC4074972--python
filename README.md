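# wavedist

Memory-lean pairwise distance matrices for sets of protein or nucleotide
sequences.

Building a guide tree for multiple sequence alignment — or any
distance-based clustering of sequences — starts from an N × N distance
matrix, which needs N(N−1)/2 pairwise local alignments. At scale both
sides of that computation blow up: 100,000 sequences mean roughly
5 billion distances (a full square matrix of 4-byte entries is 40 GB),
and each pairwise alignment of length-L sequences classically fills two
(L+1) × (L+1) dynamic-programming tables. `wavedist` attacks both:

- **Condensed storage.** Only the upper triangle of the distance matrix
  is ever materialised, as a flat distance vector `DV` of length
  N(N−1)/2 indexed by `h` — the same layout as `scipy`'s condensed
  distance form.
- **Six-vector alignment engine.** Each pairwise distance is computed by
  sweeping antidiagonals of the Smith–Waterman grid while holding only
  six rolling vectors (current/previous/previous-previous score and
  match-count diagonals), so per-pair memory drops from 2(L+1)² to at
  most 6L cells.

## The statistic

For sequences S_i, S_j of lengths L_i, L_j, with substitution scores
sbt(a, b) and a linear (non-positive) gap score g, the local-alignment
score matrix is

    H(x,y) = max{ 0,
                  H(x−1,y−1) + sbt(S_i(x), S_j(y)),
                  H(x−1,y) + g,
                  H(x,y−1) + g }

with zero boundaries. A companion matrix N carries the number of exactly
matching residue pairs on the optimal path into each cell (no traceback
needed): it copies N from whichever neighbour realised the maximum —
checked in the fixed order zero, diagonal, left, up — adding 1 on a
diagonal step whose residues are equal. With k_max = N at the H-optimum,
the distance is

    d(S_i, S_j) = 1 − k_max / min(L_i, L_j)  ∈  [0, 1].

Identical sequences get d = 0; sequences with no positive-scoring local
alignment get d = 1.

The package contains both a full-matrix reference implementation of this
recurrence (the *oracle*) and the six-vector wavefront *engine*; they
agree exactly — score, match count, and distance — on every input, which
the test suite checks on thousands of random pairs. A two-level schedule
(M emulated nodes × P emulated cores) splits the pair list into M
contiguous near-equal blocks of size ⌈N(N−1)/2M⌉ and accounts
antidiagonal cells over P cores; no choice of M or P ever changes the
result.

## Worked example

```
$ wavedist generate --n 4 --length 20 --seed 1 --out demo.fa
wrote 4 records of length 20 to demo.fa (seed 1)

$ wavedist compute --fasta demo.fa --nodes 2 --cores 2 --out demo.phy
sequences      N = 4 (mean length 20.0)
pairs          T = 6
engine         vectorized (matrix identity, gap -2)
schedule       M = 2 nodes x P = 2 cores, n_split = 3
elapsed        0.026 s
peak buffer    <= 120 cells (6*max(Li,Lj) bound)
core imbalance 1.0500 (first pair, P = 2)
wrote          demo.phy (phylip)

$ cat demo.phy
4
seq_0001  0.000000  0.800000  0.850000  0.800000
seq_0002  0.800000  0.000000  0.800000  0.800000
seq_0003  0.850000  0.800000  0.000000  0.850000
seq_0004  0.800000  0.800000  0.850000  0.000000
```

Four random 20-mers are nearly unrelated, so distances sit near 1: the
pair (seq_0001, seq_0002) has its best local alignment with k_max = 4
exact matches, giving d = 1 − 4/20 = 0.80. The summary lines report the
schedule (6 pairs cut into two splits of 3), the engine's memory
guarantee (six vectors of at most max(L_i, L_j) cells each, 120 here
versus 2·21² = 882 for the full-matrix method), and the fine-grain load
ratio over the emulated cores. `--format tsv` writes one
`h  id_i  id_j  distance` row per pair instead; `--engine oracle`
switches to the full-matrix reference and produces byte-identical
output. `wavedist storage-report --n 6000 -L 858` prints the mega-word
storage of the square-matrix versus condensed/vector layouts at any
problem size.

The same operations are available as a library:

```python
from wavedist import GeneratorSpec, random_sequences, identity_matrix, compute_distance_vector

seqs = random_sequences(GeneratorSpec(n=4, length=20, seed=1))
dv = compute_distance_vector(seqs, identity_matrix("ACGT", gap=-2))
dv.values        # array([0.8 , 0.85, 0.8 , 0.8 , 0.8 , 0.85])
dv.to_square()   # full symmetric 4x4 matrix
```

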