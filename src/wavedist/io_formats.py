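"""Reading sequences and scoring matrices; writing distance outputs.

Input formats are multi-FASTA (via Biopython) and the standard
whitespace-delimited scoring-matrix text format (NCBI style, as used for
BLOSUM/PAM tables).  Distance outputs are written either as a square
symmetric PHYLIP distance matrix or as a per-pair TSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "PROTEIN_ALPHABET",
    "NUCLEOTIDE_ALPHABET",
    "SequenceSet",
    "SubstitutionMatrix",
    "read_fasta",
    "read_substitution_matrix",
    "identity_matrix",
    "write_fasta",
    "write_phylip_distances",
    "write_distance_vector_tsv",
]

#: The 20 standard amino-acid one-letter codes.  A superset of the
#: unambiguous nucleotide codes {A, C, G, T}, so it is a safe default
#: alphabet for both kinds of input.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Unambiguous DNA codes.
NUCLEOTIDE_ALPHABET = frozenset("ACGT")


@dataclasses.dataclass(frozen=True)
class SequenceSet:
    """An ordered collection of named residue strings S_1 ... S_N.

    Parameters
    ----------
    records
        Tuples ``(id, residues)`` in input order.  Ids are unique and
        non-empty; residues are upper-case and drawn from `alphabet`.
    alphabet
        The set of residue symbols the records may use.
    """

    records: tuple[tuple[str, str], ...]
    alphabet: frozenset[str] = PROTEIN_ALPHABET

    def __post_init__(self) -> None:
        ids = [rid for rid, _ in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sequence id(s): {', '.join(dupes)}")
        for rid, residues in self.records:
            if not rid:
                raise ValueError("empty sequence id")
            if not residues:
                raise ValueError(f"record {rid!r} has an empty sequence")
            bad = set(residues) - self.alphabet
            if bad:
                raise ValueError(
                    f"record {rid!r} contains symbol(s) outside the alphabet: "
                    f"{', '.join(sorted(bad))}"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> tuple[str, str]:
        return self.records[i]

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.records]

    @property
    def lengths(self) -> list[int]:
        return [len(seq) for _, seq in self.records]

    @property
    def mean_length(self) -> float:
        """Average sequence length L (reporting only)."""
        return float(np.mean(self.lengths))

    def is_nucleotide(self) -> bool:
        """True when every residue is an unambiguous DNA code."""
        return all(set(seq) <= NUCLEOTIDE_ALPHABET for seq in self.sequences)

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], alphabet: Iterable[str] | None = None
    ) -> "SequenceSet":
        records = tuple((rid, seq.upper()) for rid, seq in pairs)
        if alphabet is None:
            alpha = PROTEIN_ALPHABET | {s for _, seq in records for s in seq}
        else:
            alpha = frozenset(str(a).upper() for a in alphabet)
        return cls(records, frozenset(alpha))


@dataclasses.dataclass(frozen=True)
class SubstitutionMatrix:
    """A symmetric residue scoring table sbt(a, b) plus a linear gap score g.

    The gap score is additive and non-positive: extending an alignment by
    one inserted or deleted residue adds ``gap`` to the running score.
    """

    alphabet: tuple[str, ...]
    scores: np.ndarray  # square int table, scores[i, j] == scores[j, i]
    gap: int = -10
    name: str = "custom"

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=np.int64)
        if scores.ndim != 2 or scores.shape[0] != scores.shape[1]:
            raise ValueError("score table must be square")
        if scores.shape[0] != len(self.alphabet):
            raise ValueError("score table size does not match alphabet")
        if not np.array_equal(scores, scores.T):
            i, j = np.argwhere(scores != scores.T)[0]
            a, b = self.alphabet[i], self.alphabet[j]
            raise ValueError(
                f"asymmetric score table: sbt({a},{b})={scores[i, j]} but "
                f"sbt({b},{a})={scores[j, i]}"
            )
        if self.gap > 0:
            raise ValueError(
                f"gap score must be <= 0 (it is an additive score, got {self.gap}); "
                "negate a positive penalty before constructing the matrix"
            )
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "_index", {a: i for i, a in enumerate(self.alphabet)})

    def score(self, a: str, b: str) -> int:
        """sbt(a, b) for single residues."""
        idx = self._index
        try:
            return int(self.scores[idx[a], idx[b]])
        except KeyError as exc:
            raise KeyError(f"symbol {exc.args[0]!r} not scored by matrix {self.name!r}") from exc

    def encode(self, residues: str) -> np.ndarray:
        """Map a residue string to integer codes into the score table."""
        idx = self._index
        try:
            return np.fromiter((idx[c] for c in residues), dtype=np.intp, count=len(residues))
        except KeyError as exc:
            raise KeyError(f"symbol {exc.args[0]!r} not scored by matrix {self.name!r}") from exc

    def with_gap(self, gap: int) -> "SubstitutionMatrix":
        return dataclasses.replace(self, gap=gap)


def identity_matrix(
    alphabet: Iterable[str], match: int = 1, mismatch: int = -1, gap: int = -2
) -> SubstitutionMatrix:
    """Match/mismatch scoring over an explicit alphabet (+1/-1 by default)."""
    alpha = tuple(sorted({str(a).upper() for a in alphabet}))
    if not alpha:
        raise ValueError("empty alphabet")
    n = len(alpha)
    scores = np.full((n, n), mismatch, dtype=np.int64)
    np.fill_diagonal(scores, match)
    return SubstitutionMatrix(alpha, scores, gap=gap, name="identity")


def read_fasta(path: str | Path, alphabet: Iterable[str] | None = None) -> SequenceSet:
    """Read a multi-FASTA file into a :class:`SequenceSet`.

    Record ids are the first whitespace-delimited token of each header;
    residues are upper-cased.  Symbols outside `alphabet` (which defaults
    to the 20 standard amino acids and therefore also covers unambiguous
    DNA) are a hard error naming the offending record — ``*`` and ``-``
    are never accepted.
    """
    alpha = PROTEIN_ALPHABET if alphabet is None else frozenset(str(a).upper() for a in alphabet)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return SequenceSet(tuple(records), alpha)


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 70) -> None:
    """Write a :class:`SequenceSet` as multi-FASTA."""
    with open(path, "w") as fh:
        for rid, seq in seqs.records:
            fh.write(f">{rid}\n")
            for start in range(0, len(seq), width):
                fh.write(seq[start : start + width] + "\n")


def read_substitution_matrix(
    source: str | Path,
    gap: int = -10,
    alphabet: Iterable[str] | None = None,
) -> SubstitutionMatrix:
    """Load a scoring matrix from a file or by builtin name.

    `source` may be a path to a whitespace-delimited scoring-matrix file
    (header row of symbols, one labelled row per symbol), or one of the
    builtin names ``"blosum62"`` (the published BLOSUM62 table) and
    ``"identity"`` (+1 match / -1 mismatch over `alphabet`, which is then
    required).
    """
    name = str(source).lower()
    if name == "identity":
        if alphabet is None:
            raise ValueError("builtin 'identity' needs an explicit alphabet")
        return identity_matrix(alphabet, gap=gap)
    if name == "blosum62":
        table = substitution_matrices.load("BLOSUM62")
        return _from_biopython(table, gap=gap, name="blosum62")
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"scoring matrix {source!r}: not a builtin name and no such file")
    table = substitution_matrices.read(str(path))
    return _from_biopython(table, gap=gap, name=path.name)


def _from_biopython(table, gap: int, name: str) -> SubstitutionMatrix:
    alpha = tuple(str(a) for a in table.alphabet)
    scores = np.asarray(table, dtype=np.int64)
    return SubstitutionMatrix(alpha, scores, gap=gap, name=name)


def write_phylip_distances(seqs: SequenceSet, dv, path: str | Path) -> None:
    """Write the condensed distances as a square symmetric PHYLIP matrix.

    First line is N; each following line is the id padded/truncated to 10
    characters followed by N distances with six decimal places.  The
    diagonal is written as 0.000000.
    """
    from .pipeline import DistanceVector  # local import to avoid a cycle

    dv = dv if isinstance(dv, DistanceVector) else DistanceVector(np.asarray(dv), len(seqs))
    n = len(seqs)
    if dv.n != n:
        raise ValueError(f"distance vector is for n={dv.n} sequences, FASTA has {n}")
    square = dv.to_square()
    with open(path, "w") as fh:
        fh.write(f"{n}\n")
        for i, rid in enumerate(seqs.ids):
            row = "  ".join(f"{square[i, j]:.6f}" for j in range(n))
            fh.write(f"{rid[:10]:<10}{row}\n")


def write_distance_vector_tsv(seqs: SequenceSet, dv, path: str | Path) -> None:
    """Write one TSV row per pair: condensed index h, both ids, distance."""
    from .pipeline import DistanceVector, index_to_pair

    dv = dv if isinstance(dv, DistanceVector) else DistanceVector(np.asarray(dv), len(seqs))
    if dv.n != len(seqs):
        raise ValueError(f"distance vector is for n={dv.n} sequences, FASTA has {len(seqs)}")
    ids = seqs.ids
    with open(path, "w") as fh:
        fh.write("h\tid_i\tid_j\tdistance\n")
        for h, value in enumerate(dv.values):
            i, j = index_to_pair(h, dv.n)
            fh.write(f"{h}\t{ids[i]}\t{ids[j]}\t{value:.6f}\n")
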