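"""Seeded generators of synthetic test sequences.

Everything downstream is testable without downloads: `random_sequences`
gives i.i.d. uniform residues, and `mutated_family` gives one ancestor
plus descendants carrying independent per-site substitutions, so the
expected distance grows with the substitution rate.  No indels are
simulated — the alignment recurrences handle gaps, but substitution-only
families keep the expected-distance trend clean.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import SequenceSet

__all__ = ["GeneratorSpec", "random_sequences", "mutated_family"]

_DNA = "ACGT"


@dataclasses.dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic sequence set.

    `length` is either a fixed int or an inclusive ``(lo, hi)`` range
    sampled uniformly per record.  A fixed seed makes the output
    byte-identical across runs.
    """

    alphabet: str = _DNA
    n: int = 10
    length: int | tuple[int, int] = 100
    sub_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alphabet:
            raise ValueError("empty alphabet")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise ValueError("alphabet symbols must be unique")
        if self.n < 1:
            raise ValueError(f"need n >= 1 sequences, got {self.n}")
        lo, hi = self.length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"invalid length specification {self.length!r}")
        if not 0.0 <= self.sub_rate <= 1.0:
            raise ValueError(f"substitution rate {self.sub_rate} outside [0, 1]")

    @property
    def length_range(self) -> tuple[int, int]:
        if isinstance(self.length, tuple):
            return self.length
        return (self.length, self.length)


def _ids(n: int) -> list[str]:
    return [f"seq_{k:04d}" for k in range(1, n + 1)]


def random_sequences(spec: GeneratorSpec) -> SequenceSet:
    """i.i.d. uniform residues; ids seq_0001...; reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    symbols = np.array(list(spec.alphabet.upper()))
    lo, hi = spec.length_range
    records = []
    for rid in _ids(spec.n):
        length = int(rng.integers(lo, hi + 1))
        records.append((rid, "".join(symbols[rng.integers(0, symbols.size, size=length)])))
    return SequenceSet.from_pairs(records, alphabet=symbols)


def mutated_family(
    ancestor_length: int, n: int, sub_rate: float, seed: int = 0, alphabet: str = _DNA
) -> SequenceSet:
    """One random ancestor and n-1 descendants with per-site substitutions.

    Each descendant site mutates independently with probability `sub_rate`;
    a mutated site is redrawn uniformly from the other alphabet symbols,
    so it always differs from the ancestor.
    """
    spec = GeneratorSpec(alphabet=alphabet, n=1, length=ancestor_length,
                         sub_rate=sub_rate, seed=seed)
    rng = np.random.default_rng(seed)
    symbols = np.array(list(spec.alphabet.upper()))
    k = symbols.size
    if k < 2 and sub_rate > 0:
        raise ValueError("substitutions need at least 2 alphabet symbols")
    ancestor = rng.integers(0, k, size=ancestor_length)
    records = [("seq_0001", "".join(symbols[ancestor]))]
    for rid in _ids(n)[1:]:
        child = ancestor.copy()
        hit = rng.random(ancestor_length) < sub_rate
        # uniform over the k-1 other symbols
        child[hit] = (child[hit] + rng.integers(1, k, size=int(hit.sum()))) % k
        records.append((rid, "".join(symbols[child])))
    return SequenceSet.from_pairs(records, alphabet=symbols)
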