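"""Spaced seeds, s-mer extraction, and s-mer / k-mer pair scoring.

A spaced seed is a pattern over ``{1, *}``: ``1`` positions must be
compared, ``*`` positions are don't-cares.  The *weight* is the number of
``1`` s and the *span* the total pattern length.  An *s-mer* is the string
of residues read at the seed's ``1`` positions of a sequence window (the
spaced analogue of a k-mer).

Two s-mers ``w`` and ``z`` score as the sum of substitution-matrix values
over the match positions::

    S_smer(w, z) = sum_{s[i] = 1} M(w_i, z_i)

and two k-mers (contiguous equal-length windows) as the sum over all
positions.  Both scores are symmetric because the matrix is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Protein, SubstitutionMatrix, encode_sequence

#: The four default spaced seeds (weight 5, span 12), chosen because four
#: seeds of weight five give the best sensitivity/speed trade-off for
#: amino-acid similarity search.
DEFAULT_SEED_PATTERNS = (
    "11****11***1",
    "1**1*1***1*1",
    "11**1***1**1",
    "1*1******111",
)


@dataclass(frozen=True)
class SpacedSeed:
    """A match/don't-care pattern; first and last characters must be ``1``."""

    pattern: str
    match_offsets: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("seed pattern must be nonempty")
        bad = set(self.pattern) - {"1", "*"}
        if bad:
            raise ValueError(f"illegal seed character(s) {sorted(bad)} "
                             f"in {self.pattern!r}")
        if self.pattern[0] != "1" or self.pattern[-1] != "1":
            raise ValueError(f"seed {self.pattern!r} must start and end with '1'")
        object.__setattr__(self, "match_offsets",
                           tuple(i for i, c in enumerate(self.pattern) if c == "1"))

    @property
    def weight(self) -> int:
        return len(self.match_offsets)

    @property
    def span(self) -> int:
        return len(self.pattern)


def parse_seed(pattern: str) -> SpacedSeed:
    """Parse a seed pattern string such as ``"11****11***1"``."""
    return SpacedSeed(pattern)


def default_seeds() -> tuple[SpacedSeed, ...]:
    """The four default weight-5, span-12 spaced seeds."""
    return tuple(parse_seed(p) for p in DEFAULT_SEED_PATTERNS)


@dataclass(frozen=True, order=True)
class SMerOccurrence:
    """One s-mer occurrence: which protein, where, and its key letters."""

    protein_ordinal: int
    start: int
    key: str


def extract_smers(protein: Protein, seed: SpacedSeed,
                  protein_ordinal: int = 0) -> list[SMerOccurrence]:
    """All s-mer occurrences of ``protein`` under ``seed``.

    One occurrence per start position in ``[0, len - span]``; empty when
    the sequence is shorter than the span.
    """
    seq = protein.sequence
    n = len(seq) - seed.span + 1
    if n <= 0:
        return []
    offs = seed.match_offsets
    return [SMerOccurrence(protein_ordinal, i, "".join(seq[i + o] for o in offs))
            for i in range(n)]


def smer_score(w: str, z: str, matrix: SubstitutionMatrix) -> int:
    """Score of two s-mer keys: sum of matrix values at the match positions."""
    if len(w) != len(z):
        raise ValueError(f"s-mer key length mismatch: {len(w)} vs {len(z)}")
    cw = encode_sequence(w)
    cz = encode_sequence(z)
    return int(matrix.codes[cw, cz].sum())


def kmer_score(a: str, b: str, matrix: SubstitutionMatrix) -> int:
    """Score of two equal-length windows: sum of matrix values positionwise."""
    if len(a) != len(b):
        raise ValueError(f"k-mer length mismatch: {len(a)} vs {len(b)}")
    ca = encode_sequence(a)
    cb = encode_sequence(b)
    return int(matrix.codes[ca, cb].sum())


def encode_keys(keys: list[str]) -> np.ndarray:
    """Encode s-mer keys into an ``(n, weight)`` residue-code array."""
    if not keys:
        return np.empty((0, 0), dtype=np.uint8)
    flat = encode_sequence("".join(keys))
    return flat.reshape(len(keys), len(keys[0]))
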