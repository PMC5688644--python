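"""Sequence, matrix and interaction-list I/O plus the core in-memory types.

Conventions used throughout the package:

* Coordinates are 0-based, half-open.  1-based coordinates appear only in
  log or report text.
* Sequences are stored uppercase over the 20 standard amino-acid letters;
  every other letter (``B``, ``Z``, ``U``, ``O``, ``J``, ``*`` ...) is
  collapsed into a single unknown class written ``X``.
* Protein pairs are unordered; the canonical form of a pair sorts the two
  identifiers (or ordinals) ascending.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, sorted; index in this string is the residue code.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Single symbol standing in for every non-standard residue.
UNKNOWN = "X"
#: Full internal alphabet; ``ALPHABET[20] == "X"``.
ALPHABET = AMINO_ACIDS + UNKNOWN
UNKNOWN_CODE = len(AMINO_ACIDS)

_CANON_TABLE = {}
for _c in map(chr, range(256)):
    up = _c.upper()
    _CANON_TABLE[ord(_c)] = up if up in AMINO_ACIDS else UNKNOWN
_CANON_TABLE = str.maketrans(_CANON_TABLE)

_ENCODE = np.full(128, UNKNOWN_CODE, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _ENCODE[ord(_c)] = _i


def canonicalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and map every non-standard letter to ``X``."""
    return seq.translate(_CANON_TABLE)


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a canonical sequence into residue codes (uint8, X == 20)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_sequence(codes: np.ndarray) -> str:
    return "".join(ALPHABET[c] for c in codes)


@dataclass(frozen=True)
class Protein:
    """A named amino-acid sequence.

    ``id`` is the first whitespace-delimited token of the FASTA header and
    must be unique within a :class:`Proteome`; ``sequence`` is canonical
    (uppercase, non-standard residues collapsed to ``X``).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be nonempty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


class Proteome:
    """An ordered collection of proteins with a stable id -> ordinal index."""

    def __init__(self, proteins: Iterable[Protein]):
        self.proteins: list[Protein] = list(proteins)
        self.index: dict[str, int] = {}
        for i, p in enumerate(self.proteins):
            if p.id in self.index:
                raise ValueError(f"duplicate protein id {p.id!r}")
            self.index[p.id] = i
        self._encoded: list[np.ndarray | None] = [None] * len(self.proteins)

    def __len__(self) -> int:
        return len(self.proteins)

    def __iter__(self) -> Iterator[Protein]:
        return iter(self.proteins)

    def __getitem__(self, key: int | str) -> Protein:
        if isinstance(key, str):
            return self.proteins[self.index[key]]
        return self.proteins[key]

    def ordinal(self, protein_id: str) -> int:
        return self.index[protein_id]

    def encoded(self, ordinal: int) -> np.ndarray:
        """Residue-code array of protein ``ordinal`` (cached)."""
        enc = self._encoded[ordinal]
        if enc is None:
            enc = encode_sequence(self.proteins[ordinal].sequence)
            self._encoded[ordinal] = enc
        return enc

    def lengths(self) -> np.ndarray:
        return np.array([len(p) for p in self.proteins], dtype=np.int64)


class SubstitutionMatrix:
    """Symmetric integer amino-acid similarity scores over ``ALPHABET``.

    The unknown class scores come from the source matrix's ``X`` wildcard
    row when present, otherwise from a configurable pessimistic default
    (the matrix minimum), so that unknown residues never create spurious
    similarity.
    """

    def __init__(self, codes: np.ndarray, name: str = ""):
        codes = np.asarray(codes, dtype=np.int32)
        n = len(ALPHABET)
        if codes.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} score array, got {codes.shape}")
        if not np.array_equal(codes, codes.T):
            raise ValueError("substitution matrix is not symmetric")
        self.codes = codes
        self.name = name

    def score(self, a: str, b: str) -> int:
        """Score of an ordered symbol pair (letters outside the alphabet read as X)."""
        ca = _ENCODE[ord(a)] if ord(a) < 128 else UNKNOWN_CODE
        cb = _ENCODE[ord(b)] if ord(b) < 128 else UNKNOWN_CODE
        return int(self.codes[ca, cb])

    def __getitem__(self, pair: tuple[str, str]) -> int:
        return self.score(*pair)

    def min_score(self) -> int:
        return int(self.codes.min())


def read_substitution_matrix(path: str | Path, name: str | None = None,
                             unknown_score: int | None = None) -> SubstitutionMatrix:
    """Read a square NCBI-style substitution matrix text file.

    The layout is a header row of symbols followed by one labelled row per
    symbol; ``#`` comment lines are ignored.  The matrix must be symmetric
    and must define all 20 standard amino acids.  When the file carries an
    ``X`` wildcard row it supplies the unknown-class scores; otherwise
    ``unknown_score`` (default: the matrix minimum) is used.
    """
    path = Path(path)
    with open(path) as fh:
        arr = substitution_matrices.read(fh)
    symbols = list(arr.alphabet)
    missing = [c for c in AMINO_ACIDS if c not in symbols]
    if missing:
        raise ValueError(f"matrix {path} is missing symbol(s): {', '.join(missing)}")
    raw = np.asarray(arr)
    if not np.array_equal(raw, raw.T):
        raise ValueError(f"matrix {path} is not symmetric")
    col = {c: i for i, c in enumerate(symbols)}
    n = len(ALPHABET)
    codes = np.zeros((n, n), dtype=np.int32)
    std = [col[c] for c in AMINO_ACIDS]
    codes[:20, :20] = raw[np.ix_(std, std)]
    if UNKNOWN in col:
        x = col[UNKNOWN]
        codes[20, :20] = raw[x, std]
        codes[:20, 20] = raw[std, x]
        codes[20, 20] = raw[x, x]
    else:
        fill = int(raw[np.ix_(std, std)].min()) if unknown_score is None else unknown_score
        codes[20, :] = fill
        codes[:, 20] = fill
    return SubstitutionMatrix(codes, name=name or path.stem.upper())


def load_default_matrix() -> SubstitutionMatrix:
    """Load the bundled PAM120 matrix (the default scoring matrix)."""
    with resources.as_file(resources.files("sprint_ppi").joinpath("data/pam120.txt")) as p:
        return read_substitution_matrix(p, name="PAM120")


class PPIList:
    """A set of unordered, deduplicated protein-identifier pairs."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[tuple[str, str]] = {self.canonical(a, b) for a, b in pairs}

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        self._pairs.add(self.canonical(a, b))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return self.canonical(*pair) in self._pairs

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._pairs))

    def __len__(self) -> int:
        return len(self._pairs)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, PPIList) and self._pairs == other._pairs

    def proteins(self) -> set[str]:
        """All protein ids occurring in at least one pair."""
        return {p for pair in self._pairs for p in pair}

    def union(self, other: "PPIList") -> "PPIList":
        out = PPIList()
        out._pairs = self._pairs | other._pairs
        return out

    def isdisjoint(self, other: "PPIList") -> bool:
        return self._pairs.isdisjoint(other._pairs)


@dataclass(frozen=True, order=True)
class SimilarRegionPair:
    """Two equal-length ungapped subsequences deemed similar.

    ``prot_a``/``prot_b`` are proteome ordinals, starts are 0-based, and
    both sides have the same ``length``.  The canonical form orders the
    sides so that ``(prot_a, start_a) <= (prot_b, start_b)``.
    """

    prot_a: int
    start_a: int
    prot_b: int
    start_b: int
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("similar region length must be >= 1")

    @property
    def end_a(self) -> int:
        return self.start_a + self.length

    @property
    def end_b(self) -> int:
        return self.start_b + self.length

    def canonical(self) -> "SimilarRegionPair":
        if (self.prot_a, self.start_a) <= (self.prot_b, self.start_b):
            return self
        return SimilarRegionPair(self.prot_b, self.start_b,
                                 self.prot_a, self.start_a, self.length)

    def validate(self, proteome: Proteome) -> None:
        for prot, start, side in ((self.prot_a, self.start_a, "A"),
                                  (self.prot_b, self.start_b, "B")):
            if start < 0 or start + self.length > len(proteome[prot]):
                raise ValueError(
                    f"similarity side {side} ({proteome[prot].id}, start {start}, "
                    f"length {self.length}) overruns the sequence "
                    f"(length {len(proteome[prot])})")


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Proteome:
    """Read a FASTA proteome.

    One :class:`Protein` per record; multi-line sequences are concatenated,
    the id is the first whitespace-delimited token after ``>``, letters are
    uppercased and non-standard residues mapped to ``X``.  Duplicate ids,
    empty records and empty files raise :class:`ValueError`.
    """
    proteins = []
    seen = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise ValueError(f"duplicate protein id {record.id!r} in {path}")
        seen.add(record.id)
        seq = canonicalize_sequence(str(record.seq))
        if not seq:
            raise ValueError(f"empty sequence for protein {record.id!r} in {path}")
        proteins.append(Protein(record.id, seq))
    if not proteins:
        raise ValueError(f"no FASTA records found in {path}")
    return Proteome(proteins)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for p in proteome:
            fh.write(f">{p.id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i:i + width] + "\n")


_HEADER_TOKENS = {
    "protein_a", "protein_b", "proteina", "proteinb", "id_a", "id_b",
    "ida", "idb", "interactor_a", "interactor_b", "protein1", "protein2",
    "uniprot_a", "uniprot_b",
}


def read_ppi_tsv(path: str | Path, proteome: Proteome | None = None,
                 strict: bool = False) -> PPIList:
    """Read a two-column tab-separated list of interacting protein ids.

    Pairs are unordered and deduplicated.  When a ``proteome`` is given,
    pairs referencing unknown ids are dropped with a logged count (or raise
    under ``strict=True``).  A first line whose fields are common column
    names is treated as a header.  Malformed lines raise with their line
    number (1-based, as in editors).
    """
    ppis = PPIList()
    dropped = 0
    first_data_line = True
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}:{lineno}: expected two tab-separated ids, "
                                 f"got {line!r}")
            a, b = fields[0].strip(), fields[1].strip()
            if first_data_line:
                first_data_line = False
                if a.lower() in _HEADER_TOKENS and b.lower() in _HEADER_TOKENS:
                    continue
            if proteome is not None and (a not in proteome.index or b not in proteome.index):
                if strict:
                    raise ValueError(f"{path}:{lineno}: unknown protein id in pair "
                                     f"({a!r}, {b!r})")
                dropped += 1
                continue
            ppis.add(a, b)
    if dropped:
        logger.info("dropped %d PPI pair(s) referencing unknown ids from %s",
                    dropped, path)
    return ppis


def write_ppi_tsv(ppis: PPIList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in ppis:
            fh.write(f"{a}\t{b}\n")


_SIM_COLUMNS = ("id_a", "start_a", "id_b", "start_b", "length")


def write_similarities(pairs: Iterable[SimilarRegionPair], path: str | Path,
                       proteome: Proteome) -> None:
    """Write similar-region pairs as a 5-column TSV (0-based starts)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_SIM_COLUMNS) + "\n")
        for s in sorted(pairs):
            fh.write(f"{proteome[s.prot_a].id}\t{s.start_a}\t"
                     f"{proteome[s.prot_b].id}\t{s.start_b}\t{s.length}\n")


def read_similarities(path: str | Path, proteome: Proteome,
                      validate: bool = True) -> list[SimilarRegionPair]:
    """Read similar-region pairs written by :func:`write_similarities`.

    With ``validate=True`` a record whose region overruns its sequence end
    raises :class:`ValueError`.
    """
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _SIM_COLUMNS:
            raise ValueError(f"{path}: unexpected similarity header {header}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            id_a, sa, id_b, sb, length = fields
            rec = SimilarRegionPair(proteome.ordinal(id_a), int(sa),
                                    proteome.ordinal(id_b), int(sb), int(length))
            if validate:
                rec.validate(proteome)
            out.append(rec)
    return out


def write_scores(rows: Sequence[tuple[str, str, float]], path: str | Path) -> None:
    """Write (id_a, id_b, score) rows, scores to 6 decimals, descending."""
    ordered = sorted(rows, key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tscore\n")
        for a, b, s in ordered:
            fh.write(f"{a}\t{b}\t{s:.6f}\n")


def read_scores(path: str | Path) -> list[tuple[str, str, float]]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id_a"):
            raise ValueError(f"{path}: unexpected scores header")
        for line in fh:
            if not line.strip():
                continue
            a, b, s = line.rstrip("\n").split("\t")
            out.append((a, b, float(s)))
    return out
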