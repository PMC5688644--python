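"""Interaction scoring: transfer evidence from known PPIs via similarities.

A similar region pair of length n contributes ``n - k + 1`` length-k
blocks.  For equal-length sides X and Y, the region score is the sum of
all corresponding k-mer pair scores::

    S_e(X, Y) = sum_{i=1}^{n-k+1} S_kmer(X[i..i+k-1], Y[i..i+k-1])

(0 when n < k, the empty sum).  Every known interacting pair (P1, P2)
then distributes evidence: for each similarity (X1, Y1) linking P1 to a
protein Q1 and each similarity (X2, Y2) linking P2 to a protein Q2, the
pair score is increased by

    S_p(Q1, Q2) += [S_e(X1,Y1) * (|X2|-k+1) + S_e(X2,Y2) * (|X1|-k+1)]
                   / (|Q1| * |Q2|)

i.e. each block-pair score on one bridge is multiplied by the number of
blocks on the other bridge, normalized by the product of the scored
proteins' lengths.  Both orientations of every stored similarity are
visible from either endpoint, and by default every protein also carries
one implicit identity similarity with itself spanning its full length, so
known interacting pairs themselves always score strictly positive.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import numpy as np

from .seqio import PPIList, Proteome, SimilarRegionPair, SubstitutionMatrix
from .seqio import encode_sequence


def block_count(length: int, k: int) -> int:
    """Number of length-k blocks in a region of the given length: (l-k+1)+."""
    return max(0, length - k + 1)


def _region_score_codes(x: np.ndarray, y: np.ndarray,
                        mat: np.ndarray, k: int) -> int:
    n = len(x)
    if n < k:
        return 0
    col = mat[x, y].astype(np.int64)
    cs = np.concatenate(([0], np.cumsum(col)))
    return int((cs[k:] - cs[:-k]).sum())


def region_score(x: str | np.ndarray, y: str | np.ndarray,
                 matrix: SubstitutionMatrix, k: int = 20) -> int:
    """S_e: summed scores of all corresponding k-mer pairs of two sides."""
    cx = encode_sequence(x) if isinstance(x, str) else np.asarray(x)
    cy = encode_sequence(y) if isinstance(y, str) else np.asarray(y)
    if len(cx) != len(cy):
        raise ValueError(f"region side length mismatch: {len(cx)} vs {len(cy)}")
    return _region_score_codes(cx, cy, matrix.codes, k)


class TrainingSet:
    """Known interacting pairs resolved to proteome ordinals."""

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        self.pairs: list[tuple[int, int]] = sorted(
            {(a, b) if a <= b else (b, a) for a, b in pairs})

    @classmethod
    def from_ppis(cls, ppis: PPIList, proteome: Proteome) -> "TrainingSet":
        return cls((proteome.ordinal(a), proteome.ordinal(b)) for a, b in ppis)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


class PairScoreTable:
    """Sparse symmetric map from unordered protein-ordinal pairs to scores.

    Absent keys read as 0.  Self-pairs (A, A) are legal keys.
    """

    def __init__(self) -> None:
        self._scores: dict[tuple[int, int], float] = {}

    @staticmethod
    def _key(a: int, b: int) -> tuple[int, int]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: int, b: int, value: float) -> None:
        key = self._key(a, b)
        self._scores[key] = self._scores.get(key, 0.0) + float(value)

    def get(self, a: int, b: int) -> float:
        return self._scores.get(self._key(a, b), 0.0)

    def items(self) -> Iterator[tuple[tuple[int, int], float]]:
        return iter(sorted(self._scores.items()))

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, pair: tuple[int, int]) -> bool:
        return self._key(*pair) in self._scores


def _incidence_lists(similarities: Iterable[SimilarRegionPair],
                     proteome: Proteome, matrix: SubstitutionMatrix, k: int,
                     include_identity: bool) -> list[list[tuple[int, int, int]]]:
    """Per-protein list of (partner, S_e, block count) for incident similarities.

    A similarity between P and Q appears once in P's list (partner Q) and
    once in Q's list (partner P); an intra-protein similarity therefore
    appears twice in the same list, once per orientation.  The identity
    self-similarity, whose two orientations coincide, appears once.
    """
    mat = matrix.codes
    inc: list[list[tuple[int, int, int]]] = [[] for _ in proteome]
    for s in similarities:
        x = proteome.encoded(s.prot_a)[s.start_a:s.end_a]
        y = proteome.encoded(s.prot_b)[s.start_b:s.end_b]
        se = _region_score_codes(x, y, mat, k)
        bc = block_count(s.length, k)
        inc[s.prot_a].append((s.prot_b, se, bc))
        inc[s.prot_b].append((s.prot_a, se, bc))
    if include_identity:
        for p in range(len(proteome)):
            enc = proteome.encoded(p)
            inc[p].append((p, _region_score_codes(enc, enc, mat, k),
                           block_count(len(enc), k)))
    return inc


def accumulate_scores(similarities: Iterable[SimilarRegionPair],
                      training: TrainingSet, proteome: Proteome,
                      matrix: SubstitutionMatrix, k: int = 20,
                      include_identity: bool = True) -> PairScoreTable:
    """Accumulate the interaction score table from similarities and known PPIs.

    Starting from all-zero, every training pair (P1, P2) contributes, for
    every similarity linking P1 to some Q1 and every similarity linking P2
    to some Q2, the bridged block-count term normalized by |Q1|*|Q2| (see
    the module docstring).  With ``include_identity`` every protein also
    bridges to itself over its full length.
    """
    lengths = proteome.lengths()
    inc = _incidence_lists(similarities, proteome, matrix, k, include_identity)
    table = PairScoreTable()
    for p1, p2 in training:
        for q1, se1, b1 in inc[p1]:
            lq1 = lengths[q1]
            for q2, se2, b2 in inc[p2]:
                table.add(q1, q2,
                          (se1 * b2 + se2 * b1) / (lq1 * lengths[q2]))
    return table


def count_candidate_pairs(n: int) -> int:
    """Number of candidate pairs over n proteins, self-pairs included."""
    return (n * n + n) // 2


def rank_predictions(table: PairScoreTable, proteome: Proteome,
                     threshold: float | None = None
                     ) -> list[tuple[str, str, float]]:
    """Score table entries as (id_a, id_b, score), best first.

    Sorted by descending score, ties broken by lexicographic pair ids.
    With a threshold, only pairs scoring >= threshold are reported.
    """
    rows = []
    for (a, b), score in table.items():
        if threshold is not None and score < threshold:
            continue
        id_a, id_b = sorted((proteome[a].id, proteome[b].id))
        rows.append((id_a, id_b, score))
    rows.sort(key=lambda r: (-r[2], r[0], r[1]))
    return rows
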