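"""Promiscuity filtering of similarities.

Positions covered by very many similarity sides are taken to be generic
repeats with no bearing on interaction, so they are eliminated: coverage
counts are computed once over the whole similarity set, positions with
count >= T_hc (default 40) are removed from every similarity they touch,
and the surviving aligned columns are re-emitted as maximal contiguous
segments.  Removal on one side is mirrored onto the aligned positions of
the counterpart side, so segments stay equal-length and keep the original
columnwise alignment.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

from .seqio import Proteome, SimilarRegionPair


class PositionCounts:
    """Per-protein, per-residue similarity coverage counts."""

    def __init__(self, counts: Sequence[np.ndarray]):
        self.counts = list(counts)

    def count(self, protein_ordinal: int, position: int) -> int:
        return int(self.counts[protein_ordinal][position])

    def __getitem__(self, protein_ordinal: int) -> np.ndarray:
        return self.counts[protein_ordinal]


class EliminationSet:
    """Per-protein boolean masks of eliminated (high-count) positions."""

    def __init__(self, masks: Sequence[np.ndarray]):
        self.masks = [np.asarray(m, dtype=bool) for m in masks]

    @classmethod
    def from_positions(cls, lengths: Sequence[int],
                       positions: dict[int, Iterable[int]]) -> "EliminationSet":
        """Build from explicit position sets (mainly for tests / tools)."""
        masks = [np.zeros(n, dtype=bool) for n in lengths]
        for prot, pos in positions.items():
            masks[prot][list(pos)] = True
        return cls(masks)

    def is_eliminated(self, protein_ordinal: int, position: int) -> bool:
        return bool(self.masks[protein_ordinal][position])

    def positions(self, protein_ordinal: int) -> np.ndarray:
        return np.flatnonzero(self.masks[protein_ordinal])

    def __getitem__(self, protein_ordinal: int) -> np.ndarray:
        return self.masks[protein_ordinal]


def position_counts(similarities: Iterable[SimilarRegionPair],
                    proteome: Proteome) -> PositionCounts:
    """How many similarity sides cover each residue of each protein.

    Every similarity contributes +1 to every covered position on *both* of
    its sides (twice to the same protein for intra-protein similarities).
    """
    counts = [np.zeros(len(p), dtype=np.int32) for p in proteome]
    for s in similarities:
        s.validate(proteome)
        counts[s.prot_a][s.start_a:s.end_a] += 1
        counts[s.prot_b][s.start_b:s.end_b] += 1
    return PositionCounts(counts)


def eliminate_positions(counts: PositionCounts, t_hc: int) -> EliminationSet:
    """Positions with coverage count >= ``t_hc`` (default threshold 40)."""
    return EliminationSet([c >= t_hc for c in counts.counts])


def split_similarities(similarities: Iterable[SimilarRegionPair],
                       elim: EliminationSet) -> list[SimilarRegionPair]:
    """Remove eliminated columns from every similarity and re-segment.

    A column is dropped when its position on either side is eliminated
    (each side's removals are mirrored onto the counterpart through the
    fixed columnwise alignment).  Surviving columns are re-emitted as
    maximal contiguous equal-length segments; segments shorter than k are
    kept — they simply contribute no k-windows downstream.
    """
    out: list[SimilarRegionPair] = []
    for s in similarities:
        keep = ~(elim[s.prot_a][s.start_a:s.end_a]
                 | elim[s.prot_b][s.start_b:s.end_b])
        if keep.all():
            out.append(s)
            continue
        padded = np.concatenate(([False], keep, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for lo, hi in zip(edges[::2], edges[1::2]):
            out.append(SimilarRegionPair(s.prot_a, s.start_a + int(lo),
                                         s.prot_b, s.start_b + int(lo),
                                         int(hi - lo)))
    return out


def filter_similarities(similarities: Sequence[SimilarRegionPair],
                        proteome: Proteome,
                        t_hc: int = 40) -> list[SimilarRegionPair]:
    """Single-pass high-count filter: count, eliminate, split."""
    counts = position_counts(similarities, proteome)
    elim = eliminate_positions(counts, t_hc)
    return split_similarities(similarities, elim)
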