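"""Hit-and-extend search for similar subsequence pairs across a proteome.

The search has three stages, all ungapped:

1. **Indexing** — every s-mer of every protein, for each spaced seed, goes
   into a hash table keyed by its letters.
2. **Hits** — every unordered pair of occurrences whose s-mer keys score at
   least ``T_hit`` under the substitution matrix is a hit.  Exact hits are
   two occurrences of the same key (kept only when the key's self-score
   meets the threshold); approximate hits pair merely similar keys.
3. **Verify and extend** — for each hit the two k-mers centred on the
   s-mer occurrences are scored; if they reach ``T_sim`` the pair is
   extended outwards, one residue at a time on either side, for as long as
   the newly exposed terminal k-window pair still scores at least
   ``T_sim``.  Both sides grow in lockstep, so every similar region pair
   has equal lengths and a fixed residue-to-residue alignment (a single
   "diagonal" ``start_a - start_b``).

Overlapping or adjacent regions of the same protein pair on the same
diagonal are merged into their maximal cover, which also makes the output
independent of seed order and traversal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seqio import Proteome, SimilarRegionPair, SubstitutionMatrix
from .seeds import (SMerOccurrence, SpacedSeed, default_seeds, encode_keys,
                    extract_smers)

__all__ = [
    "SimilarityParams", "Hit", "index_smers", "find_hits", "central_kmers",
    "verify_and_extend", "compute_similarities", "SimilarRegionPair",
]


@dataclass
class SimilarityParams:
    """Search parameters: window length k, thresholds, seeds and matrix.

    Defaults are ``k=20``, ``T_hit=15``, ``T_sim=35`` with the four default
    weight-5 seeds.  ``k`` must be at least the largest seed span so a
    k-mer can contain an s-mer span.
    """

    matrix: SubstitutionMatrix
    k: int = 20
    t_hit: int = 15
    t_sim: int = 35
    seeds: tuple[SpacedSeed, ...] = field(default_factory=default_seeds)

    def __post_init__(self) -> None:
        if not self.seeds:
            raise ValueError("at least one seed is required")
        max_span = max(s.span for s in self.seeds)
        if self.k < max_span:
            raise ValueError(f"k={self.k} must be >= the largest seed span "
                             f"({max_span})")


@dataclass(frozen=True)
class Hit:
    """An unordered pair of s-mer occurrences scoring >= T_hit.

    Canonical form: ``(protein_ordinal, start)`` of ``occ_a`` <= ``occ_b``.
    """

    seed: SpacedSeed
    occ_a: SMerOccurrence
    occ_b: SMerOccurrence
    score: int


def _make_hit(seed: SpacedSeed, oa: SMerOccurrence, ob: SMerOccurrence,
              score: int) -> Hit:
    if (oa.protein_ordinal, oa.start) > (ob.protein_ordinal, ob.start):
        oa, ob = ob, oa
    return Hit(seed, oa, ob, score)


def index_smers(proteome: Proteome,
                seed: SpacedSeed) -> dict[str, list[SMerOccurrence]]:
    """Hash table key -> occurrence list over every protein of the proteome."""
    table: dict[str, list[SMerOccurrence]] = {}
    for ordinal, protein in enumerate(proteome):
        for occ in extract_smers(protein, seed, protein_ordinal=ordinal):
            table.setdefault(occ.key, []).append(occ)
    return table


def find_hits(index: dict[str, list[SMerOccurrence]], seed: SpacedSeed,
              matrix: SubstitutionMatrix, t_hit: int) -> list[Hit]:
    """All hits of ``seed``: unordered occurrence pairs scoring >= ``t_hit``.

    The output contains exactly the pairs of *distinct* occurrences whose
    key pair scores at least ``t_hit``; two occurrences of the same key
    (exact hits) qualify iff the key's self-score does.  Candidate
    enumeration scores all distinct key pairs blockwise with the matrix,
    which keeps the result identical to a brute-force evaluation.
    """
    keys = sorted(index)
    if not keys:
        return []
    kcodes = encode_keys(keys).astype(np.intp)
    n_keys, weight = kcodes.shape
    mat = matrix.codes.astype(np.int32)
    hits: list[Hit] = []
    block = max(1, (1 << 23) // n_keys)
    for r0 in range(0, n_keys, block):
        r1 = min(n_keys, r0 + block)
        # only columns j >= r0 can satisfy j >= i within this row block
        scores = np.zeros((r1 - r0, n_keys - r0), dtype=np.int32)
        for p in range(weight):
            scores += mat[kcodes[r0:r1, p][:, None], kcodes[r0:, p][None, :]]
        rows, cols = np.nonzero(scores >= t_hit)
        for ri, cj in zip(rows.tolist(), cols.tolist()):
            i = r0 + ri
            j = r0 + cj
            if j < i:
                continue
            score = int(scores[ri, cj])
            occs_i = index[keys[i]]
            if i == j:
                for x in range(len(occs_i)):
                    for y in range(x + 1, len(occs_i)):
                        hits.append(_make_hit(seed, occs_i[x], occs_i[y], score))
            else:
                for oa in occs_i:
                    for ob in index[keys[j]]:
                        hits.append(_make_hit(seed, oa, ob, score))
    return hits


def central_kmers(hit: Hit, k: int, proteome: Proteome,
                  clip: str = "shift") -> tuple[int, int] | None:
    """Start positions of the two k-windows centred on the hit's s-mers.

    The ideal start offset is ``occ.start - floor((k - span) / 2)`` on both
    sides, which keeps the windows on the hit's diagonal.  When an ideal
    window overruns a sequence end, ``clip="shift"`` (default) slides both
    windows minimally along the diagonal so that they fit and still contain
    the s-mer spans, while ``clip="strict"`` returns ``None``.  ``None`` is
    also returned when no k-window on the diagonal can satisfy both
    constraints (diagonal overlap shorter than k).
    """
    if clip not in ("shift", "strict"):
        raise ValueError(f"unknown clip mode {clip!r}")
    oa, ob = hit.occ_a, hit.occ_b
    span = hit.seed.span
    len_a = len(proteome[oa.protein_ordinal])
    len_b = len(proteome[ob.protein_ordinal])
    diag = oa.start - ob.start
    margin = (k - span) // 2
    ideal = oa.start - margin
    lo = max(0, diag, oa.start + span - k)
    hi = min(len_a - k, len_b - k + diag, oa.start)
    if lo > hi:
        return None
    if clip == "strict":
        if not lo <= ideal <= hi:
            return None
        start_a = ideal
    else:
        start_a = min(max(ideal, lo), hi)
    return start_a, start_a - diag


def _diagonal_window_scores(enc_a: np.ndarray, enc_b: np.ndarray, diag: int,
                            k: int, mat: np.ndarray) -> tuple[int, np.ndarray]:
    """Scores of every k-window pair along diagonal ``start_a - start_b = diag``.

    Returns ``(a0, ws)`` where ``ws[i]`` is the score of the window pair
    whose A-side starts at residue ``a0 + i``.
    """
    a_lo = max(0, diag)
    a_hi = min(len(enc_a), len(enc_b) + diag)
    if a_hi - a_lo < k:
        return a_lo, np.empty(0, dtype=np.int64)
    col = mat[enc_a[a_lo:a_hi], enc_b[a_lo - diag:a_hi - diag]]
    cs = np.concatenate(([0], np.cumsum(col, dtype=np.int64)))
    return a_lo, cs[k:] - cs[:-k]


def _expand_run(qualify: np.ndarray, idx: int) -> tuple[int, int]:
    """Maximal run of True around ``idx`` (inclusive window-index bounds)."""
    left_bad = np.flatnonzero(~qualify[:idx])
    lo = int(left_bad[-1]) + 1 if left_bad.size else 0
    right_bad = np.flatnonzero(~qualify[idx + 1:])
    hi = idx + int(right_bad[0]) if right_bad.size else len(qualify) - 1
    return lo, hi


def verify_and_extend(hit: Hit, proteome: Proteome, params: SimilarityParams,
                      clip: str = "shift") -> SimilarRegionPair | None:
    """Verify a hit's central k-mer pair and extend it into a similar region.

    Returns ``None`` when the central window pair scores below ``T_sim``;
    otherwise the region obtained by growing both sides in lockstep while
    the terminal k-window pair keeps scoring at least ``T_sim`` (and the
    sequence boundaries permit).  Every returned region has equal-length
    sides and contains the generating s-mer occurrences.
    """
    centre = central_kmers(hit, params.k, proteome, clip=clip)
    if centre is None:
        return None
    start_a, start_b = centre
    pa = hit.occ_a.protein_ordinal
    pb = hit.occ_b.protein_ordinal
    diag = start_a - start_b
    a0, ws = _diagonal_window_scores(proteome.encoded(pa), proteome.encoded(pb),
                                     diag, params.k, params.matrix.codes)
    idx = start_a - a0
    if ws.size == 0 or ws[idx] < params.t_sim:
        return None
    lo, hi = _expand_run(ws >= params.t_sim, idx)
    region_start = a0 + lo
    return SimilarRegionPair(pa, region_start, pb, region_start - diag,
                             hi - lo + params.k).canonical()


def _merge_runs(runs: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Merge window-index runs whose residue spans overlap or touch."""
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(runs):
        if merged and lo <= merged[-1][1] + k:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def compute_similarities(proteome: Proteome, params: SimilarityParams,
                         clip: str = "shift") -> list[SimilarRegionPair]:
    """All similar region pairs of a proteome under ``params``.

    Union over all seeds and hits of the verified, extended regions;
    overlapping or adjacent regions of the same protein pair on the same
    diagonal are merged into their maximal cover.  The result is
    deterministic and independent of seed order.
    """
    k = params.k
    t_sim = params.t_sim
    mat = params.matrix.codes
    # (prot_a, prot_b, diag) -> (a0, qualify boolean array)
    diag_cache: dict[tuple[int, int, int], tuple[int, np.ndarray]] = {}
    # (prot_a, prot_b, diag) -> discovered runs as window-index intervals
    found: dict[tuple[int, int, int], list[tuple[int, int]]] = {}

    for seed in params.seeds:
        index = index_smers(proteome, seed)
        for hit in find_hits(index, seed, params.matrix, params.t_hit):
            centre = central_kmers(hit, k, proteome, clip=clip)
            if centre is None:
                continue
            start_a, start_b = centre
            pa = hit.occ_a.protein_ordinal
            pb = hit.occ_b.protein_ordinal
            diag = start_a - start_b
            key = (pa, pb, diag)
            cached = diag_cache.get(key)
            if cached is None:
                a0, ws = _diagonal_window_scores(proteome.encoded(pa),
                                                 proteome.encoded(pb),
                                                 diag, k, mat)
                cached = (a0, ws >= t_sim)
                diag_cache[key] = cached
            a0, qualify = cached
            idx = start_a - a0
            if qualify.size == 0 or not qualify[idx]:
                continue
            runs = found.get(key)
            if runs is not None and any(lo <= idx <= hi for lo, hi in runs):
                continue
            found.setdefault(key, []).append(_expand_run(qualify, idx))

    out: list[SimilarRegionPair] = []
    for (pa, pb, diag), runs in found.items():
        a0 = diag_cache[(pa, pb, diag)][0]
        for lo, hi in _merge_runs(runs, k):
            start_a = a0 + lo
            out.append(SimilarRegionPair(pa, start_a, pb, start_a - diag,
                                         hi - lo + k))
    return sorted(set(out))
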