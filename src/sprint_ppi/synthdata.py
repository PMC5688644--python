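"""Synthetic proteomes and interaction networks with planted homology.

The generator emulates the premise that proteins similar to an interacting
pair are themselves likely to interact: proteins are i.i.d. uniform
random sequences, families of proteins share one planted region (copied
into each member at a random offset with i.i.d. substitutions), and
interactions hold between members of designated family pairs.  Holding
out the pair between one member of each family — while keeping those
members out of training entirely — makes the held-out pair recoverable
only through similarity bridges.

Mutations are substitutions only; similarities downstream are ungapped,
so indels would only obscure what is being tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import AMINO_ACIDS, PPIList, Protein, Proteome


@dataclass
class SynthSpec:
    """Generation parameters.

    Defaults produce a 100-protein instance with eight 5-member families
    (planted 60-residue regions, 5% per-residue substitution on each
    copy), four interacting family pairs and a handful of background
    interactions — sized so that family structure is detectable by the
    default search parameters while leaving most of the proteome as
    unrelated background.
    """

    n_proteins: int = 100
    min_length: int = 120
    max_length: int = 200
    n_families: int = 8
    family_size: int = 5
    region_length: int = 60
    mutation_rate: float = 0.05
    n_interacting_family_pairs: int = 4
    n_background_ppis: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.region_length < 1:
            raise ValueError("region_length must be >= 1")
        if self.region_length > self.min_length:
            raise ValueError("planted region longer than the shortest sequence")
        if self.n_families * self.family_size > self.n_proteins:
            raise ValueError("not enough proteins for the requested families")
        if 2 * self.n_interacting_family_pairs > self.n_families:
            raise ValueError("not enough families for the interacting pairs")


def _protein_id(i: int) -> str:
    return f"P{i:04d}"


def generate_proteome(spec: SynthSpec) -> tuple[Proteome, pd.DataFrame]:
    """Random proteome with planted family regions, plus a manifest.

    Proteins ``0 .. n_families*family_size - 1`` are family members
    (family f owns the block starting at ``f * family_size``); the rest
    are pure background.  The manifest records every planted copy as
    (protein, family, start, length).
    """
    rng = np.random.default_rng(spec.rng_seed)
    lengths = rng.integers(spec.min_length, spec.max_length + 1,
                           size=spec.n_proteins)
    seqs = [rng.integers(0, 20, size=n).astype(np.uint8) for n in lengths]
    manifest_rows = []
    for fam in range(spec.n_families):
        motif = rng.integers(0, 20, size=spec.region_length).astype(np.uint8)
        for m in range(spec.family_size):
            prot = fam * spec.family_size + m
            offset = int(rng.integers(0, lengths[prot] - spec.region_length + 1))
            copy = motif.copy()
            mutate = rng.random(spec.region_length) < spec.mutation_rate
            # substitution to a uniformly random *different* residue
            shifts = rng.integers(1, 20, size=spec.region_length).astype(np.uint8)
            copy[mutate] = (copy[mutate] + shifts[mutate]) % 20
            seqs[prot][offset:offset + spec.region_length] = copy
            manifest_rows.append({"protein": _protein_id(prot), "family": fam,
                                  "start": offset, "length": spec.region_length})
    proteins = [Protein(_protein_id(i), "".join(AMINO_ACIDS[c] for c in s))
                for i, s in enumerate(seqs)]
    manifest = pd.DataFrame(manifest_rows,
                            columns=["protein", "family", "start", "length"])
    return Proteome(proteins), manifest


def generate_interactions(spec: SynthSpec,
                          manifest: pd.DataFrame) -> tuple[PPIList, PPIList]:
    """Training PPIs and held-out positives over the planted families.

    Families are paired (0,1), (2,3), ... for the first
    ``n_interacting_family_pairs`` pairs.  For each pair, one member of
    each family is set aside; the pair between the two set-aside members
    is held out and *all* their other cross pairs go to training, so the
    held-out pair is supported only by similarity bridges.  Background
    PPIs are random non-family pairs added to training.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    members: dict[int, list[str]] = {
        int(f): sorted(g["protein"]) for f, g in manifest.groupby("family")
    } if len(manifest) else {}
    train = PPIList()
    heldout = PPIList()
    for i in range(spec.n_interacting_family_pairs):
        fam_a, fam_b = 2 * i, 2 * i + 1
        mem_a, mem_b = members[fam_a], members[fam_b]
        if len(mem_a) < 2 or len(mem_b) < 2:
            raise ValueError(f"family pair ({fam_a}, {fam_b}) needs >= 2 "
                             f"members per family")
        hold_a = mem_a[int(rng.integers(len(mem_a)))]
        hold_b = mem_b[int(rng.integers(len(mem_b)))]
        heldout.add(hold_a, hold_b)
        for a in mem_a:
            if a == hold_a:
                continue
            for b in mem_b:
                if b != hold_b:
                    train.add(a, b)
    family_proteins = {p for ms in members.values() for p in ms}
    background = [ _protein_id(i) for i in range(spec.n_proteins)
                   if _protein_id(i) not in family_proteins ]
    added = 0
    attempts = 0
    while added < spec.n_background_ppis and len(background) >= 2:
        attempts += 1
        if attempts > 1000 * max(spec.n_background_ppis, 1):
            break
        a, b = (background[int(j)] for j in
                rng.integers(len(background), size=2))
        if a == b or (a, b) in train:
            continue
        train.add(a, b)
        added += 1
    return train, heldout


def planted_copy_pairs(manifest: pd.DataFrame) -> list[tuple[dict, dict]]:
    """All unordered pairs of planted copies within the same family."""
    pairs = []
    for _, group in manifest.groupby("family"):
        rows = group.to_dict("records")
        for i in range(len(rows)):
            for j in range(i + 1, len(rows)):
                pairs.append((rows[i], rows[j]))
    return pairs


def planted_region_recall(similarities, manifest: pd.DataFrame,
                          proteome: Proteome,
                          min_overlap_fraction: float = 0.5) -> float:
    """Fraction of same-family copy pairs recovered by the similarity set.

    A copy pair counts as recovered when some similarity links its two
    proteins with each side overlapping the respective planted interval by
    at least ``min_overlap_fraction`` of the planted length.
    """
    pairs = planted_copy_pairs(manifest)
    if not pairs:
        return float("nan")
    by_protein_pair: dict[tuple[int, int], list] = {}
    for s in similarities:
        by_protein_pair.setdefault((s.prot_a, s.prot_b), []).append(s)

    def overlap(lo1, hi1, lo2, hi2) -> int:
        return max(0, min(hi1, hi2) - max(lo1, lo2))

    recovered = 0
    for ci, cj in pairs:
        pi, pj = proteome.ordinal(ci["protein"]), proteome.ordinal(cj["protein"])
        need_i = min_overlap_fraction * ci["length"]
        need_j = min_overlap_fraction * cj["length"]
        hit = False
        for (a, b), swap in (((pi, pj), False), ((pj, pi), True)):
            for s in by_protein_pair.get((a, b), ()):
                c_a, c_b = (cj, ci) if swap else (ci, cj)
                need_a, need_b = (need_j, need_i) if swap else (need_i, need_j)
                if (overlap(s.start_a, s.end_a, c_a["start"],
                            c_a["start"] + c_a["length"]) >= need_a
                        and overlap(s.start_b, s.end_b, c_b["start"],
                                    c_b["start"] + c_b["length"]) >= need_b):
                    hit = True
                    break
            if hit:
                break
        recovered += hit
    return recovered / len(pairs)
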