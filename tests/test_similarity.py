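"""Hit enumeration, central-window verification and region extension."""

import itertools

import numpy as np
import pytest

from sprint_ppi import (AMINO_ACIDS, Hit, Protein, Proteome,
                        SimilarityParams, central_kmers,
                        compute_similarities, default_seeds, extract_smers,
                        find_hits, index_smers, kmer_score, parse_seed,
                        smer_score, verify_and_extend)
from sprint_ppi.seeds import SMerOccurrence


def random_proteome(rng, n_proteins, min_len, max_len, prefix="P"):
    return Proteome([
        Protein(f"{prefix}{i}",
                "".join(rng.choice(list(AMINO_ACIDS), size=n)))
        for i, n in enumerate(rng.integers(min_len, max_len + 1,
                                           size=n_proteins))
    ])


def brute_force_hits(proteome, seed, matrix, t_hit):
    """Independent oracle: score every occurrence pair directly."""
    occs = [o for i, p in enumerate(proteome)
            for o in extract_smers(p, seed, protein_ordinal=i)]
    found = set()
    for a, b in itertools.combinations(occs, 2):
        if smer_score(a.key, b.key, matrix) >= t_hit:
            pa = (a.protein_ordinal, a.start)
            pb = (b.protein_ordinal, b.start)
            found.add((pa, pb) if pa <= pb else (pb, pa))
    return found


def hit_set(hits):
    return {((h.occ_a.protein_ordinal, h.occ_a.start),
             (h.occ_b.protein_ordinal, h.occ_b.start)) for h in hits}


class TestIndexSmers:
    def test_total_occurrence_count(self, rng):
        proteome = Proteome([
            Protein("A", "".join(rng.choice(list(AMINO_ACIDS), size=16))),
            Protein("B", "".join(rng.choice(list(AMINO_ACIDS), size=20))),
        ])
        seed = parse_seed("11****11***1")
        table = index_smers(proteome, seed)
        assert sum(len(v) for v in table.values()) == 5 + 9

    def test_empty_proteome(self):
        assert index_smers(Proteome([]), parse_seed("1*1")) == {}

    def test_identical_proteins_share_buckets(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=30))
        proteome = Proteome([Protein("A", seq), Protein("B", seq)])
        table = index_smers(proteome, parse_seed("11****11***1"))
        for occs in table.values():
            assert {o.protein_ordinal for o in occs} == {0, 1}


class TestFindHits:
    def test_matches_brute_force(self, pam120, rng):
        proteome = random_proteome(rng, 6, 30, 50)
        for seed in default_seeds():
            index = index_smers(proteome, seed)
            got = hit_set(find_hits(index, seed, pam120, t_hit=15))
            assert got == brute_force_hits(proteome, seed, pam120, 15)

    def test_huge_threshold_gives_no_hits(self, pam120, rng):
        proteome = random_proteome(rng, 5, 40, 60)
        seed = default_seeds()[0]
        index = index_smers(proteome, seed)
        assert find_hits(index, seed, pam120, t_hit=10**6) == []

    def test_planted_exact_hit_present(self, pam120, rng):
        planted = "WCMFHWCMFHWC"  # high self-score 12-mer
        seqs = ["".join(rng.choice(list(AMINO_ACIDS), size=60))
                for _ in range(2)]
        seqs = [s[:20] + planted + s[32:] for s in seqs]
        proteome = Proteome([Protein("A", seqs[0]), Protein("B", seqs[1])])
        seed = default_seeds()[0]
        key = "".join(planted[o] for o in seed.match_offsets)
        assert smer_score(key, key, pam120) >= 15
        index = index_smers(proteome, seed)
        hits = hit_set(find_hits(index, seed, pam120, t_hit=15))
        assert ((0, 20), (1, 20)) in hits

    def test_trivial_self_hit_excluded(self, pam120):
        proteome = Proteome([Protein("A", "WCMFH" * 6)])
        seed = default_seeds()[0]
        hits = find_hits(index_smers(proteome, seed), seed, pam120, 15)
        for h in hits:
            assert (h.occ_a.protein_ordinal, h.occ_a.start) != \
                (h.occ_b.protein_ordinal, h.occ_b.start)

    def test_lowering_t_hit_is_monotone(self, pam120, rng):
        proteome = random_proteome(rng, 5, 40, 60)
        seed = default_seeds()[1]
        index = index_smers(proteome, seed)
        high = hit_set(find_hits(index, seed, pam120, t_hit=18))
        low = hit_set(find_hits(index, seed, pam120, t_hit=15))
        assert high <= low


def make_hit(seed, pa, sa, pb, sb, score=99):
    return Hit(seed, SMerOccurrence(pa, sa, "X" * seed.weight),
               SMerOccurrence(pb, sb, "X" * seed.weight), score)


class TestCentralKmers:
    def test_centering_arithmetic(self, rng):
        proteome = random_proteome(rng, 2, 30, 30)
        seed = default_seeds()[0]
        hit = make_hit(seed, 0, 10, 1, 10)
        assert central_kmers(hit, 20, proteome) == (6, 6)

    def test_boundary_strict_returns_none(self, rng):
        proteome = random_proteome(rng, 2, 40, 40)
        seed = default_seeds()[0]
        hit = make_hit(seed, 0, 1, 1, 25)
        assert central_kmers(hit, 20, proteome, clip="strict") is None

    def test_boundary_shift_clips_to_fit(self, rng):
        proteome = random_proteome(rng, 2, 40, 40)
        seed = default_seeds()[0]
        hit = make_hit(seed, 0, 1, 1, 20)
        result = central_kmers(hit, 20, proteome)
        assert result is not None
        start_a, start_b = result
        # windows fit, stay on the diagonal, and contain the s-mer spans
        assert start_a >= 0 and start_b >= 0
        assert start_a - start_b == 1 - 20
        assert start_a <= 1 and start_a + 20 >= 1 + seed.span

    def test_k_equal_span_coincides_with_smer(self, rng):
        proteome = random_proteome(rng, 2, 40, 40)
        seed = default_seeds()[0]
        hit = make_hit(seed, 0, 7, 1, 12)
        assert central_kmers(hit, 12, proteome) == (7, 12)


class TestVerifyAndExtend:
    def test_identical_proteins_extend_to_full_overlap(self, pam120, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        proteome = Proteome([Protein("A", seq), Protein("B", seq)])
        params = SimilarityParams(matrix=pam120)
        seed = default_seeds()[0]
        hit = make_hit(seed, 0, 25, 1, 25)
        region = verify_and_extend(hit, proteome, params)
        assert region is not None
        assert (region.start_a, region.start_b, region.length) == (0, 0, 60)

    def test_failed_verification_returns_none(self, pam120, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=60))
        proteome = Proteome([Protein("A", seq), Protein("B", seq)])
        params = SimilarityParams(matrix=pam120, t_sim=10**6)
        hit = make_hit(default_seeds()[0], 0, 25, 1, 25)
        assert verify_and_extend(hit, proteome, params) is None

    def test_terminal_windows_meet_t_sim(self, pam120, rng):
        proteome = random_proteome(rng, 4, 80, 120)
        # plant a shared 40-mer to guarantee regions exist
        shared = "".join(rng.choice(list(AMINO_ACIDS), size=40))
        proteins = list(proteome)
        proteins[0] = Protein("P0", proteins[0].sequence[:10] + shared
                              + proteins[0].sequence[50:])
        proteins[2] = Protein("P2", proteins[2].sequence[:30] + shared
                              + proteins[2].sequence[70:])
        proteome = Proteome(proteins)
        params = SimilarityParams(matrix=pam120)
        regions = compute_similarities(proteome, params)
        assert regions
        k = params.k
        for r in regions:
            a = proteome[r.prot_a].sequence[r.start_a:r.end_a]
            b = proteome[r.prot_b].sequence[r.start_b:r.end_b]
            assert len(a) == len(b) == r.length
            assert kmer_score(a[:k], b[:k], pam120) >= params.t_sim
            assert kmer_score(a[-k:], b[-k:], pam120) >= params.t_sim


class TestComputeSimilarities:
    def make_planted(self, rng, region_len=40):
        shared = "".join(rng.choice(list(AMINO_ACIDS), size=region_len))
        s0 = "".join(rng.choice(list(AMINO_ACIDS), size=100))
        s1 = "".join(rng.choice(list(AMINO_ACIDS), size=100))
        s0 = s0[:15] + shared + s0[15 + region_len:]
        s1 = s1[:42] + shared + s1[42 + region_len:]
        return Proteome([Protein("A", s0), Protein("B", s1)]), (15, 42,
                                                                region_len)

    def test_planted_region_recovered_once_and_fully(self, pam120, rng):
        proteome, (sa, sb, n) = self.make_planted(rng)
        params = SimilarityParams(matrix=pam120)
        sims = compute_similarities(proteome, params)
        diag = sa - sb
        on_diag = [s for s in sims
                   if {s.prot_a, s.prot_b} == {0, 1}
                   and s.start_a - s.start_b == diag]
        assert len(on_diag) == 1
        region = on_diag[0]
        assert region.start_a <= sa and region.end_a >= sa + n

    def test_high_t_hit_gives_empty(self, pam120, rng):
        proteome = random_proteome(rng, 5, 60, 90)
        params = SimilarityParams(matrix=pam120, t_hit=10**6)
        assert compute_similarities(proteome, params) == []

    def test_seed_order_invariance(self, pam120, rng):
        proteome, _ = self.make_planted(rng)
        fwd = SimilarityParams(matrix=pam120, seeds=default_seeds())
        rev = SimilarityParams(matrix=pam120,
                               seeds=tuple(reversed(default_seeds())))
        assert compute_similarities(proteome, fwd) == \
            compute_similarities(proteome, rev)

    def test_determinism(self, pam120, rng):
        proteome, _ = self.make_planted(rng)
        params = SimilarityParams(matrix=pam120)
        assert compute_similarities(proteome, params) == \
            compute_similarities(proteome, params)

    def test_regions_are_canonical_and_in_bounds(self, pam120, rng):
        proteome, _ = self.make_planted(rng)
        sims = compute_similarities(proteome,
                                    SimilarityParams(matrix=pam120))
        for s in sims:
            assert (s.prot_a, s.start_a) <= (s.prot_b, s.start_b)
            s.validate(proteome)


def test_params_reject_k_below_seed_span(pam120):
    with pytest.raises(ValueError, match="span"):
        SimilarityParams(matrix=pam120, k=10)
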