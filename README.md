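# sprint-ppi

Sequence-based prediction of protein–protein interactions (PPIs) with
multiple spaced seeds, for computational biologists who want to score an
entire proteome's candidate interactome from nothing but amino-acid
sequences and a list of known interactions.

## The method

The underlying hypothesis is classic: if P1′ is similar to P1, P2′ is
similar to P2, and (P1, P2) is a known interaction, then (P1′, P2′) is
more likely to interact. The pipeline makes that quantitative in four
stages:

1. **Similar subsequences.** Four spaced seeds of weight 5 and span 12
   (e.g. `11****11***1`) index every *s-mer* — the residues at the seed's
   `1` positions — of every protein. Occurrence pairs whose s-mers score
   `S_smer(w, z) = Σ_{s[i]=1} M(w_i, z_i) ≥ T_hit` under a substitution
   matrix `M` (PAM120 by default, bundled) are hits; each hit's centred
   k-mer pair (k = 20) is verified against `T_sim` and extended outwards
   while the terminal k-window pair keeps scoring `≥ T_sim`, yielding
   ungapped, equal-length similar region pairs.
2. **Repeat filtering.** Residue positions covered by ≥ T_hc similarity
   sides are eliminated everywhere (mirrored across each similarity's
   alignment) — they are promiscuous repeats, not interaction evidence.
3. **Scoring.** A region of length ℓ holds ℓ−k+1 length-k blocks, and
   `S_e(X, Y)` sums the scores of all corresponding k-mer pairs. Each
   known pair (P1, P2) adds, for each similarity (X1, Y1) linking P1 to
   Q1 and (X2, Y2) linking P2 to Q2,

       S_p(Q1,Q2) += [S_e(X1,Y1)(|X2|−k+1) + S_e(X2,Y2)(|X1|−k+1)] / (|Q1||Q2|)

   and all (N²+N)/2 candidate pairs are ranked by score.
4. **Evaluation.** Train/test splits stratify held-out pairs into C1, C2
   and C3 — both, one, or neither protein seen in training — with sampled
   negatives, ROC/PR areas, and sensitivity/precision/F1 at high
   specificity. C2/C3 performance is what generalizes to genuinely novel
   proteins.

Defaults: `k=20`, `T_hit=15`, `T_sim=35`, `T_hc=40`, PAM120.
See `docs/methods.md` for the assumptions and interpretation choices.

## Worked example

Simulate a small proteome with planted homology, then run the pipeline:

```sh
sprint simulate --spec spec.toml --seed 5 --out-dir data
# wrote 24 proteins, 10 training PPIs, 2 held-out PPIs to data
sprint similarities --fasta data/proteome.fasta --out sims.tsv
# wrote 13 similarities to sims.tsv
sprint filter --similarities sims.tsv --fasta data/proteome.fasta --out sims.filtered.tsv
# 13 similarities -> 13 after filtering (T_hc=40)
sprint score --fasta data/proteome.fasta --similarities sims.filtered.tsv \
             --train data/train.tsv --out scores.tsv
# wrote 22 scored pairs to scores.tsv
```

(`spec.toml` here used 24 proteins, four 3-member families with 30-residue
planted regions at 5% substitution, and two interacting family pairs.)
The top of `scores.tsv`:

```
id_a    id_b    score
P0002   P0005   254.532054
P0000   P0005   249.760988
P0002   P0003   249.726438
```

The highest scores go to members of the interacting families — the known
training pairs and their family siblings. The two held-out pairs, whose
proteins never appear in training, still score strictly positive through
similarity bridges (`P0007–P0010` at 55.5, `P0001–P0004` at 47.4), placing
them in the top 7% of all 300 candidate pairs while the hundreds of
unrelated pairs score 0. `sprint split` and `sprint evaluate` then produce
C1/C2/C3 datasets and ROC/PR / fixed-specificity reports for scored
predictions.

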