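# Methods

## Model and procedure

The package predicts protein–protein interactions (PPIs) from sequence
alone, under the standard transfer hypothesis: a pair of proteins that is
pairwise similar to a known interacting pair is itself more likely to
interact. The pipeline has four stages.

**1. Similar subsequence search (`similarity`).** For each spaced seed
(a pattern over `{1, *}`; default: the four weight-5, span-12 seeds
`11****11***1`, `1**1*1***1*1`, `11**1***1**1`, `1*1******111`), every
s-mer — the residues at the seed's `1` positions of a sequence window —
is recorded in a hash table. Two s-mers `w`, `z` score
`S_smer(w, z) = Σ_{s[i]=1} M(w_i, z_i)` under the substitution matrix `M`
(default PAM120); every unordered pair of occurrences with
`S_smer ≥ T_hit` (default 15) is a *hit*, covering both exact and
approximate spaced matches. Each hit is verified by scoring the two
k-mers (k = 20) that contain the s-mer occurrences centred,
`S_kmer(A, B) = Σ_i M(A_i, B_i)`; if that reaches `T_sim` (default 35)
the windows are extended outwards, one residue at a time on either side,
while the newly exposed terminal k-window pair still scores `≥ T_sim`.
Both sides grow in lockstep, so every similar region pair is ungapped,
equal-length, and lives on one diagonal `start_a − start_b`.

**2. Promiscuity filter (`postfilter`).** Positions covered by `≥ T_hc`
(default 40) similarity sides are treated as generic repeats: they are
removed from every similarity (removals on one side are mirrored onto the
aligned columns of the other) and the surviving columns re-emitted as
maximal contiguous segments. Counting and filtering are single-pass —
counts are not recomputed after splitting. Segments shorter than k are
retained; they simply contain no k-window and contribute zero downstream.

**3. Scoring (`scoring`).** A region of length ℓ contributes
`(ℓ − k + 1)+` length-k blocks. For equal-length sides,
`S_e(X, Y) = Σ_{i=1}^{n−k+1} S_kmer(X[i..i+k−1], Y[i..i+k−1])` (0 when
n < k). Every known interacting pair `(P1, P2)` then adds, for each
similarity `(X1, Y1)` linking `P1` to `Q1` and each `(X2, Y2)` linking
`P2` to `Q2`:

    S_p(Q1, Q2) += [S_e(X1,Y1)·(|X2|−k+1)+ + S_e(X2,Y2)·(|X1|−k+1)+] / (|Q1|·|Q2|)

Pairs are ranked by descending score (ties broken lexicographically by
ids; an optional threshold reports pairs scoring `≥` it). Over N proteins
an all-vs-all prediction considers `(N² + N)/2` pairs, self-pairs
included.

**4. Evaluation (`evalsplit`).** Positives are split at random into
training and test (default ratio 10:1); each test pair is classed C1/C2/C3
by whether both / one / neither of its proteins occurs in a training
pair — the harder classes indicate generalization beyond seen proteins.
Negatives are sampled uniformly from non-interacting, non-homo pairs
(default ratio 1:1, optionally under the same class constraint). Metrics
are ROC/PR curves and areas and sensitivity/precision/F1 at requested
specificities (default {0.95, 0.99}), computed with scikit-learn;
repeated splits with derived per-repeat seeds support averaging over
e.g. 40 replicates.

## Parameters

| name | default | meaning |
|------|---------|---------|
| `k` | 20 | block / verification window length (residues); must be ≥ the largest seed span |
| `T_hit` | 15 | minimum s-mer pair score (matrix units) to form a hit |
| `T_sim` | 35 | minimum k-window pair score for verification and extension |
| `T_hc` | 40 | coverage count at and above which a position is eliminated |
| matrix | PAM120 | any symmetric NCBI-layout matrix is accepted |
| seeds | 4 × weight 5, span 12 | lower weight raises sensitivity but multiplies random hits |

The elimination comparison is inclusive (`count ≥ T_hc`): the worked
repeat-filtering example removes positions whose counts are "5 or higher"
at threshold 5, which fixes the boundary semantics.

## Interpretation choices

These points are underdetermined by the method's published description and
were fixed as follows:

* **Extension stopping rule** — grow while the newly exposed *terminal*
  k-window pair scores `≥ T_sim`, the same gate used for verification.
  Equivalently: a region is the maximal run of consecutive qualifying
  k-window positions around the verified central window.
* **Window centring** — the central window starts at
  `occ.start − ⌊(k − span)/2⌋` (exact margin 4 for k=20, span=12).
  When it would overrun a sequence end it is shifted minimally *along the
  diagonal* so both windows fit and still contain the s-mer spans
  (`clip="shift"`, default); `clip="strict"` discards such hits instead.
* **Merging** — regions of the same protein pair on the same diagonal that
  overlap or touch merge into their maximal cover; different diagonals
  stay separate (the block sum assumes positionally aligned columns).
* **Intra-protein hits** — allowed at distinct positions (repeats must be
  countable by the promiscuity filter); the zero-offset self-hit is not.
* **Identity self-similarity** — each protein implicitly carries one
  full-length similarity with itself (disableable). Without it a known
  interacting pair with no computed similarities would score zero; with
  it, every training pair scores strictly positive, matching the
  intuition that known PPIs are the strongest predictions.
* **Unknown residues** — all non-standard letters collapse to one class
  `X`, scored by the matrix's wildcard row when present, else by the
  pessimistic matrix minimum. Unknown letters participate in s-mer keys.
* **Self-pairs in training** — a training pair (P, P) iterates the full
  cross product of P's incidence list with itself, exactly as the update
  formula reads.

## Numerical notes

* All window sums use exact integer arithmetic (cumulative sums of matrix
  values); the only floating-point step is the final normalized
  accumulation, which is order-independent addition of exact ratios — the
  quadruple-loop reference agrees to 1e−9 relative.
* Hit enumeration scores all distinct key pairs blockwise (int32,
  ~8 M cells per block) and is verified against brute-force evaluation of
  every occurrence pair; output is independent of traversal order.
* Score ties in ranked output are broken lexicographically by protein ids
  so runs are reproducible bytewise.

## Synthetic data

The generator plants detectable homology: i.i.d. uniform-background
sequences (a residue-frequency table can be supplied in principle, but
uniform is the default for simplicity), families sharing one planted
region copied into each member at a random offset with i.i.d.
substitutions, and interactions between designated family pairs. For each
interacting family pair, one member of each family is set aside: the pair
between the two set-aside members is held out and *their* other cross
pairs are dropped, so the held-out pair's proteins never occur in
training and the pair is recoverable only through similarity bridges
(a C3-type test case by construction). Mutations are substitutions only,
since the search is ungapped.

Defaults (100 proteins of 120–200 residues, eight 5-member families,
60-residue planted regions at 5% per-copy substitution, four interacting
family pairs, 10 background PPIs) are sized so family structure is
detectable at the default thresholds while most of the proteome stays
unrelated background. What passing tests show is that the implementation
recovers planted, ungapped, moderately diverged homology and transfers
interaction evidence across it; real proteomes add domain shuffling,
indels, low-complexity repeats and biased residue composition that the
generator deliberately omits, so synthetic recall does not predict
benchmark accuracy on curated PPI databases.

## Problem sizes

Tests and the acceptance script run the full pipeline on the 100-protein
default instance (5,050 candidate pairs), plus oracle checks on smaller
instances (20 proteins × 100 residues for hit-set equality; tiny
quadruple-loop instances for the accumulation). These sizes were chosen
as the smallest at which every pipeline stage — including the promiscuity
filter and rank-based recovery — is meaningfully exercised.

## Known limitations

* Ungapped, equal-length similarities only; no affine-gap extension.
* No probability calibration of scores; ranks, not probabilities.
* No sequence-identity clustering (CD-HIT-style) during dataset
  construction — callers supply pre-clustered data if they need it.
* The promiscuity filter is single-pass; an iterated fixed-point variant
  could eliminate more repeats but is not implemented.
* Accession mapping / database retrieval is out of scope; inputs are
  plain FASTA and two-column TSV.
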