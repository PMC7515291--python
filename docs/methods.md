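# Methods

This note documents the models, conventions and design decisions behind
`dpiscope`, in the order the pipeline runs.

## Data model and coordinates

All residue coordinates are 1-based with inclusive segment ends (the UniProt
convention), stated in every file header the package writes. Per-residue
tracks are stored sparsely as merged segment lists and expanded to 0/1
vectors on demand; the contract is positional equality, not storage form.
Proteins with a sequence but no annotation rows are legal (prediction-only
mode uses the sequence-feature functions only). Canonical set names are
`proteome, synaptome, psd, psc, immunome, nucleus, histone_methylases`,
with the nesting proteome ⊇ synaptome ⊇ PSD ⊇ PSC validated on load.
Ids outside the universe and nesting violations produce warnings, not
errors, because the upstream localization databases are noisy; "exclusive"
complements (e.g. the PSD-exclusive proteome, 21,766 − 1,761 = 20,005
proteins at the canonical sizes) are first-class, and both inclusive and
exclusive reference sets are supported in every comparison.

## Sequence features

Residues are partitioned into eight physicochemical groups (hydrophobic
AILMV, aromatic FWY, polar NQST, positive HKR, negative DE, rigid P,
flexible G, covalent C). Group fractions are computed over standard
residues only — nonstandard letters (X/B/Z/U) are excluded from numerator
and denominator, never imputed. Scale means are arithmetic means of
per-residue 20-value property tables.

Scale-collection reduction clusters standardized scales (each scale's 20
values to zero mean/unit variance, so shape rather than units drives the
distance) by Ward-linkage hierarchical clustering; the cluster count is the
elbow of the within-cluster sum of squares — argmax of the second forward
difference over the candidate k range — and one representative per cluster
is drawn uniformly under a stated seed. Standardization before clustering
is this package's choice, documented rather than inherited. The packaged
default scale set (`data/default_scales_synthetic.tsv`) contains five
*synthetic stand-in* tables spanning hydropathy, charge, size, flexibility
and aromaticity axes, so prediction-only mode works offline; any real scale
database in the same TSV layout can be substituted.

## Structural elements

Stringent disorder: consensus (AND) of the two disorder tracks, minus the
permissive union (OR) of the fibrillar tracks (two coiled-coil predictors,
single α-helix, collagen). "Longer than 10 residues" is read strictly:
qualifying IDRs and coiled coils have length ≥ 11; the threshold is a
parameter. TM helices and domains qualify at any length. Missing tracks
read as all-zero ("no prediction = absent").

Proteins are partitioned into twelve co-occurrence categories: the ten
conventionally reported ones (four single-element classes, IDR+CC, IDR+TM,
IDR+DOMAIN, IDR+CC+DOMAIN, all four, and ordered combinations without IDR)
plus two residuals (`idr_other_combo` for IDR+CC+TM and IDR+TM+DOMAIN, and
`none`), so the 16 flag combinations map to exactly one category each and
counts always sum to the set size. Proportions for a subset can be taken
against the subset size or against the exclusive-proteome denominator;
the exclusive denominator is the default for proteome-column reproduction.
Inter-domain linker lengths are the gaps between consecutive domain
segments, termini excluded. The residue-overlap audit reports the fraction
of covered residues claimed by two or more element kinds.

## DPI

`DPI = Σ ln(term)` over DOM, CC10, IDR10, TMH, Ph+Ub, ELM. The sum is
undefined whenever a term is zero, so the default convention evaluates
`ln(1 + x)` per term: DPI is 0 for a featureless protein, monotone
non-decreasing in every argument, and rankings among proteins with positive
counts are essentially unchanged. This is the package's largest
interpretive decision; it is recorded in every output header, and the raw
`ln(x)` variant (zero terms dropped) is available behind a flag. Per-set
DPI is the arithmetic mean of per-protein DPI.

## Statistics

* **Bootstrap enrichment**: 1000 replicates; each draws `sample_size`
  proteins *with replacement* from subset and reference and compares
  per-feature means by `ln(mean_sub / mean_ref)`. The sample size derives
  from the smallest set — 80% of the 51-protein PSC rounds half-up to 41
  (floor available). Replicates with a zero mean flag the feature as
  undefined rather than being dropped silently. Natural log throughout;
  the base shifts scale only, never significance calls.
* **Interval significance**: the largest k ∈ {1,2,3} at which the two
  mean ± k·SD intervals are disjoint maps to p < 0.32 / 0.05 / 0.01;
  overlap at k = 1 is "ns".
* **KS**: two-sample, two-sided, asymptotic p (sidedness was an open
  choice; two-sided is the conservative default).
* **Chi-square**: 2×2 above/below-threshold tables (threshold = proteome
  mean) with Yates continuity correction, 1 df; zero marginals raise.
* **Spearman**: average ranks for ties; the p-value is by exhaustive
  permutation enumeration for n ≤ 8 and the t-approximation above that.
  (Exact enumeration over n! permutations is the natural small-n choice but
  is infeasible beyond single digits; 8 covers the set-level use case of
  ~7 protein sets.)
* No multiple-testing correction is applied by default; a
  Benjamini–Hochberg helper can be layered by the user — an extension, not
  a default.

## Classifier

Redundancy filtering removes homologs incrementally at 90/70/50/40%
identity: at each threshold, greedy longest-first clustering discards any
sequence whose global-alignment identity (matches / alignment columns,
Needleman–Wunsch) to a kept representative reaches the threshold. Exact
alignment keeps this honest at desk scale (up to a few thousand
sequences); word-filter heuristics of large-scale tools are deliberately
not replicated.

Each of 10 bags holds all minority-class rows plus an equal-size uniform
sample of majority rows. Each bag trains one feed-forward network — one
hidden layer of 40 logistic units, logistic output, cross-entropy loss,
per-sample SGD, learning rate 0.01, up to 200 epochs with early stopping
(patience 10) on a 10% validation split — the smallest standard choice set
for a shallow net of this design. Features are standardized on training
rows only; the parameters travel with the network, so held-out rows never
leak into them. Training is bitwise-deterministic per seed, the per-epoch
loss curve is retained, and a non-finite loss raises a divergence error
naming the epoch.

Ensemble prediction is confidence-weighted: Σ wᵢpᵢ / Σ wᵢ with
wᵢ = |2pᵢ − 1|, so an abstaining network (p = 0.5) contributes nothing and
full abstention returns 0.5. Raw-probability weighting is available behind
a flag; the confidence form was chosen precisely because it nulls
uninformative networks. Bags are redrawn inside every cross-validation
fold, and aggregation weights are per-sample. Evaluation: MCC and balanced
accuracy at threshold 0.5, AUC by trapezoid over the exact ROC step
function (tied scores step simultaneously; AUC equals the Mann–Whitney
U-statistic normalisation, which the tests assert). Benchmarks: stratified
10-fold CV plus a 20% stratified hold-out taken before CV as the
independent set. Two feature modes mirror the two predictors: `all`
(every feature) and `intrinsic` (sequence-derivable only: length, group
fractions, scale means, predicted IDR/CC/TM/low-complexity/anchor counts).

## Synthetic proteome generator

The generator defines the study conditions; its defaults are fixed, not
tuned. Set sizes default to 21,766 / 1,891 / 1,761 / 51 (proteome /
synaptome / PSD / PSC) plus controls 834 / 180 / 52 (immunome / nucleus /
histone methylases), scalable by `size_factor` (floor 10 per set). Lengths
are log-normal (shape 0.7) with set means 524 / 705 / 970 residues
(proteome / PSD / PSC). Feature counts are negative-binomial
(dispersion 2 — overdispersed, matching the high per-feature variance such
data show) with proteome-baseline means and explicit per-set multipliers:
PSD-like sets gain coiled coils (×2.2), domains (×1.5), phosphorylation
(×2.5), ubiquitination (×2.0), interactions (×2.0) and isoforms (×1.5) and
lose TM helices (×0.6); IDR enrichment (×1.8) appears only in the
scaffold-like PSC profile; controls are a globular multidomain set, a
high-interaction nuclear set and a disorder-rich enzyme family. Synaptic
non-PSD proteins sit halfway to the PSD profile in log space.
`effect_scale` exponentiates every multiplier and attenuates the length and
composition differences identically, giving a continuous dial from a null
proteome (0) through the default conditions (1) to strongly separated sets
(2), used for the monotone-AUC property.

Residue composition targets ~25% charged / ~3% Cys / ~6% Pro
(proteome-like) vs ~28% / ~2% / ~5% (PSD-like), imposed on human-like
baseline frequencies with the remainder renormalised; group fractions and
scale means in the feature table come from multinomial residue counts at
the protein's length, and sequence strings (for the redundancy filter and
composition checks) are i.i.d. draws from the same distributions. Homolog
families can be planted at a stated identity by point-mutating a template.

Tracks realise the drawn counts as uniformly placed, non-overlapping
segments (length ranges: domains 40–120, TM 17–26, coiled coils 12–30,
IDRs 11–40, low-complexity 8–25 residues) with a 1-residue guard so
same-kind segments never merge; a configurable rate (default 0.005) lets a
segment ignore other kinds' occupancy, reproducing the sub-1% residue-level
cross-overlap observed in real predictor output. Segment-bearing counts are
capped so their expected footprint stays below 75% of the protein length
(the cap binds only for short, feature-dense proteins); genuinely
unplaceable requests raise a packing error. With overlap disabled and full
predictor agreement the element pipeline recovers the drawn counts exactly
(asserted in the closed-loop tests). The two disorder tracks each keep a
consensus residue with probability `disorder_agreement` (default 1).

The DPI–PPI coupling is a Gaussian copula: normal scores of DPI ranks
(random tie-break) are mixed with noise at Pearson parameter
2·sin(π·ρ/6) — so the induced Spearman correlation is the target ρ
(default 0.35) — and the existing interaction-degree values are reassigned
by latent rank within each stratum, preserving every stratum's marginal
exactly.

What the generator does *not* emulate: real sequence grammar (motifs,
domain order, local composition), between-feature correlations beyond the
DPI–PPI coupling and shared set effects, annotation noise or database
bias. Passing tests therefore demonstrate correctness of the pipeline's
computations and recoverability of planted structure — not that real PSD
proteins carry these exact effect sizes.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at reduced sizes (a few
hundred to a few thousand proteins; CV at ~2,400 proteins with a 450-strong
PSD) — the package's choice of desk-scale conditions under which the
planted effects remain comfortably detectable. Tolerances follow the
source of noise: exact equality for boolean/combinatorial oracles, ~1e-9
for closed-form statistics, sampling-based bands (binomial/SE arguments)
for stochastic recoveries. Degenerate inputs raise typed errors
(zero-variance ranks, single-class labels, zero marginals, empty sets)
rather than returning NaN.

## Known limitations

* The external structure/disorder/motif predictors are consumed as tracks
  or counts, never re-implemented; conclusions inherit their quality.
* Real-data headline values (AUC 0.84/0.76 etc.) require the original
  databases and are deliberately out of scope; the synthetic study
  reproduces the *structure* of those results (feature-mode ordering,
  correlation magnitudes), not their exact values.
* The redundancy filter's exact pairwise alignment is quadratic; use a
  dedicated clustering tool beyond a few thousand sequences.
* Exact permutation p-values are limited to n ≤ 8.
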