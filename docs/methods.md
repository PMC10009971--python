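# Methods

`ctfrag` implements a mutation-centric fragmentomic assay for detecting
circulating tumor DNA (ctDNA) in plasma cell-free DNA (cfDNA), of the kind
used to separate patients with early-stage hepatocellular carcinoma from
healthy controls on a deep targeted gene panel. This note records the model,
its assumptions, the numerical choices, and what the synthetic cohorts do
and do not establish.

## Background filtering of WBC-derived variants

Plasma cfDNA is dominated by DNA of hematopoietic origin, so most plasma
variant calls reflect clonal hematopoiesis or germline alleles also present
in white blood cells (WBC). Rather than sequencing a matched buffy coat for
every sample, the package models the pooled WBC variant allele frequencies
(VAF) as a zero-inflated beta distribution

    VAF = 0          with probability pi0,
    VAF ~ Beta(a,b)  otherwise.

`pi0` is estimated as the exact-zero fraction; `(a, b)` by maximum
likelihood on the strictly positive VAFs (L-BFGS-B on log-shapes, analytic
digamma gradient, method-of-moments start, tolerance 1e-8). Positive VAFs
are clipped to `[1e-9, 1-1e-9]` before taking logs.

A plasma call with allele depth AD out of DP is scored by the upper tail of
the compound background law, a point mass at zero mixed with a
beta-binomial:

    p = P(X >= AD | DP) = (1 - pi0) * SF_BetaBinom(AD - 1; DP, a, b),

with `p = 1` when `AD = 0`. Deeper sequencing therefore makes the test more
discriminating, and `p` is non-increasing in AD at fixed DP. Variants with
`p < alpha` (strict; default `alpha = 0.05`) are **LB-unique** — candidate
tumor-derived or benign-somatic calls — and the rest are **LB-share-WBC**.
The p-value is one-tailed (upper tail): only an *excess* of alternate reads
relative to the hematopoietic background is evidence against WBC origin.
One pooled background is fitted over all WBC samples; per-site error models
are out of scope.

Calibration: when variants are drawn from the fitted background itself, the
LB-unique rate at `alpha = 0.05` is ~0.046 rather than exactly 0.05 — the
beta-binomial tail is discrete, so the test is slightly conservative.
P-values are uniform to within KS < 0.02 below ~0.2; above that the `AD = 0`
convention introduces a deliberate conservative atom.

## Fragmentomic features

Mononucleosomal cfDNA peaks near 166 bp; tumor-derived fragments run
shorter (~150 bp and below). Only fragments with template length in
[100, 250] bp are used — 151 integer sizes. Fragments overlapping a
retained variant are labeled ALT (mutation-bearing) or REF. Features are
computed per sample on the *pooled* fragments of all retained LB-unique
variants with VAF < 0.1 (strict); pooling, not per-variant averaging,
matches the aggregation the assay is built on. Seventeen values per sample:

1. **f1 — short/long ALT ratio.** `count(length <= 150) / count(length >
   150)` over ALT fragments. The boundary is a config knob; "short" is
   inclusive of 150 so every fragment is counted exactly once. A sample with
   no long ALT fragments gets a clamped denominator of 1 (logged).
2. **f2 — size-selection enrichment.** One-tailed Fisher exact test for ALT
   over-representation in the 110–135 bp window against REF, on the 2x2
   table (REF in/out, ALT in/out); reported as the PHRED-scaled p-value
   `-10*log10(p)`, capped at 300 to keep the feature bounded under
   numerical underflow. Sidedness is configurable; the one-tailed default
   reflects that only ALT enrichment in the short window is evidence of
   tumor origin. Note a perfectly balanced table has a one-tailed p of
   ~0.67, not 1: the PHRED feature is small but nonzero in the null.
3. **f3 — windowed size likelihood ratios.** With add-one (Laplace)
   smoothing on the per-size counts of each class, `lambda(s) =
   P(len=s|ALT) / P(len=s|REF)`; f3 is the sum of `lambda(s)` over 15
   non-overlapping 10-bp windows covering s = 100..249 (s = 250, the
   incomplete trailing window, is dropped — the only layout that produces
   the 15-dimensional vector from 151 sizes). Smoothing keeps lambda finite
   and makes identical ALT/REF distributions give exactly 10.0 per window.

A genome-wide diagnostic, the per-5-Mb short/long count ratio
(short = 100–150, long = 151–250 bp, autosomes only, `ceil(L/5Mb)` bins per
chromosome, zero-long bins flagged as missing rather than infinite), is
provided for cohort-level fragment profiles but does not enter the
classifier.

## Classification and evaluation

Gradient-boosted trees (XGBoost, `tree_method="exact"`) on the N x 17
matrix. Exact splits are used deliberately: histogram bin edges can sit on
a cluster boundary and misclassify held-out points at these sample sizes.
Every fit uses class-balancing sample weights so that removing one sample
during leave-one-out cross-validation (LOOCV) does not shift the effective
class prior — the classical source of pessimistic bias that pushes
permutation-null LOOCV AUC below 0.5. With weighting, the permutation null
is centered (mean over 20 permutations ~0.498 at N = 110).

Hyperparameters come from a grid search (depth {2,3}, learning rate
{0.1,0.3}, rounds {50,100}) nested *inside* each training fold via inner
stratified 5-fold CV on AUC; the held-out sample and the validation cohort
never influence selection. The ROC curve sweeps the unique out-of-fold
scores (positive call: score >= threshold, inclusive); AUC is the
trapezoidal integral, which equals the normalized Mann-Whitney U statistic
including under ties. The operating threshold maximizes Youden's
J = sensitivity + specificity - 1, ties broken toward the higher cut
(higher specificity), with a 1e-12 tolerance absorbing float jitter between
mathematically tied J values. External validation fits once on the full
discovery cohort and scores the validation cohort at the frozen threshold —
no refitting or rethresholding.

Group comparisons of individual features use a one-tailed Mann-Whitney U
test (cancer > healthy): exact enumeration over all group assignments for
n1 + n2 <= 12 (ties get half credit), normal approximation with tie and
continuity correction otherwise.

## Synthetic cohorts

The raw study data are not public, so the generator reproduces the
*statistical structure* of the study and carries truth labels:

* Design scale: 55 cancer + 55 healthy discovery plasma samples paired 1:1
  with 110 WBC samples; 54 + 53 validation samples (unpaired); ~73 plasma
  variants per sample (the study's median), of which ~41% are WBC-shared.
* WBC background: `pi0 = 0.6`, positive VAFs `Beta(0.3, 20)`
  (mean ~1.5%, heavy right tail). Depth is lognormal with median 500x
  (UMI-consensus coverage scale), floored at 50x; recorded AD is binomial.
  The heavy tail is load-bearing: with a tighter beta, binomial depth noise
  at 500x alone caps the recorded-VAF correlation near 0.90.
* Shared-variant coupling: plasma latent VAF = logistic(logit(WBC latent
  VAF) + N(0, 0.15)). The noise SD is a documented constant tuned once so
  the pooled per-variant recorded-VAF Pearson r lands at ~0.95; the
  per-sample-mean correlation (the quantity a paired-sequencing comparison
  would plot) comes out at ~0.95 as well.
* Unique variants: `Beta(5, 45)` VAFs (mean ~0.1). In cancer samples 35%
  of non-shared variants are tumor-derived (`tumor_fraction`), resampled
  below the 0.1 feature ceiling; the rest, and all non-shared variants in
  healthy samples, are benign somatic calls. Called variants get
  `AD = max(1, Binomial(DP, VAF))` — a called variant has at least one
  supporting read.
* Fragment lengths: discretized truncated-normal laws on [100, 250]
  (pmf proportional to the normal density at each integer size). REF and
  non-tumor ALT fragments: mode 166, sd 9. Tumor-variant ALT fragments: a
  mixture with weight 0.7 on a mode-150, sd-8 component and 0.3 on the
  reference law. With the 150 and 166 modes only 16 bp apart, a flatter or
  lighter-weight tumor component merges into a single mode near 157; the
  chosen mixture has its histogram mode at 150, matching the left-shifted
  ALT profile the assay exploits. Per-variant fragment counts are
  ALT ~ Poisson(AD), REF ~ Poisson(DP - AD), keeping VAF and fragment
  support coherent.
* Seeding: one master seed; WBC, discovery, and validation cohorts consume
  independent spawned streams, so the validation cohort is independent in
  the sense an external cohort is, while remaining reproducible from a
  single integer.

With these defaults the synthetic study lands near the structure it
emulates: LB-unique share ~60% of plasma calls, background-partition
concordance with truth ~0.92, shared-VAF correlation ~0.95.

## What the synthetic experiment does and does not show

The generator reproduces marginal and joint *distributions* — it contains
no sequencing-error model, no per-site mutation spectrum, no batch or
center effects, no age/sex structure, and no biological variation in tumor
fragment-length shift between patients. Consequently the classifier
separates the synthetic classes more cleanly (LOOCV AUC 0.98–1.0 across
seeds) than any
real cohort of this size would (real-data AUCs for assays of this design
are in the 0.85–0.90 range). Passing tests therefore establish that the
pipeline is correct and well-calibrated — background type-I error at the
nominal level, features that respond monotonically to the planted effect,
leakage-free evaluation with a centered permutation null — not that any
particular clinical performance would be attained on real samples.

## Problem sizes and runtime choices

Default test and acceptance runs use the full design scale (110 + 107
plasma samples, ~16k plasma variants, ~8M fragment records) — a few
minutes on one CPU. The hyperparameter grid is intentionally small
(config-exposed) and the permutation null uses 20 permutations with fixed
first-grid hyperparameters; these are desk-scale analysis choices, and all
knobs accept larger values.

## Known limitations

* The background model is pooled, not per-site; it cannot separate a
  recurrent artifact at one locus from genuine signal.
* The p-value's `AD = 0 -> p = 1` convention makes the null distribution
  conservative above ~0.2; only the rejection region is calibrated.
* Variant keys in the generator are synthetic identifiers; no real genomic
  coordinates or panel content are modeled.
* `vaf_correlation` requires variation in both lists; cohorts in which all
  shared variants have identical VAFs are rejected rather than reported as
  r = NaN.
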