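# ctfrag

Fragment-length analysis of plasma mutations for circulating tumor DNA
(ctDNA) detection.

Mutation-based liquid biopsy is confounded by the fact that most plasma
cfDNA variant calls are of white-blood-cell (WBC) origin — clonal
hematopoiesis and germline alleles — and that tumor-derived mutations
overlap benign somatic mutations found in healthy people. `ctfrag`
implements the analysis chain that works around both problems for a deep
targeted panel:

1. **WBC background filtering.** Pooled WBC VAFs are modeled as a
   zero-inflated beta: a point mass π₀ at zero plus Beta(a, b) over positive
   frequencies. A plasma call with allele depth AD of total depth DP gets an
   upper-tail p-value under the compound background law

       p = (1 − π₀) · SF_BetaBinom(AD − 1; DP, a, b),   p = 1 at AD = 0,

   and calls with p < 0.05 are kept as *LB-unique* (candidate tumor origin).
2. **Fragmentomic features** per sample, over pooled fragments (100–250 bp)
   of LB-unique variants with VAF < 0.1, split into mutation-bearing (ALT)
   and reference (REF) reads:
   * **f1** — ratio of short (≤150 bp) to long (>150 bp) ALT fragments;
   * **f2** — PHRED-scaled one-tailed Fisher exact p for ALT enrichment in
     the 110–135 bp window versus REF;
   * **f3** — sums of λ(s) = P(len=s|ALT)/P(len=s|REF) over 15
     non-overlapping 10-bp windows (add-one smoothed).
3. **Classification.** Gradient-boosted trees on the N×17 matrix, evaluated
   by leave-one-out cross-validation with a nested hyperparameter grid
   search, ROC/AUC, a Youden-index operating threshold, and frozen-threshold
   scoring of an independent validation cohort.

Because the underlying patient data are not public, the package ships a
first-class synthetic-cohort generator that reproduces the study's
statistical structure (cohort sizes 55+55 and 54+53, ~73 variants per
sample with ~41% WBC-shared, shared-VAF correlation ~0.95, 166 bp reference
vs 150 bp tumor fragment modes) with per-variant truth labels, so every
stage is testable end to end. See `docs/methods.md` for the model details
and what the synthetic experiments do and do not show.

## Worked example

```python
from ctfrag import RunConfig, run_pipeline

metrics = run_pipeline(RunConfig(rng_seed=1, out_dir="demo_out"))
print(round(metrics["discovery"]["auc"], 3),
      round(metrics["validation"]["auc"], 3),
      round(metrics["wbc_model"]["concordance"], 3),
      round(metrics["wbc_model"]["shared_vaf_pearson_r"], 3))
```

prints (a few minutes on one CPU):

```
1.0 1.0 0.917 0.951
```

i.e. on the default synthetic study the 17-feature model separates the
classes completely in both cohorts; the background filter agrees with the
generator's truth labels for 91.7% of plasma variants, and per-sample mean
VAFs of truly shared variants correlate at r = 0.951 between plasma and
matched WBC. (The AUC is higher than a real cohort of this design would
give — synthetic data lack biological nuisance variation; see
`docs/methods.md`.)
`demo_out/` then holds `features.tsv` (one row per sample: `sample_id`,
`label`, `f1`, `f2`, `f3_01…f3_15`), `metrics.json`, and the serialized run
configuration.

The same pipeline is scriptable from the shell:

```sh
ctfrag simulate --seed 1 --out cohort/
ctfrag filter-wbc --variants cohort/variants.tsv --out filtered/
ctfrag run-all --seed 1 --out full_run/
```

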