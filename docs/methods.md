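# Methods

## Synthetic cohort model

The cohort generator emulates a pooled PDAC cohort (TCGA plus two ICGC
studies) at the patient-profile level: driver-mutation statuses, survival
outcome, and basic covariates.

**Mutation statuses.** KRAS and TP53 are independent Bernoulli draws at
their marginal frequencies (defaults 0.9043 and 0.6913, the observed
cohort values; SMAD4 0.2321, CDKN2A 0.2066).  SMAD4 and CDKN2A are linked
to TP53 through a logistic model
`P(mut | TP53 status) = sigmoid(b + δ·TP53)` with a single co-occurrence
log-odds δ shared by both genes (default 1.5).  The intercept b is solved
numerically (Brent's method) so that the mixture marginal equals the
target frequency exactly — co-occurrence strength and marginal frequency
are therefore independent knobs.  One mutation row is emitted per mutated
gene per patient (no multi-hit modelling), always in the exon region,
with effect classes drawn as 70% nonsynonymous / 15% stopgain / 15%
frameshift for realism; effect class carries no signal.

**Survival.** Exponential proportional hazards: the per-patient hazard is
`baseline_hazard × HR_TP53^tp53 × HR_SMAD4^smad4 × HR_CDKN2A^cdkn2a`,
with independent exponential censoring at rate `censor_rate`.  This is
the simplest generative model under which log-rank and Cox parameter
recovery are exactly testable.  KRAS carries no hazard parameter: it is
the near-universal background mutation whose role in the analysis is
stratification, not effect size.  Time is in months; the defaults
(`baseline_hazard` 0.035/month ≈ 20-month median survival in the
reference stratum, `censor_rate` 0.02/month) give event fractions around
60–70%, typical of resected-PDAC follow-up.  The default effect
configuration — TP53 HR 2.0, SMAD4/CDKN2A HR 1.0, δ = 1.5 — plants the
confounded-null structure the contrast battery is designed to dissect:
SMAD4/CDKN2A are marginally associated with survival only through their
co-occurrence with TP53.  No published effect sizes exist for these
contrasts (the source curves are not accompanied by hazard ratios), so
these are study conditions, not estimates.

**What the generator does not emulate:** batch structure between source
cohorts, tumor purity, panel-vs-WGS ascertainment differences,
non-proportional hazards, informative censoring, and correlation between
mutation status and age/gender.  Passing tests therefore demonstrate the
statistical machinery's correctness and calibration under a clean
generative model, not robustness to these real-data artifacts.

## Expression and DEG benchmark

Expression is log-normal: per-gene baseline log2 means ~
N(`baseline_log2_mean`, `baseline_log2_sd`), i.i.d. Gaussian log2 noise
per sample (default sd 0.3), dropout zeros injected uniformly at rate
`frac_zero`.  The planted family's mean log2 expression is shifted by
`family_shift_log2` (default 2, i.e. 4-fold) in TP53-mutant samples.

The DEG benchmark adds two constructed boundary sets: genes positive in
*exactly* 20% of samples (the expressed-gene filter requires strictly
more than 20%, so these must be removed, and any correct implementation
removes exactly these) and genes with group means below 5 in both groups.
Baseline means in the benchmark are clipped at log2 ≥ 3.5 so no ordinary
gene can stray under the minimum-level threshold.

**Threshold readings.** "More than 0 in over 20% of samples" and
"below 5 in both groups" are read as strict inequalities; the group-level
summary for the minimum-level rule is the group mean.  The t-test is the
classical equal-variance two-sample test computed on log2(x+1) (variance
stabilisation; the pseudocount keeps zeros finite), while the fold change
is computed from raw group means with pseudocount 1 — the standard
combination for normalized expression matrices.  No multiple-testing
correction is applied: the DEG definition is the raw-P threshold pair
(P ≤ 0.05, |log2FC| ≥ 1).  Rank-based DEG callers are not reimplemented;
their output lists are consumed as files.

## Survival statistics

Kaplan–Meier estimation, the Mantel–Cox log-rank test (hypergeometric
variance at ties) and Cox partial-likelihood fits are delegated to
lifelines.  The median survival time is the first time the curve reaches
0.5 or below, and is reported as undefined (None) when never reached
rather than as the maximum follow-up.  Per-variable significance in the
multivariate Cox model is a sequential likelihood-ratio test (each
covariate against the model containing those listed before it, df = the
number of terms it contributes), mirroring a sequential
analysis-of-deviance table.  The driver-mutation count covariate enters
as an integer 0–4 by default; a categorical coding is available by
casting the column before the fit.

The contrast battery reports raw log-rank P values — no multiplicity
correction across its 13 contrasts, since each contrast answers a
distinct planned question.  Patients not matching a stratum (e.g.
TP53-mutant without KRAS in the KRAS-background contrasts) are simply
outside both arms of that contrast; the marginal and TP53-excluded
contrasts ignore KRAS entirely.  Contrasts with an empty arm degrade to
"not evaluable" instead of raising, so an all-wildtype cohort yields a
complete, fully annotated battery.

## Family enrichment

The contingency table for one (DEG list, family) pair is
a = |DEGs ∩ family|, m = |family ∩ background|, k = |DEGs|,
N = |background|, after dropping (with a logged warning) DEGs outside
the background.

Three statistics are computed per pair:

- **Fisher's exact test**, two-sided, on
  `[[a, m−a], [k−a, N−m−(k−a)]]`; the sample odds ratio
  `a(N−m−k+a)/((m−a)(k−a))` with the conventions 0 at a=0 and ∞ when the
  denominator vanishes with a>0; the reported CI is the exact conditional
  (noncentral-hypergeometric) interval.
- **Enrichment ratio** `(a/m)/((k−a)/(N−m))`: the DEG rate inside the
  family relative to outside.  This is the statistic that reproduces the
  published Fisher-side OR cells from their printed counts to within
  0.3%, which neither the sample OR nor the conditional MLE does; it is 0
  at a=0 and ∞ when every DEG is in the family.
- **Permutation test**: each of `reps` (default 10⁶) simulated DEG sets
  draws k genes uniformly without replacement from the background.
  Because only the family-overlap count matters, the draw is implemented
  as a hypergeometric sample of that count — mathematically identical to
  sampling k-subsets and orders of magnitude faster; a literal
  subset-sampling mode is retained and tested against it.  The
  Monte-Carlo P is the raw `count/reps` (not `(count+1)/(reps+1)`): the
  raw estimator is what makes a "< 1/reps" bound reportable when no draw
  reaches the observed count, and zero counts are reported exactly so.
  The permutation OR is `a / mean(counts)`, converging to `aN/(km)`, with
  CI `(a/(mean+1.96·se), a/(mean−1.96·se))` where se is the standard
  error of the simulated mean.  The default tail is one-sided toward
  enrichment; depletion is available via `alternative="less"`.

One published inconsistency is deliberately not modelled: the
t-test-side permutation ORs in the source table imply an effective
background different from the printed N = 11789 (the recomputed values
are ~3–4% lower), whereas the larger-background side is fully consistent
with its printed N = 16859.  The comparisons against published
permutation values therefore use the consistent side only.

## qPCR fractions

Ct replicates are averaged per amplicon before ratioing; amplification
efficiency is fixed at 2.0 per cycle (100%), configurable per call.  Each
primer-pair label denotes the single amplicon amplified by that primer
pair, so each component ratio is one unprocessed amplicon quantity over
one total amplicon quantity, and the species fraction is the arithmetic
mean of its two component ratios.  The fraction is a within-sample ratio
and is invariant to any additive Ct shift (input-amount differences);
with Gaussian Ct noise the estimator is unbiased on the log2 scale.
Group comparisons divide each sample's fraction by the control-group mean
within species.  The direction of a treatment effect is reported, not
asserted: the module makes no claim about whether a given perturbation
should raise or lower the unprocessed fraction.

## Pipeline and reproducibility

All tables are TSV with a fixed float format; the orchestrated
`full-run` derives one deterministic sub-seed per stage from the root
seed and writes a JSON manifest with sha256 checksums of every output, so
reruns with the same configuration are byte-identical and silent changes
are detectable.  Permutation reps below 1000 are rejected at
configuration time.

## Problem sizes used in the test suite

The statistical checks run at sizes chosen to make their assertions
sharp while keeping the suite fast: marginal-frequency and co-occurrence
checks at n = 5000–8000 patients (3 binomial SDs); the
confounding-dissection check at n = 3000 patients × 50 seeds; log-rank
type-I calibration at 1000 null simulations of 60 + 60 subjects; Cox CI
coverage at 100 cohorts of n = 2000; DEG recovery at 2000 genes × 100
samples; permutation convergence at 10⁵–10⁶ draws; Fisher-vs-enumeration
equivalence on 200 random tables with N ≤ 60.

## Known limitations

- The exponential survival model cannot probe proportional-hazards
  violations; the Cox and log-rank implementations are only validated
  under proportionality.
- The enrichment engine is annotation-agnostic: it consumes any GMT file
  and performs no ontology-aware correction for gene-set overlap.
- Published cohort-level quantities (the real cohorts' DEG counts,
  mutation percentages, and survival P values) depend on patient-level
  data that is not redistributable; they are covered by parameter-recovery
  and calibration surrogates on planted data, not reproduced.
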