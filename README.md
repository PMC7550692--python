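# pdacdriver

Which of the four recurrently mutated PDAC driver genes — *KRAS*, *TP53*,
*SMAD4*, *CDKN2A* — actually carries the prognostic signal?  Because most
pancreatic ductal adenocarcinoma patients carry two or more of these
mutations at once, a gene that merely co-occurs with the true driver of
poor survival will look prognostic in a marginal comparison.  `pdacdriver`
implements the analysis chain that untangles this: mutation-exclusive
survival stratification, thresholded differential expression between
*TP53* groups, gene-family over-representation statistics for snoRNA
families, and qPCR-based quantification of unprocessed ribosomal RNA —
together with a synthetic-cohort generator that plants known structure so
every stage is testable without patient-level data access.

It is written for biostatisticians and computational biologists who want
the statistical machinery of this kind of driver-gene dissection as a
reusable, tested library with a CLI.

## The statistics at the core

**Mutation-exclusive survival contrasts.** Patients are assigned to exact
driver-status strata (e.g. *KRAS*-only = *KRAS* mutant and the other three
wildtype). The contrast battery compares, by Kaplan–Meier curves and the
Mantel–Cox log-rank test: KRAS-only vs no-driver; each KRAS+X-only
stratum vs KRAS-only; each co-mutation combination vs KRAS-only; and the
marginal SMAD4/CDKN2A contrasts both on all patients and after excluding
*TP53*-mutant patients.  If SMAD4/CDKN2A significance disappears under
TP53 exclusion while the TP53 contrast stands, the TP53 mutation is the
real prognostic factor.  Multivariate Cox proportional-hazards fits with
sequential likelihood-ratio significance per covariate complete the
picture.

**Family enrichment.** For a gene family of size m in an N-gene
background with k DEGs of which a fall in the family:

- Fisher's exact test on `[[a, m−a], [k−a, N−m−(k−a)]]` with an
  exact-conditional OR confidence interval;
- the enrichment ratio `(a/m) / ((k−a)/(N−m))` — the DEG fraction inside
  the family over the DEG fraction outside it;
- a random-sampling permutation test: 10⁶ draws of k genes without
  replacement from the background; `P = #{draws with family count ≥ a}/reps`,
  `OR = a / mean(simulated counts)` with a CI from the standard error of
  that mean.

**DEG calling.** Genes expressed (value > 0) in more than 20% of samples
and with mean level ≥ 5 in at least one group are tested with a
two-tailed Student t-test on log2(x+1); DEGs have P ≤ 0.05 and
|log2FC| ≥ 1.

**Unprocessed rRNA fractions.** With amplicons over precursor-only spacer
regions ("unprocessed") and regions common to all transcripts ("total"),
each ratio is `2^(Ct_total − Ct_unprocessed)` and the per-species
unprocessed fraction is the mean of its two amplicon ratios
(pairs 4/3 and 6/5 over 2/1 for 18S; d/c and f/e over b/a for 28S).

## Worked example

The numbered drivers under `analysis/` run each stage on synthetic data
and on the published contingency counts, writing tables under `results/`.

```bash
python analysis/02_survival_battery.py
```

prints (n = 3000 synthetic patients; planted hazards: TP53 HR 2.0, SMAD4
and CDKN2A HR 1.0 but linked to TP53 with log-odds 1.5):

```
  KRAS+TP53_only_vs_KRAS_only                n=  939/  708  P=8.46e-28
  KRAS+SMAD4_only_vs_KRAS_only               n=   59/  708  P=0.477
  ...
  SMAD4_vs_wt_all                            n=  698/ 2302  P=4.14e-06
  SMAD4_vs_wt_TP53_excluded                  n=   75/  867  P=0.429
  TP53_vs_wt                                 n= 2058/  942  P=4.03e-45
```

SMAD4 looks strongly prognostic marginally (P ≈ 4e-06) purely because it
co-occurs with TP53; once TP53-mutant patients are excluded the contrast
is null (P = 0.43) — the confounding mechanism the battery is built to
expose.

```bash
python analysis/04_family_enrichment.py
```

recomputes the family table from the published counts; e.g. for the box
H/ACA snoRNA family against the rank-based DEG list (a=4, m=48, k=90,
N=16859) it prints Fisher P = 1.23e-04, enrichment ratio 16.29, and a
permutation OR of 15.58 (CI 15.52–15.64) at 10⁶ draws — the family is
~16-fold over-represented among the DEGs.

The same pipeline is scriptable end to end:

```bash
pdacdriver full-run --seed 1 --out runs/demo
pdacdriver enrich run --degs degs.txt --gmt families.gmt \
    --background genes.txt --reps 1000000 --seed 1 --out enrichment.tsv
```

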