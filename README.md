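# tmbstrat

A tested, reusable pipeline for combined **tumor mutational burden (TMB)**
and **PD-L1** biomarker analysis in non-small cell lung cancer (NSCLC)
cohorts. It is aimed at translational researchers and biostatisticians who
have targeted-panel sequencing of paired tumor/normal samples plus PD-L1
immunohistochemistry, and who want to reproduce a combined-biomarker
survival stratification end to end — including on fully synthetic cohorts
with known ground truth.

## What it computes

1. **Paired somatic filtering.** Candidate variants (VCF, with tumor and
   normal ref/alt and strand counts, plus annotation fields) pass a fixed
   filter chain: coverage minima (normal ≥ 8×, tumor ≥ 6×); a one-sided
   exact test on the 2×2 allele-count table, calling a site somatic at
   p ≤ 0.05; a strand-bias rule (majority-strand fraction of tumor alt
   reads must be < 0.90); restriction to coding, on-panel sites; and
   germline/benign exclusions (population-database count ≥ 2, known-germline
   flag, zygosity call, deleteriousness score < 0.452 for missense). Every
   rule is evaluated for every variant, giving a complete per-variant audit
   trail.
2. **TMB.** TMB = retained mutations / panel coding territory (Mb),
   synonymous variants included by default. The cohort is trichotomized
   data-adaptively: High at TMB ≥ median + SD, Low below median − SD/2
   (floored at 0), Moderate between; the dichotomized view collapses
   Low/Moderate.
3. **PD-L1 scoring.** SP142-style ladders: TC3 ≥ 50%, TC2 5 to < 50%,
   TC1 ≥ 1 to < 5%, TC0 < 1% on tumor cells; IC3 ≥ 10%, IC2 ≥ 5 to < 10%,
   IC1 ≥ 1 to < 5%, IC0 < 1% on immune-cell tumor area. Category 0 is
   negative; any+ is positive; grades are negative/weak/moderate/strong.
4. **Combined stratification.** Dichotomized TMB × TC positivity gives
   four classes (LM_neg, LM_pos, H_pos, and the explicit H_neg), with Venn
   overlap summaries under both subgroup and whole-cohort normalizations.
5. **Statistics.** Kaplan–Meier estimates (Greenwood log-log 95% CI,
   median = smallest t with S(t) ≤ 0.5), Mantel–Haenszel log-rank,
   Pearson chi-square / Fisher's exact with the expected-count-below-5
   switch, Spearman rank correlation (exact p for n ≤ 9), tie-corrected
   Kruskal–Wallis with Dunn's pairwise comparisons. All tests two-sided.
6. **Synthetic cohorts.** A generator emulating all inputs — capture panel,
   per-patient paired variant evidence (somatic/germline mixture,
   negative-binomial depths, strand artifacts), per-histology PD-L1
   category mixtures, and exponential survival with per-class hazards —
   with ground-truth labels for every quantity the pipeline estimates.

## Worked example

```python
import tmbstrat as ts

cfg = ts.CohortConfig(n_patients=60, seed=7)
cohort = ts.generate_cohort(cfg)

retained, audit = ts.filter_cohort(cohort.variants, ts.FilterConfig(), cohort.panel)
print("variants:", len(audit), "kept:", int(audit["kept"].sum()))

tmb = {p: ts.compute_tmb(v, cohort.panel, patient_id=p).tmb
       for p, v in retained.items()}
cut = ts.derive_cutoffs(tmb.values())
print(f"cutoffs: low={cut.low_cutoff:.2f} high={cut.high_cutoff:.2f}")

df = cohort.clinical.assign(tmb=cohort.clinical["patient_id"].map(tmb))
report = ts.run_full_analysis(df, seed=7)
for cls, row in report["survival"]["ADC"]["by_combined_class"].items():
    print(cls, row)
```

prints

```
variants: 1703 kept: 677
cutoffs: low=3.93 high=13.56
H_pos {'n': 4, 'events': 3, 'median_os_months': 7.95...}
LM_neg {'n': 23, 'events': 21, 'median_os_months': 36.27...}
LM_pos {'n': 14, 'events': 11, 'median_os_months': 13.07...}
logrank {'statistic': 10.02..., 'p': 0.0066..., 'df': 2}
```

The filter chain kept 677 of 1703 candidates (the rest are simulated
germline variants, strand artifacts, off-panel or benign calls); the
median + SD / median − SD/2 rule put the High cutoff at 13.56 mut/Mb; and
the combined classes recover the planted survival separation — patients
with Low/Moderate TMB and negative PD-L1 ("responders" to
chemotherapy/targeted therapy) live markedly longer (median ≈ 36 months)
than PD-L1-positive or TMB-high patients (medians ≈ 13 and 8 months),
log-rank p ≈ 0.007.

The same pipeline is available from the shell:

```bash
tmbstrat simulate --seed 7 --out cohort/
tmbstrat filter --panel cohort/panel.bed --vcf-dir cohort/vcf --out filtered/
tmbstrat tmb --audit filtered/audit.tsv --panel cohort/panel.bed --out tmb/
tmbstrat score --clinical cohort/clinical.csv --out scores/
tmbstrat all --seed 7 --out run/       # everything in one go
```

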