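# Methods

## Scope and model

`tmbstrat` implements a combined TMB + PD-L1 biomarker workflow for NSCLC
cohorts profiled with a targeted capture panel and SP142-style PD-L1
immunohistochemistry. The pipeline runs in five stages — paired somatic
filtering, panel-normalized TMB with data-adaptive trichotomization, TC/IC
PD-L1 scoring, combined-class stratification, and survival/association
statistics — and ships a synthetic cohort generator whose ground truth
makes every stage testable without patient-level data.

## Somatic filter chain

A candidate variant carries paired tumor/normal ref/alt read counts,
tumor strand counts for alt-supporting reads, and four annotation fields
supplied by upstream annotation (the package does not compute them):
a consequence class, a population-database observation count, a
known-germline flag, a somatic/germline/ambiguous zygosity call, and a
deleteriousness score in [0, 1] (defined for missense only).

Rules, evaluated in fixed order and **without short-circuiting** so the
audit log lists every failed rule:

1. coverage: normal depth ≥ 8, tumor depth ≥ 6 (both configurable; the two
   minima attach to normal and tumor respectively);
2. somatic evidence: one-sided Fisher exact test on the 2×2 table
   (tumor/normal × alt/ref), alternative "tumor alt fraction greater";
   called somatic at p ≤ 0.05 (inclusive by default, both the threshold
   and inclusivity configurable; two-sided variant available). A
   zero-depth sample makes the site uncallable and the rule fails;
3. strand bias: fraction of tumor alt reads on the majority strand must be
   **strictly below** 0.90 — this is the only reading under which "kept"
   is a pass criterion. Variants with no alt reads or missing strand
   counts are unassessable and fail by default (configurable pass);
4. coding territory: consequence must be coding and the position on-panel;
   synonymous variants count toward TMB by default
   (`count_synonymous_for_tmb=False` excludes them, audit tag
   `synonymous`) — counting them reduces sampling noise on small panels;
5. germline exclusions: population-database count ≥ 2; known-germline
   flag; zygosity call "germline" ("ambiguous" passes);
6. benign exclusion: missense with deleteriousness score < 0.452. The
   score is undefined for other consequence classes, which pass this rule
   vacuously.

Monotonicity holds by construction: tightening any threshold can only
shrink the retained set. No multiple-testing correction is applied across
sites. Coordinates: BED intervals are 0-based half-open, VCF positions
1-based; the conversion lives in exactly one place
(`PanelDefinition.contains`).

## TMB quantification and cutoffs

TMB = retained mutation count / coding territory in Mb, exactly; each alt
allele passing filters counts once (multi-allelic sites contribute one
count per retained allele). Cohort cutoffs are derived on the **pooled**
cohort (both histologies): high = median + SD, low = max(0, median − SD/2),
with SD the sample standard deviation (ddof = 1; population SD available
for sensitivity analysis). Classification: High iff TMB ≥ high cutoff,
Low iff TMB < low cutoff, Moderate otherwise — the boundary inclusivity
follows the convention "High (TMB ≥ cut), Moderate (low ≤ TMB < cut),
Low (TMB < low)". When SD = 0 both cutoffs coincide and every patient is
High (≥ rule applies first). Note the cutoff rule is a data-adaptive
convention, not a calibrated clinical threshold; published cutoff pairs
from specific cohorts cannot generally be regenerated from their published
median alone.

## PD-L1 scoring

TC bins percentages of PD-L1-expressing tumor cells (lower bounds
inclusive): TC0 < 1, TC1 [1, 5), TC2 [5, 50), TC3 ≥ 50. IC bins the
percentage of tumor area occupied by PD-L1-positive immune cells: IC0 < 1,
IC1 [1, 5), IC2 [5, 10), IC3 ≥ 10. Category 0 maps to negative, 1/2/3 to
weak/moderate/strong; positivity is any+. TC and IC are scored and
analyzed separately (combination analysis uses TC positivity only, the
compartment with demonstrated survival association; a max-of-compartments
grade exists but is off the default path). Frequency tables report raw
counts, exact proportions, and integer percentages rounded **half-up** —
the rounding that reproduces published frequency tables (e.g. 50/136 → 37,
23/51 → 45). Cytoplasmic staining is outside the data model.

## Stratification

Dichotomized TMB (High vs Low/Moderate) × TC positivity yields four
mutually exclusive classes: LM_neg, LM_pos, H_pos, H_neg. H_neg patients
are assigned and reported explicitly but excluded from combined-class
survival comparisons by default (flag to include), mirroring the common
three-class presentation. Overlap summaries give the Venn counts
{PD-L1+ only, TMB-high only, both, neither} with percentages over the
subgroup and, optionally, over the total cohort — published overlap
figures are quoted under either normalization, so both are reported.

## Survival and association statistics

* **Kaplan–Meier** via lifelines: product-limit estimate, Greenwood
  variance with log-log 95% CI, median = smallest observed time with
  S(t) ≤ 0.5 (infinite when not reached).
* **Log-rank**: Mantel–Haenszel chi-square with k−1 df, hypergeometric
  variance with ties (lifelines `multivariate_logrank_test`).
* **Contingency tests**: Pearson chi-square unless any expected cell is
  below 5, then Fisher's exact — scipy for 2×2; for larger tables an exact
  enumeration over all tables with the observed margins (probabilities
  summed for tables no more probable than observed), falling back to
  chi-square (tagged `chi2_fallback`) if the enumeration would exceed
  2×10⁶ tables. Yates continuity correction for 2×2 is off by default and
  exposed as a flag, since reported conventions differ.
* **Spearman**: midrank ties; exact two-sided permutation p for n ≤ 9,
  t approximation otherwise. Constant vectors are an error.
* **Kruskal–Wallis + Dunn**: tie-corrected KW (scipy); Dunn's pairwise
  z-statistics computed from pooled midranks with the tie term
  Σ(t³−t)/(12(N−1)). Pairwise p-values are **unadjusted by default**
  (matching reports that quote single pairwise P values without naming a
  correction); Bonferroni by flag.

All tests are two-sided. The report generator (`run_full_analysis`)
derives scores, cutoffs, classes and strata from a cohort table, then
emits frequency tables, per-characteristic association tests, KM + log-rank
per stratification (driver-mutation status, PD-L1, TMB, combined class,
per histology), overlap summaries, Spearman TMB-vs-TC%, and KW/Dunn of TMB
across TC grades. Single-histology cohorts skip the missing group's
sections with a notice.

## Synthetic cohort generator

The generator's defaults define the study conditions:

| parameter | default | rationale |
|---|---|---|
| n_patients | 187 | reference cohort size (136 ADC / 51 SQCC) |
| territory | 1.4 Mb, 150 intervals | coding footprint typical of a ~1000-gene panel |
| TMB distribution | log-normal, median 8.0 mut/Mb, σ = 0.8 | cohort median 8.0; σ chosen so a ~190-patient cohort spans ≈ 0–60 mut/Mb |
| somatic fraction | 0.5 | half of candidate calls truly somatic before filtering |
| depths | NB mean 300× tumor / 150× normal, shape 10 | targeted-panel coverage with overdispersion |
| strand-bias rate | 0.02 | small artifact fraction (skew p = 0.98) |
| PD-L1 mixtures | ADC TC 63/10/7/20, IC 65/10/5/20; SQCC TC 45/14/14/27, IC 43/29/4/24 (%) | published per-histology category frequencies; uniform percentage within bin |
| hazards | median OS 32 (LM_neg), 8.5 (LM_pos), 6 (H_pos), 8.5 (H_neg) months | exponential per class; reproduces the reported responder/non-responder separation |
| censor rate | 0.15 | administrative censoring, uniform before death time |

Survival is exponential per combined class — the simplest model matching
reported medians and log-rank separations. Germline variants get matched
tumor/normal allele fractions (het 0.5 / hom 1.0), population-database
counts ≥ 2 with a 10% "leakage" fraction at ≤ 1 to exercise false-positive
paths, dbSNP flags at 80%, and germline zygosity calls at 90%. Somatic
variants get VAF uniform on [0.1, 0.6], near-zero normal alt fraction, and
missense deleteriousness scores above 0.452 except for a 5% benign
fraction. Ages center on the published medians (58 ADC / 60 SQCC) — purely
cosmetic. Per-patient true TMB is, exactly, the count of truly somatic
coding variants over territory; the "true" combined class applies the
median + SD rule to the true TMB values and the drawn TC positivity.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level errors and mapping artifacts (counts
are simulated directly, not from reads), coverage bias along the genome
(GC, footprint, repeats), inter-lab IHC antibody/platform variability,
non-exponential (e.g. plateauing) survival, covariate-dependent hazards,
and informative censoring. Annotation fields are inputs by design;
agreement with ground truth measures the filter logic, not annotation
quality.

## Numerical and design choices

* Exact tests: the somatic test is scipy's Fisher exact (one-sided); unit
  tests verify it against an independent hypergeometric-tail enumeration.
* The r×c exact enumeration uses log-gamma arithmetic and a ≤ 1e-9
  probability tolerance when collecting "as or less probable" tables.
* Percent rounding is half-up everywhere percentages are printed.
* Determinism: every generator consumes a `numpy.random.Generator` seeded
  from the config; identical config + seed reproduces all tabular outputs
  byte-for-byte. Outputs embed the seed and a SHA-256 config hash.
* Degenerate inputs are errors, not silent passes: zero-depth samples,
  empty cohorts, zero-margin tables, constant correlation inputs, < 2 TMB
  values for cutoffs.
* Problem sizes in tests and the acceptance script (200-patient synthetic
  cohorts, 200–2000 simulation replicates, 1000-draw KM recovery) were
  chosen so each check's sampling error is several times smaller than the
  tolerance it asserts.

## Known limitations

* No Cox regression or multivariable adjustment (out of scope; the
  workflow is deliberately univariate/stratified).
* The exact r×c Fisher path is exponential in table size; large sparse
  tables fall back to chi-square with an explicit method tag.
* TMB is panel-normalized only; no whole-exome extrapolation.
* The KM median CI is reported through lifelines' log-log machinery at the
  curve level; per-median CIs for very small strata (< ~10 events) are
  unstable, as usual.
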