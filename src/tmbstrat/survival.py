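"""Survival and association statistics for biomarker stratifications.

Kaplan-Meier estimation (Greenwood variance, log-log 95% CI, median = the
smallest time with S(t) <= 0.5), the Mantel-Haenszel log-rank test with the
tied-data hypergeometric variance, Pearson chi-square / Fisher's exact
contingency tests with the expected-count-below-5 switch, Spearman rank
correlation (exact permutation p for n <= 9), the tie-corrected
Kruskal-Wallis test with Dunn's pairwise z comparisons, and the cohort-level
report generator tying the stages together.

All tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps

from . import pdl1 as _pdl1
from . import stratify as _stratify
from . import tmb as _tmb


# ---------------------------------------------------------------- Kaplan-Meier

@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate over the observed event times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    median: float  # months; math.inf when not reached
    n: int
    n_events: int

    @property
    def median_reached(self) -> bool:
        return math.isfinite(self.median)


def km_estimate(time: Sequence[float], event: Sequence[bool]) -> KMCurve:
    """Kaplan-Meier estimate with Greenwood log-log 95% CI.

    ``time`` is months since therapy start; ``event`` is True for death,
    False for censoring. The median is the smallest observed time with
    S(t) <= 0.5, infinite if the curve never drops that far.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival data")
    if (t < 0).any():
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter(alpha=0.05)
    kmf.fit(t, event_observed=e)
    event_times = np.asarray(kmf.event_table.index, dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    ci = kmf.confidence_interval_
    at_risk = kmf.event_table["at_risk"].to_numpy()
    median = float(kmf.median_survival_time_)
    return KMCurve(
        times=event_times,
        survival=surv,
        at_risk=at_risk,
        ci_lower=ci.iloc[:, 0].to_numpy(),
        ci_upper=ci.iloc[:, 1].to_numpy(),
        median=median,
        n=int(t.size),
        n_events=int(e.sum()),
    )


@dataclass(frozen=True)
class LogrankResult:
    statistic: float
    p: float
    df: int


def logrank_test(
    times_by_group: Mapping[str, Sequence[float]],
    events_by_group: Mapping[str, Sequence[bool]],
) -> LogrankResult:
    """Mantel-Haenszel log-rank across k groups (chi-square, k-1 df)."""
    labels = list(times_by_group)
    if len(labels) < 2:
        raise ValueError("log-rank needs at least two groups")
    durations, groups, events = [], [], []
    for g in labels:
        t = np.asarray(times_by_group[g], dtype=float)
        if t.size == 0:
            raise ValueError(f"group {g!r} has zero subjects")
        durations.append(t)
        events.append(np.asarray(events_by_group[g], dtype=bool))
        groups.extend([g] * t.size)
    res = multivariate_logrank_test(
        np.concatenate(durations), groups, np.concatenate(events)
    )
    return LogrankResult(
        statistic=float(res.test_statistic), p=float(res.p_value), df=len(labels) - 1
    )


# ---------------------------------------------------------- contingency tests

def _rxc_exact_p(table: np.ndarray, max_tables: int = 2_000_000) -> Optional[float]:
    """Fisher's exact p for an r x c table by enumeration over fixed margins.

    Sums the probabilities of all tables no more probable than the observed
    one. Returns None if the enumeration would exceed ``max_tables``.
    """
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = int(table.sum())
    lgam = math.lgamma
    log_const = (
        sum(lgam(r + 1) for r in row_sums)
        + sum(lgam(c + 1) for c in col_sums)
        - lgam(n + 1)
    )

    def log_prob(cells: Iterable[int]) -> float:
        return log_const - sum(lgam(x + 1) for x in cells)

    obs_lp = log_prob(table.ravel())
    r, c = table.shape
    total = 0.0
    count = 0

    # fill row-major; last column and last row are forced by the margins
    def rec(i: int, j: int, row_rem: int, col_rem: list[int], cells: list[int]) -> bool:
        nonlocal total, count
        if i == r - 1:
            # last row forced
            forced = col_rem.copy()
            if row_rem != sum(forced) or any(x < 0 for x in forced):
                return True
            lp = log_prob(cells + forced)
            count += 1
            if count > max_tables:
                return False
            if lp <= obs_lp + 1e-9:
                total += math.exp(lp)
            return True
        if j == c - 1:
            if row_rem > col_rem[j] or row_rem < 0:
                return True
            col_rem[j] -= row_rem
            ok = rec(i + 1, 0, int(row_sums[i + 1]), col_rem, cells + [row_rem])
            col_rem[j] += row_rem
            return ok
        hi = min(row_rem, col_rem[j])
        for x in range(hi + 1):
            col_rem[j] -= x
            ok = rec(i, j + 1, row_rem - x, col_rem, cells + [x])
            col_rem[j] += x
            if not ok:
                return False
        return True

    completed = rec(0, 0, int(row_sums[0]), [int(x) for x in col_sums], [])
    if not completed:
        return None
    return min(1.0, total)


@dataclass(frozen=True)
class ContingencyResult:
    p: float
    method: str  # "fisher" | "chi2" | "chi2_fallback"
    statistic: Optional[float] = None


def contingency_test(
    table: Sequence[Sequence[int]],
    correction: bool = False,
) -> ContingencyResult:
    """Pearson chi-square or Fisher's exact test on an r x c count table.

    Fisher's exact test is used when any expected cell count is below 5
    (exact enumeration for small r x c beyond 2x2); Pearson's chi-square
    otherwise. ``correction`` applies the Yates continuity correction to the
    2x2 chi-square variant.
    """
    tab = np.asarray(table, dtype=np.int64)
    if (tab < 0).any():
        raise ValueError("counts must be nonnegative")
    if tab.sum() == 0:
        raise ValueError("all-zero table")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: zero margin")
    expected = sps.contingency.expected_freq(tab)
    if (expected < 5).any():
        if tab.shape == (2, 2):
            p = float(sps.fisher_exact(tab)[1])
            return ContingencyResult(p=p, method="fisher")
        p = _rxc_exact_p(tab)
        if p is not None:
            return ContingencyResult(p=p, method="fisher")
        chi2, p, _, _ = sps.chi2_contingency(tab, correction=False)
        return ContingencyResult(p=float(p), method="chi2_fallback", statistic=float(chi2))
    chi2, p, _, _ = sps.chi2_contingency(tab, correction=correction and tab.shape == (2, 2))
    return ContingencyResult(p=float(p), method="chi2", statistic=float(chi2))


# ----------------------------------------------------------------- Spearman

def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midrank ties; two-sided p.

    For n <= 9 the p-value is exact, from full enumeration of pairings of
    the observed rank vectors; otherwise the t approximation is used.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.size != yv.size:
        raise ValueError("x and y must be paired")
    n = xv.size
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("constant vector: correlation undefined")
    rho = float(sps.spearmanr(xv, yv)[0])
    if n <= 9:
        rx = sps.rankdata(xv)
        ry = sps.rankdata(yv)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        hits = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
            hits += r >= obs - 1e-12
            total += 1
        return rho, hits / total
    return rho, float(sps.spearmanr(xv, yv)[1])


# ------------------------------------------------------ Kruskal-Wallis + Dunn

@dataclass(frozen=True)
class KruskalDunnResult:
    kw_statistic: float
    kw_p: float
    pairwise: pd.DataFrame  # columns: group1, group2, z, p
    adjustment: str


def kruskal_dunn(
    groups: Mapping[str, Sequence[float]],
    adjustment: Literal["none", "bonferroni"] = "none",
) -> KruskalDunnResult:
    """Tie-corrected Kruskal-Wallis plus Dunn's pairwise z comparisons.

    Dunn's z for groups i, j uses pooled midranks:
    z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj)) with the tie term
    T = sum(t^3 - t) / (12 (N - 1)). Pairwise p-values are unadjusted by
    default; Bonferroni multiplies by k(k-1)/2.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = []
    for g in labels:
        a = np.asarray(groups[g], dtype=float)
        if a.size == 0:
            raise ValueError(f"group {g!r} is empty")
        arrays.append(a)
    kw_stat, kw_p = sps.kruskal(*arrays)
    pooled = np.concatenate(arrays)
    ranks = sps.rankdata(pooled)
    big_n = pooled.size
    # tie correction over pooled ranks
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (big_n - 1))
    mean_ranks = {}
    i = 0
    for g, a in zip(labels, arrays):
        mean_ranks[g] = float(ranks[i : i + a.size].mean())
        i += a.size
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for g1, g2 in itertools.combinations(labels, 2):
        n1 = len(groups[g1])
        n2 = len(groups[g2])
        denom = math.sqrt((big_n * (big_n + 1) / 12.0 - tie_term) * (1.0 / n1 + 1.0 / n2))
        z = (mean_ranks[g1] - mean_ranks[g2]) / denom if denom > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        if adjustment == "bonferroni":
            p = min(1.0, p * n_pairs)
        rows.append({"group1": g1, "group2": g2, "z": z, "p": p})
    return KruskalDunnResult(
        kw_statistic=float(kw_stat),
        kw_p=float(kw_p),
        pairwise=pd.DataFrame(rows),
        adjustment=adjustment,
    )


# ------------------------------------------------------------- report bundle

REQUIRED_COLUMNS = (
    "patient_id", "histology", "age", "sex", "smoking", "stage",
    "mutation_status", "tc_pct", "ic_pct", "tmb", "os_months", "os_event",
)


def _km_summary(curve: KMCurve) -> dict:
    return {
        "n": curve.n,
        "events": curve.n_events,
        "median_os_months": curve.median if curve.median_reached else "not_reached",
    }


def _survival_comparison(df: pd.DataFrame, by: str) -> dict:
    groups = {str(g): sub for g, sub in df.groupby(by) if len(sub) > 0}
    out = {g: _km_summary(km_estimate(sub["os_months"], sub["os_event"].astype(bool)))
           for g, sub in groups.items()}
    if len(groups) >= 2:
        lr = logrank_test(
            {g: sub["os_months"].to_numpy() for g, sub in groups.items()},
            {g: sub["os_event"].astype(bool).to_numpy() for g, sub in groups.items()},
        )
        out["logrank"] = {"statistic": lr.statistic, "p": lr.p, "df": lr.df}
    return out


def run_full_analysis(
    cohort: pd.DataFrame,
    dunn_adjustment: Literal["none", "bonferroni"] = "none",
    include_h_neg_in_survival: bool = False,
    seed: Optional[int] = None,
) -> dict:
    """End-to-end cohort analysis: scoring, cutoffs, strata, tables, survival.

    ``cohort`` needs the columns in :data:`REQUIRED_COLUMNS`; ``tmb`` is the
    per-patient mutations/Mb already computed from filtered variants.
    Returns a JSON-serializable report bundle; single-histology cohorts get
    a notice instead of the missing group's sections. H_neg patients are
    excluded from combined-class survival curves unless requested.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing required columns: {missing}")
    df = cohort.copy()

    # PD-L1 scoring
    scores = [
        _pdl1.score_patient(_pdl1.IHCReadout(str(r.patient_id), r.tc_pct, r.ic_pct))
        for r in df.itertuples()
    ]
    df["tc_category"] = [s.tc_category for s in scores]
    df["ic_category"] = [s.ic_category for s in scores]
    df["tc_grade"] = [s.tc_grade for s in scores]
    df["pdl1_tc_positive"] = [s.tc_positive for s in scores]

    # TMB cutoffs on the pooled cohort, classes, dichotomy
    cutoffs = _tmb.derive_cutoffs(df["tmb"])
    df["tmb_class"] = [_tmb.classify_tmb(v, cutoffs) for v in df["tmb"]]
    df["tmb_binary"] = [_tmb.dichotomize_tmb(c) for c in df["tmb_class"]]
    df["combined_class"] = [
        _stratify.combine(b, p) for b, p in zip(df["tmb_binary"], df["pdl1_tc_positive"])
    ]

    report: dict = {
        "seed": seed,
        "n_patients": int(len(df)),
        "tmb_cutoffs": {
            "median": cutoffs.median,
            "sd": cutoffs.sd,
            "low_cutoff": cutoffs.low_cutoff,
            "high_cutoff": cutoffs.high_cutoff,
        },
        "notices": [],
    }

    histologies = [h for h in ("ADC", "SQCC") if (df["histology"] == h).any()]
    for h in ("ADC", "SQCC"):
        if h not in histologies:
            report["notices"].append(f"no {h} patients: {h} sections skipped")

    # PD-L1 frequency tables per histology
    freq: dict = {}
    for h in histologies:
        sub_scores = [s for s, hh in zip(scores, df["histology"]) if hh == h]
        freq[h] = {
            comp: {
                "four": _pdl1.frequency_table(sub_scores, comp, 4),
                "two": _pdl1.frequency_table(sub_scores, comp, 2),
            }
            for comp in ("TC", "IC")
        }
    report["pdl1_frequencies"] = freq

    # characteristic association tables (per histology): each characteristic
    # cross-tabulated against TC positivity, tested per row
    assoc: dict = {}
    for h in histologies:
        sub = df[df["histology"] == h]
        assoc[h] = {}
        for char in ("sex", "smoking", "stage", "mutation_status"):
            tab = pd.crosstab(sub[char], sub["pdl1_tc_positive"])
            if tab.shape[0] >= 2 and tab.shape[1] >= 2 and not (
                (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any()
            ):
                res = contingency_test(tab.to_numpy())
                assoc[h][char] = {"p": res.p, "method": res.method}
            else:
                assoc[h][char] = {"p": None, "method": "degenerate"}
    report["pdl1_associations"] = assoc

    # survival stratifications per histology
    survival: dict = {}
    for h in histologies:
        sub = df[df["histology"] == h]
        entry: dict = {}
        if sub["mutation_status"].nunique() >= 2:
            entry["by_mutation_status"] = _survival_comparison(sub, "mutation_status")
        entry["by_pdl1"] = _survival_comparison(
            sub.assign(pdl1=np.where(sub["pdl1_tc_positive"], "positive", "negative")),
            "pdl1",
        )
        entry["by_tmb"] = _survival_comparison(sub, "tmb_binary")
        comb = sub if include_h_neg_in_survival else sub[sub["combined_class"] != "H_neg"]
        if comb["combined_class"].nunique() >= 2:
            entry["by_combined_class"] = _survival_comparison(comb, "combined_class")
        survival[h] = entry
    report["survival"] = survival

    # overlap of PD-L1 positive and TMB-high per histology
    overlap: dict = {}
    for h in histologies:
        sub = df[df["histology"] == h]
        assignments = [
            _stratify.assign(str(r.patient_id), r.tmb_binary, bool(r.pdl1_tc_positive))
            for r in sub.itertuples()
        ]
        overlap[h] = _stratify.overlap_summary(assignments, total_n=len(df))
    report["overlap"] = overlap

    # TMB vs PD-L1: Spearman per histology and Kruskal-Wallis/Dunn by TC grade
    corr: dict = {}
    for h in histologies:
        sub = df[df["histology"] == h]
        try:
            rho, p = spearman_corr(sub["tmb"].to_numpy(), sub["tc_pct"].to_numpy())
            corr[h] = {"rho": rho, "p": p}
        except ValueError as exc:
            corr[h] = {"rho": None, "p": None, "note": str(exc)}
    report["tmb_pdl1_spearman"] = corr

    kd: dict = {}
    for h in histologies:
        sub = df[df["histology"] == h]
        groups = {
            g: sub.loc[sub["tc_grade"] == g, "tmb"].to_numpy()
            for g in ("negative", "weak", "moderate", "strong")
            if (sub["tc_grade"] == g).sum() > 0
        }
        if len(groups) >= 2:
            res = kruskal_dunn(groups, adjustment=dunn_adjustment)
            kd[h] = {
                "kw_statistic": res.kw_statistic,
                "kw_p": res.kw_p,
                "pairwise": res.pairwise.to_dict(orient="records"),
            }
    report["tmb_by_pdl1_grade"] = kd
    report["cohort_annotated"] = df
    return report
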