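"""Kaplan-Meier, log-rank, contingency, Spearman, Kruskal-Wallis/Dunn."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from tmbstrat import (
    CohortConfig,
    contingency_test,
    generate_cohort,
    km_estimate,
    kruskal_dunn,
    logrank_test,
    run_full_analysis,
    spearman_corr,
)
from tmbstrat.survival import _rxc_exact_p

LN2 = math.log(2.0)


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        curve = km_estimate([1.0, 2.0, 3.0], [True, True, True])
        # S(1)=2/3, S(2)=1/3, S(3)=0; median = smallest t with S <= 0.5 -> 2
        surv = dict(zip(curve.times, curve.survival))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)
        assert curve.median == pytest.approx(2.0)

    def test_all_censored_median_not_reached(self):
        curve = km_estimate([5.0, 8.0, 10.0], [False, False, False])
        assert (curve.survival == 1.0).all()
        assert not curve.median_reached

    def test_exponential_median_recovery(self):
        rng = np.random.default_rng(42)
        t = rng.exponential(32.0 / LN2, size=1000)
        curve = km_estimate(t, np.ones(1000, dtype=bool))
        assert curve.median == pytest.approx(32.0, abs=2.0)

    def test_uncensored_km_equals_empirical_survival(self, rng):
        t = rng.integers(1, 15, size=40).astype(float)
        curve = km_estimate(t, np.ones(40, dtype=bool))
        for time, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(t > time))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])

    def test_survival_nonincreasing_starts_at_one(self, rng):
        t = rng.exponential(10, size=50)
        e = rng.random(50) < 0.7
        curve = km_estimate(t, e)
        assert curve.survival[0] <= 1.0 + 1e-12
        assert (np.diff(curve.survival) <= 1e-12).all()


def _brute_force_logrank(times, events, groups):
    """Independent Mantel-Haenszel computation from the risk tables."""
    labels = sorted(set(groups))
    k = len(labels)
    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    event_times = sorted(df.loc[df["e"], "t"].unique())
    z = np.zeros(k)
    v = np.zeros((k, k))
    for t in event_times:
        at_risk = df["t"] >= t
        n = at_risk.sum()
        d = (at_risk & df["e"] & (df["t"] == t)).sum()
        nj = np.array([(at_risk & (df["g"] == g)).sum() for g in labels], dtype=float)
        dj = np.array(
            [(at_risk & df["e"] & (df["t"] == t) & (df["g"] == g)).sum() for g in labels],
            dtype=float,
        )
        z += dj - d * nj / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            for a in range(k):
                for b in range(k):
                    delta = 1.0 if a == b else 0.0
                    v[a, b] += factor * (nj[a] / n) * (delta - nj[b] / n)
    stat = z[:-1] @ np.linalg.solve(v[:-1, :-1], z[:-1])
    return float(stat)


class TestLogrank:
    def test_identical_groups_give_null(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, True, False, True]
        res = logrank_test({"a": t, "b": t}, {"a": e, "b": e})
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p == pytest.approx(1.0)

    def test_three_group_statistic_matches_brute_force(self, rng):
        times = rng.exponential(10, size=30).round(1) + 0.1
        events = rng.random(30) < 0.8
        groups = np.array(["a", "b", "c"])[rng.integers(0, 3, size=30)]
        expected = _brute_force_logrank(times, events, groups)
        got = logrank_test(
            {g: times[groups == g] for g in "abc"},
            {g: events[groups == g] for g in "abc"},
        )
        assert got.statistic == pytest.approx(expected, rel=1e-6)
        assert got.df == 2

    def test_power_under_hazard_ratio_four(self):
        # two exponential arms, HR 4, n=200/arm: reject at 0.05 in >=95% of runs
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 500
        for _ in range(n_rep):
            t1 = rng.exponential(32 / LN2, size=200)
            t2 = rng.exponential(8 / LN2, size=200)
            res = logrank_test(
                {"a": t1, "b": t2},
                {"a": np.ones(200, bool), "b": np.ones(200, bool)},
            )
            rejections += res.p < 0.05
        assert rejections / n_rep >= 0.95

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="zero subjects"):
            logrank_test({"a": [1.0], "b": []}, {"a": [True], "b": []})

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test({"a": [1.0]}, {"a": [True]})


class TestContingency:
    def test_sex_by_positivity_strongly_associated(self):
        res = contingency_test([[45, 41], [41, 9]])
        assert res.p < 0.001
        assert res.method == "chi2"

    def test_balanced_table_null(self):
        res = contingency_test([[5, 5], [5, 5]])
        assert res.p == pytest.approx(1.0)

    def test_small_expected_uses_fisher(self):
        res = contingency_test([[8, 2], [1, 9]])
        assert res.method == "fisher"
        assert res.p == pytest.approx(sps.fisher_exact([[8, 2], [1, 9]])[1])

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            contingency_test([[5, 0], [3, 0]])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            contingency_test([[0, 0], [0, 0]])

    @pytest.mark.parametrize("seed", range(10))
    def test_rxc_enumeration_matches_scipy_on_2x2(self, seed):
        rng = np.random.default_rng(seed)
        tab = rng.integers(1, 10, size=(2, 2))
        assert _rxc_exact_p(tab) == pytest.approx(
            sps.fisher_exact(tab)[1], abs=1e-9
        )

    def test_small_2x3_exact(self):
        res = contingency_test([[3, 0, 2], [0, 4, 1]])
        assert res.method == "fisher"
        assert 0.0 < res.p < 1.0

    def test_continuity_correction_flag(self):
        plain = contingency_test([[20, 10], [10, 20]], correction=False)
        corrected = contingency_test([[20, 10], [10, 20]], correction=True)
        assert corrected.p > plain.p


class TestSpearman:
    def test_monotone_pairs_rho_one_exact_p(self):
        rho, p = spearman_corr([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        # only the identity and reversal of 5 ranks reach |rho| = 1
        assert p == pytest.approx(2 / 120)

    def test_tied_example_matches_brute_force_ranks(self):
        x = [1.0, 2.0, 2.0, 3.0]
        y = [5.0, 7.0, 9.0, 9.0]
        rho, _ = spearman_corr(x, y)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        assert rho == pytest.approx(np.corrcoef(rx, ry)[0, 1])

    def test_null_correlation_small(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            rho, _ = spearman_corr(rng.normal(size=1000), rng.normal(size=1000))
            hits += abs(rho) < 0.1
        assert hits >= 19

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_corr([1, 1, 1], [1, 2, 3])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1, 2], [3, 4])


class TestKruskalDunn:
    def test_identical_groups_null_statistic(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = kruskal_dunn({"a": g, "b": g, "c": g})
        assert res.kw_statistic == pytest.approx(0.0, abs=1e-9)
        assert len(res.pairwise) == 3  # k(k-1)/2

    def test_two_group_matches_scipy_kruskal(self, rng):
        a = rng.normal(0, 1, size=30)
        b = rng.normal(1, 1, size=25)
        res = kruskal_dunn({"a": a, "b": b})
        stat, p = sps.kruskal(a, b)
        assert res.kw_statistic == pytest.approx(stat)
        assert res.kw_p == pytest.approx(p)
        # with two groups Dunn's z^2 equals the KW chi-square
        assert res.pairwise["z"].iloc[0] ** 2 == pytest.approx(stat, rel=1e-6)

    def test_planted_shift_detected(self):
        rng = np.random.default_rng(5)
        groups = {
            "low": rng.normal(0, 1, 100),
            "mid": rng.normal(0.6, 1, 100),
            "high": rng.normal(1.2, 1, 100),
        }
        res = kruskal_dunn(groups)
        assert res.kw_p < 0.01

    def test_bonferroni_inflates_p(self, rng):
        groups = {g: rng.normal(0, 1, 20) for g in "abc"}
        plain = kruskal_dunn(groups, adjustment="none")
        bonf = kruskal_dunn(groups, adjustment="bonferroni")
        assert (bonf.pairwise["p"] >= plain.pairwise["p"] - 1e-12).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_dunn({"a": [1.0], "b": []})


@pytest.fixture(scope="module")
def cohort_df():
    cfg = CohortConfig(n_patients=120, seed=21)
    cohort = generate_cohort(cfg)
    df = cohort.clinical.copy()
    truth = cohort.ground_truth.set_index("patient_id")["true_tmb"]
    df["tmb"] = df["patient_id"].map(truth)
    return df


class TestRunFullAnalysis:
    def test_planted_hazard_medians_ordered(self, cohort_df):
        report = run_full_analysis(cohort_df, seed=21)
        adc = report["survival"]["ADC"]["by_combined_class"]
        med = {
            k: v["median_os_months"]
            for k, v in adc.items()
            if k != "logrank" and v["median_os_months"] != "not_reached"
        }
        if {"LM_neg", "LM_pos"} <= set(med):
            assert med["LM_neg"] > med["LM_pos"]
        if {"LM_neg", "H_pos"} <= set(med):
            assert med["LM_neg"] > med["H_pos"]

    def test_missing_columns_named(self, cohort_df):
        with pytest.raises(ValueError, match="os_months"):
            run_full_analysis(cohort_df.drop(columns=["os_months"]))

    def test_single_histology_skipped_with_notice(self, cohort_df):
        sub = cohort_df[cohort_df["histology"] == "ADC"]
        report = run_full_analysis(sub)
        assert any("SQCC" in n for n in report["notices"])
        assert "SQCC" not in report["survival"]

    def test_deterministic_report(self, cohort_df):
        import json

        from tmbstrat.io import _jsonable

        r1 = run_full_analysis(cohort_df, seed=3)
        r2 = run_full_analysis(cohort_df, seed=3)
        r1.pop("cohort_annotated")
        r2.pop("cohort_annotated")
        assert json.dumps(_jsonable(r1), sort_keys=True) == json.dumps(
            _jsonable(r2), sort_keys=True
        )
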