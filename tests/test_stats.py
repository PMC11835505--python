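"""Exact 2x2 inference, survival analysis and rank-sum statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, strategies as st

from esccmrd.stats import (
    ContingencyTable, build_contingency, conditional_mle_or, cox_fit, cox_ph,
    diagnostic_metrics, fisher_exact, km_logrank, rank_sum,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def cmle_oracle(a, b, c, d, tol=1e-10):
    """Solve E[a | margins, psi] = a by direct enumeration and bisection."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    if a == lo:
        return 0.0
    if a == hi:
        return math.inf

    def mean(psi):
        w = [math.comb(r1, k) * math.comb(r2, c1 - k) * psi**k for k in range(lo, hi + 1)]
        return sum(k * wk for k, wk in zip(range(lo, hi + 1), w)) / sum(w)

    left, right = 1e-12, 1e12
    while right / left > 1 + tol:
        mid = math.sqrt(left * right)
        if mean(mid) < a:
            left = mid
        else:
            right = mid
    return math.sqrt(left * right)


# ---------------------------------------------------------------------------
# 2x2 construction and diagnostics
# ---------------------------------------------------------------------------

class TestContingency:
    def test_not_evaluable_excluded(self):
        df = pd.DataFrame(
            {
                "preop_status": ["positive", "negative", "not_evaluable", "positive"],
                "recurrence": [1, 0, 1, 0],
            }
        )
        t = build_contingency(df, "preop")
        assert (t.a, t.b, t.c, t.d) == (1, 1, 0, 1)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            build_contingency(pd.DataFrame(columns=["preop_status", "recurrence"]), "preop")

    def test_all_not_evaluable_rejected(self):
        df = pd.DataFrame({"preop_status": ["not_evaluable"], "recurrence": [1]})
        with pytest.raises(ValueError, match="not_evaluable"):
            build_contingency(df, "preop")

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(1, -1, 0, 2)


class TestDiagnostics:
    @pytest.mark.parametrize(
        "table, sens, spec, ppv",
        [
            ((6, 13, 0, 16), 100.0, 55.2, 31.6),
            ((5, 1, 1, 28), 83.3, 96.6, 83.3),
            ((6, 0, 0, 29), 100.0, 100.0, 100.0),
        ],
    )
    def test_printed_metric_values(self, table, sens, spec, ppv):
        m = diagnostic_metrics(ContingencyTable(*table))
        assert round(100 * m.sensitivity, 1) == sens
        assert round(100 * m.specificity, 1) == spec
        assert round(100 * m.ppv, 1) == ppv

    def test_zero_denominator_is_undefined_not_zero(self):
        m = diagnostic_metrics(ContingencyTable(0, 0, 3, 4))
        assert m.sensitivity is not None and m.ppv is None

    def test_sensitivity_plus_fnr_is_one(self):
        t = ContingencyTable(7, 2, 3, 11)
        m = diagnostic_metrics(t)
        fnr = t.c / (t.a + t.c)
        assert m.sensitivity + fnr == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Fisher's exact test + conditional MLE odds ratio
# ---------------------------------------------------------------------------

class TestFisher:
    def test_preop_table_p(self):
        res = fisher_exact(ContingencyTable(6, 13, 0, 16))
        assert round(res.p_two_sided, 3) == 0.022

    def test_postop_table_or_cmle(self):
        res = fisher_exact(ContingencyTable(5, 1, 1, 28))
        # conditional MLE, verified against the enumeration oracle; the
        # sample cross-product ratio for this table is 140, far off
        assert res.or_cmle == pytest.approx(cmle_oracle(5, 1, 1, 28), rel=1e-7)
        assert round(res.or_cmle, 2) == 88.75
        assert res.p_two_sided < 0.001

    def test_symmetric_table(self):
        res = fisher_exact(ContingencyTable(1, 1, 1, 1))
        assert res.p_two_sided == pytest.approx(1.0)
        assert res.or_cmle == pytest.approx(1.0, abs=1e-8)

    def test_zero_margin_degenerate(self):
        res = fisher_exact(ContingencyTable(0, 0, 3, 5))
        assert res.p_two_sided == 1.0 and res.or_cmle is None

    def test_boundary_tables(self):
        assert fisher_exact(ContingencyTable(0, 5, 3, 2)).or_cmle == 0.0
        assert fisher_exact(ContingencyTable(3, 0, 2, 5)).or_cmle == math.inf

    def test_self_consistency_of_score_equation(self):
        for tab in [(5, 1, 1, 28), (6, 13, 1, 16), (3, 7, 2, 9), (10, 2, 4, 8)]:
            t = ContingencyTable(*tab)
            psi = fisher_exact(t).or_cmle
            r1, r2, c1 = t.a + t.b, t.c + t.d, t.a + t.c
            lo, hi = max(0, c1 - r2), min(r1, c1)
            ks = range(lo, hi + 1)
            w = [math.comb(r1, k) * math.comb(r2, c1 - k) * psi**k for k in ks]
            mean = sum(k * wk for k, wk in zip(ks, w)) / sum(w)
            assert mean == pytest.approx(t.a, abs=1e-6)

    def test_ci_brackets_estimate(self):
        res = fisher_exact(ContingencyTable(5, 1, 1, 28))
        lo, hi = res.or_ci
        assert lo < res.or_cmle < hi

    @given(
        st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
    )
    def test_p_matches_scipy_on_random_tables(self, a, b, c, d):
        mine = fisher_exact(ContingencyTable(a, b, c, d)).p_two_sided
        ref = sps.fisher_exact([[a, b], [c, d]])[1]
        assert 0.0 <= mine <= 1.0
        assert mine == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_cmle_matches_scipy_conditional(self):
        for tab in [(5, 1, 1, 28), (6, 13, 1, 16), (2, 3, 4, 5)]:
            mine = fisher_exact(ContingencyTable(*tab)).or_cmle
            ref = sps.contingency.odds_ratio([tab[:2], tab[2:]], kind="conditional")
            assert mine == pytest.approx(ref.statistic, rel=1e-6)


# ---------------------------------------------------------------------------
# Kaplan-Meier + log-rank
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_hand_product_limit(self):
        res = km_logrank([1, 2, 3], [1, 1, 0])
        curve = res.curves[0]
        assert list(curve["survival"]) == pytest.approx([2 / 3, 1 / 3, 1 / 3])

    def test_no_events_flat_at_one(self):
        res = km_logrank([5, 8, 13], [0, 0, 0])
        assert (res.curves[0]["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=40)
        res = km_logrank(t, np.ones(40, dtype=bool))
        curve = res.curves[0]
        emp = [(t > ti).mean() for ti in curve["time"]]
        assert list(curve["survival"]) == pytest.approx(emp)

    def test_identical_groups_give_null_logrank(self):
        t = [1, 2, 3, 4.0] * 2
        e = [1, 0, 1, 1] * 2
        g = [0] * 4 + [1] * 4
        res = km_logrank(t, e, g)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_logrank([-1, 2], [1, 1])

    def test_against_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import logrank_test

        rng = np.random.default_rng(9)
        n = 120
        g = rng.integers(0, 2, size=n)
        t = rng.exponential(np.where(g, 5.0, 10.0))
        e = t < 12
        t = np.minimum(t, 12)
        res = km_logrank(t, e, g)
        ref = logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
        assert res.chi2 == pytest.approx(ref.test_statistic, rel=1e-9)
        assert res.p_value == pytest.approx(ref.p_value, rel=1e-9)

        kmf = lifelines.KaplanMeierFitter().fit(t[g == 0], e[g == 0])
        curve = res.curves[0]
        ref_surv = kmf.survival_function_at_times(curve["time"]).to_numpy()
        assert curve["survival"].to_numpy() == pytest.approx(ref_surv, rel=1e-9)


# ---------------------------------------------------------------------------
# Cox proportional hazards
# ---------------------------------------------------------------------------

def _exp_cohort(rng, n=200, hr=3.0, p_exposed=0.4, followup=24.0, base=0.03):
    z = (rng.random(n) < p_exposed).astype(float)
    t = rng.exponential(1.0 / (base * hr**z))
    e = t < followup
    return np.minimum(t, followup), e, z


class TestCox:
    def test_null_covariate_near_zero(self):
        rng = np.random.default_rng(21)
        t, e, _ = _exp_cohort(rng, n=400, hr=1.0)
        z = rng.random(400)  # independent of outcome
        res = cox_ph(t, e, z)
        assert abs(res.coef[0]) < 3 * res.se[0]

    def test_recovers_true_hazard_ratio(self):
        rng = np.random.default_rng(22)
        t, e, z = _exp_cohort(rng, n=2000, hr=3.0)
        res = cox_ph(t, e, z)
        assert res.hr[0] == pytest.approx(3.0, rel=0.15)
        assert res.converged

    def test_against_lifelines(self):
        pytest.importorskip("lifelines")
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(23)
        t, e, z = _exp_cohort(rng, n=300, hr=2.0)
        x2 = rng.normal(size=300)
        df = pd.DataFrame({"t": t, "e": e.astype(int), "z": z, "x2": x2})
        cph = CoxPHFitter().fit(df, duration_col="t", event_col="e")
        res = cox_ph(t, e, np.column_stack([z, x2]), names=["z", "x2"])
        assert res.coef == pytest.approx(cph.params_.to_numpy(), rel=1e-5, abs=1e-7)
        assert res.se == pytest.approx(cph.standard_errors_.to_numpy(), rel=1e-4)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            cox_ph([1.0, 2.0], [False, False], np.array([0.0, 1.0]))

    def test_separation_detected_and_reported(self):
        # every event in the exposed group: monotone partial likelihood
        t = np.array([2.0, 3, 4, 5, 20, 21, 22, 23, 24, 24])
        e = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        z = np.array([1.0, 1, 1, 1, 0, 0, 1, 0, 0, 0])
        res = cox_ph(t, e, z)
        assert res.separated[0]
        assert math.isinf(res.hr[0])
        lo, hi = res.ci_lower[0], res.ci_upper[0]
        assert 0 <= lo and math.isinf(hi)
        assert res.ci_method[0] == "profile"

    def test_cox_fit_encodings(self, fixture_report):
        _, out = fixture_report
        ann = pd.read_csv(out / "clinical_annotated.csv", dtype={"patient_id": str})
        res = cox_fit(ann, ["postop_status", "age"])
        assert res.names == ["postop_status", "age"]
        assert res.n_events == int(ann["dfs_event"].sum())
        assert res.coef[0] > 0  # MRD positivity is the adverse level


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

class TestRankSum:
    def test_complete_separation_minimal_u(self):
        res = rank_sum([1, 2], [3, 4])
        assert res.w == 0.0
        assert res.method == "exact"
        assert res.p_two_sided == pytest.approx(1 / 3)

    def test_exact_matches_scipy_small_samples(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            n1, n2 = rng.integers(1, 6, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = rank_sum(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.w == pytest.approx(ref.statistic)
            assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_normal_approx_matches_scipy_with_ties(self):
        rng = np.random.default_rng(8)
        x = rng.integers(0, 6, size=25).astype(float)
        y = rng.integers(0, 6, size=30).astype(float)
        res = rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.method == "normal"
        assert res.w == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=10),
        st.lists(st.integers(0, 8), min_size=1, max_size=10),
    )
    def test_u_symmetry_identity(self, x, y):
        assert rank_sum(x, y).w + rank_sum(y, x).w == pytest.approx(len(x) * len(y))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])
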