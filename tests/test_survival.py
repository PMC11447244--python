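"""Stratification, Kaplan-Meier, log-rank and Cox regression."""

import numpy as np
import pandas as pd
import pytest

from rxsig.survival import (
    cox_fit,
    km_curve,
    logrank_test,
    score_group_cox,
    stratify_by_score,
)

# Reference coefficients computed once with the R `survival` package
# (coxph, ties="efron") on the two toy datasets below.
R_TOY1_COEF = -0.6931471806
R_TOY2_COEF = (0.8808446775, 0.6481240308)

TOY1 = pd.DataFrame({"time": [1, 1, 2, 2, 3, 4],
                     "event": [1, 0, 1, 1, 0, 1],
                     "x": [0, 1, 1, 0, 1, 0]})
TOY2 = pd.DataFrame({"time": [5, 5, 7, 7, 9, 12, 12, 15],
                     "event": [1, 1, 1, 0, 1, 1, 1, 0],
                     "x": [1, 0, 1, 1, 0, 1, 0, 0],
                     "z": [0.5, -0.2, 1.1, 0.0, 0.3, -0.7, 0.9, 0.1]})


class TestStratify:
    def test_quartile_split_with_interpolated_cuts(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=[f"p{i}" for i in range(8)])
        st = stratify_by_score(scores, "QUARTILE")
        assert st.samples("LOW") == ["p0", "p1"]     # scores 1, 2 <= Q1 = 2.75
        assert st.samples("HIGH") == ["p6", "p7"]    # scores 7, 8 >= Q3 = 6.25
        assert len(st.samples("EXCLUDED")) == 4
        assert st.thresholds == (2.75, 6.25)

    def test_median_split_no_exclusions(self):
        scores = pd.Series(np.arange(1.0, 9.0), index=[f"p{i}" for i in range(8)])
        st = stratify_by_score(scores, "MEDIAN")
        assert st.samples("LOW") == [f"p{i}" for i in range(4)]
        assert st.samples("HIGH") == [f"p{i}" for i in range(4, 8)]
        assert st.samples("EXCLUDED") == []

    def test_identical_scores_error(self):
        with pytest.raises(ValueError, match="identical"):
            stratify_by_score(pd.Series([1.0] * 10), "QUARTILE")

    def test_quartile_needs_eight(self):
        with pytest.raises(ValueError):
            stratify_by_score(pd.Series([1.0, 2.0, 3.0]), "QUARTILE")


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        km = km_curve([5, 8, 12], [0, 0, 0])
        assert (km.survival_function_["KM_estimate"] == 1.0).all()

    def test_product_limit_by_hand(self):
        km = km_curve([1, 2], [1, 1])
        sf = km.survival_function_["KM_estimate"]
        assert sf.loc[1.0] == pytest.approx(0.5)
        assert sf.loc[2.0] == pytest.approx(0.0)

    def test_censoring_after_last_event_leaves_tail_flat(self):
        sf = km_curve([1, 2, 5], [1, 1, 0]).survival_function_["KM_estimate"]
        assert sf.loc[5.0] == sf.loc[2.0]

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(21)
        t = np.round(rng.exponential(10, size=40), 1) + 0.1
        km = km_curve(t, np.ones_like(t))
        sf = km.survival_function_["KM_estimate"]
        for ti in np.unique(t):
            assert sf.loc[ti] == pytest.approx((t > ti).mean(), abs=1e-12)

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            km_curve([], [])


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Hand-rolled Mantel-Haenszel O-E with hypergeometric variance."""
    t = np.concatenate([times_a, times_b])
    e = np.concatenate([events_a, events_b])
    grp = np.concatenate([np.zeros(len(times_a)), np.ones(len(times_b))])
    O = E = V = 0.0
    for ti in np.unique(t[e == 1]):
        at_risk = t >= ti
        n = at_risk.sum()
        n_a = (at_risk & (grp == 0)).sum()
        d = ((t == ti) & (e == 1)).sum()
        d_a = ((t == ti) & (e == 1) & (grp == 0)).sum()
        O += d_a
        E += d * n_a / n
        if n > 1:
            V += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_give_null_statistic(self):
        g = pd.DataFrame({"time": [1, 2, 3, 4], "event": [1, 1, 0, 1]})
        chi2, p = logrank_test(g, g.copy())
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_computed_oracle(self):
        a = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1]})
        b = pd.DataFrame({"time": [4, 5, 6], "event": [1, 1, 1]})
        chi2, _ = logrank_test(a, b)
        expected = logrank_oracle(a["time"].to_numpy(), a["event"].to_numpy(),
                                  b["time"].to_numpy(), b["event"].to_numpy())
        assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_doubling_sample_size_increases_statistic(self):
        a = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1]})
        b = pd.DataFrame({"time": [4, 5, 6], "event": [1, 1, 1]})
        chi_small, _ = logrank_test(a, b)
        chi_big, _ = logrank_test(pd.concat([a, a]), pd.concat([b, b]))
        assert chi_big > chi_small

    def test_group_relabel_invariance(self):
        rng = np.random.default_rng(22)
        a = pd.DataFrame({"time": rng.exponential(10, 30).round(1) + 0.1,
                          "event": rng.integers(0, 2, 30)})
        b = pd.DataFrame({"time": rng.exponential(14, 25).round(1) + 0.1,
                          "event": rng.integers(0, 2, 25)})
        chi_ab, _ = logrank_test(a, b)
        chi_ba, _ = logrank_test(b, a)
        assert chi_ab == pytest.approx(chi_ba, abs=1e-10)

    def test_zero_events_error(self):
        g = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            logrank_test(g, g.copy())


class TestCox:
    def test_matches_reference_implementation_with_ties(self):
        res = cox_fit(TOY1, ["x"])
        assert res.coef("x") == pytest.approx(R_TOY1_COEF, abs=1e-4)
        res2 = cox_fit(TOY2, ["x", "z"])
        assert res2.coef("x") == pytest.approx(R_TOY2_COEF[0], abs=1e-4)
        assert res2.coef("z") == pytest.approx(R_TOY2_COEF[1], abs=1e-4)

    def test_null_covariate_recovers_hr_one(self):
        rng = np.random.default_rng(1)
        n = 5000
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(10, n)
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        res = cox_fit(df, ["x"])
        assert 0.93 <= res.hazard_ratio("x") <= 1.07

    def test_true_hazard_ratio_two_recovered(self):
        rng = np.random.default_rng(1)
        n = 2000
        x = np.repeat([0.0, 1.0], n // 2)
        t = rng.exponential(1.0 / np.exp(np.log(2.0) * x))
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        res = cox_fit(df, ["x"])
        assert 1.83 <= res.hazard_ratio("x") <= 2.18

    def test_covariate_rescaling_inverts_coefficient(self):
        rng = np.random.default_rng(23)
        n = 400
        z = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(0.5 * z))
        df = pd.DataFrame({"time": t, "event": 1, "z": z})
        res1 = cox_fit(df, ["z"])
        df["z"] = df["z"] * 10.0
        res2 = cox_fit(df, ["z"])
        assert res2.coef("z") == pytest.approx(res1.coef("z") / 10.0, abs=1e-8)
        assert res2.p_value("z") == pytest.approx(res1.p_value("z"), abs=1e-8)

    def test_ci_brackets_hr_and_counts(self):
        res = cox_fit(TOY2, ["x", "z"])
        row = res.summary.set_index("variable").loc["x"]
        assert row["ci_low"] <= row["hazard_ratio"] <= row["ci_high"]
        assert res.n == 8 and res.events == 6

    def test_missing_column_error(self):
        with pytest.raises(ValueError, match="missing"):
            cox_fit(TOY1, ["nope"])


class TestEndToEndSurvival:
    def test_score_driven_cohort_recovers_effect(self, cohort_seed1):
        """High-vs-low median split gives HR significantly above 1 and the
        continuous-score coefficient recovers the generating log-hazard."""
        _, clinical, truth = cohort_seed1
        res = score_group_cox(clinical, truth.true_score, covariates=())
        assert res.hazard_ratio("score_high") > 1
        assert res.p_value("score_high") < 0.01
        df = clinical.copy()
        df["score"] = truth.true_score
        cont = cox_fit(df, ["score", "age", "stage", "grade"])
        assert cont.coef("score") == pytest.approx(truth.beta, abs=0.1)
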