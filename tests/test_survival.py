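"""Prognosis arm: LASSO-Cox, risk scores, KM/log-rank, Cox fits, stratification."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from perirad import simulate_survival
from perirad.survival import (
    RiskModel,
    compare_risk_groups,
    compute_rrs,
    cox_fit,
    cox_partial_loglik,
    km_estimate,
    lasso_cox,
    logrank_test,
    median_split,
    screen_then_multivariable,
    select_signature_size,
    signature_candidates,
    stratified_km,
)


class TestLassoCox:
    def test_full_shrinkage_limit_all_zero(self, rng):
        X = pd.DataFrame(rng.normal(size=(80, 5)), columns=list("abcde"))
        t, e = simulate_survival(X["a"].to_numpy(), seed=1, censor_rate=0.2)
        res = lasso_cox(X, t, e, seed=0)
        # the largest penalty on the path zeroes every coefficient
        assert (res.coef_path.iloc[:, 0] == 0).all()

    def test_planted_predictor_dominates_recovered_signature(self):
        """One planted predictor (log-HR 1) among 20 noise features carries
        the largest |coefficient| in >= 90% of seeds."""
        wins = 0
        n_seeds = 20
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(
                r.normal(size=(300, 21)), columns=["sig"] + [f"n{i:02d}" for i in range(20)]
            )
            t, e = simulate_survival(X["sig"].to_numpy(), baseline_scale=5,
                                     censor_rate=0.3, seed=seed)
            res = lasso_cox(X, t, e, seed=seed)
            if not res.empty_signature and res.coefficients.abs().idxmax() == "sig":
                wins += 1
        assert wins / n_seeds >= 0.9

    def test_weak_penalty_limit_matches_plain_cox(self, rng):
        X = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        lp = 0.8 * X["a"] - 0.5 * X["b"]
        t, e = simulate_survival(lp.to_numpy(), seed=3, censor_rate=0.2)
        res = lasso_cox(X, t, e, seed=0)
        ref = cox_fit(X, t, e)
        beta_path = res.coef_path.iloc[:, -1]  # smallest penalty on the path
        for c in ("a", "b"):
            assert abs(beta_path[c] - ref.summary.loc[c, "coef"]) < 0.1 * abs(
                ref.summary.loc[c, "coef"]
            )

    def test_no_events_rejected(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="event"):
            lasso_cox(X, np.ones(20), np.zeros(20, dtype=int), seed=0)


class TestRRS:
    def test_zero_coefficients_give_zero_score(self):
        m = RiskModel(["a", "b"], [0.0, 0.0])
        assert compute_rrs(pd.Series({"a": 3.0, "b": -1.0}), m) == 0.0

    def test_hand_dot_product(self):
        m = RiskModel(["a", "b"], [1.0, -2.0])
        assert compute_rrs(pd.Series({"a": 0.5, "b": 0.25}), m) == pytest.approx(0.0)

    def test_missing_feature_rejected_no_imputation(self):
        m = RiskModel(["a", "b"], [1.0, 1.0])
        with pytest.raises(KeyError, match="missing"):
            compute_rrs(pd.Series({"a": 1.0}), m)

    def test_json_round_trip(self, tmp_path):
        m = RiskModel(["x", "y", "z"], [0.4, -0.2, 1.1], lambda_=0.05, cutoff=-0.0809, tag="t")
        m.to_json(tmp_path / "m.json")
        back = RiskModel.from_json(tmp_path / "m.json")
        assert back.features == m.features
        assert np.allclose(back.coefficients, m.coefficients)
        assert back.cutoff == m.cutoff


class TestMedianSplit:
    def test_four_scores(self):
        groups, cutoff = median_split([1.0, 2.0, 3.0, 4.0])
        assert cutoff == 2.5
        assert list(groups) == ["low", "low", "high", "high"]

    def test_external_cutoff_applied_to_validation(self):
        groups, cutoff = median_split([0.0], [-0.5, 0.2], cutoff=-0.0809)
        assert cutoff == -0.0809
        assert list(groups) == ["low", "high"]

    def test_all_below_cutoff_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            groups, _ = median_split([1.0, 2.0], [-5.0, -6.0], cutoff=10.0)
        assert set(groups) == {"low"}

    def test_invariance_under_monotone_transform(self, rng):
        scores = rng.normal(size=31)
        g1, c1 = median_split(scores)
        g2, _ = median_split(np.exp(scores), cutoff=np.exp(c1))
        assert np.array_equal(g1, g2)

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        st.lists(
            st.floats(min_value=-100, max_value=100, allow_nan=False),
            min_size=3,
            max_size=40,
        )
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_group_labels_invariant_to_any_increasing_transform(self, scores):
        from hypothesis import assume

        scores = np.asarray(scores)
        g1, c1 = median_split(scores)
        for f in (np.exp, lambda x: 3 * x + 7, np.arctan):
            fc = float(f(np.array([c1]))[0])
            fs = f(scores)
            # the transform must keep scores distinguishable from the cutoff
            # at float precision, else strict comparisons are undefined
            assume(bool(np.all((fs == fc) == (scores == c1))))
            g2, _ = median_split(fs, cutoff=fc)
            assert np.array_equal(g1, g2)


class TestKaplanMeier:
    def test_three_subject_hand_product_limit(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_curve_stays_at_one(self):
        km = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.survival_at(100.0) == 1.0

    def test_moving_censoring_after_last_event_leaves_curve_unchanged(self):
        a = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
        b = km_estimate([1.0, 2.0, 9.0], [1, 1, 0])
        assert np.allclose(a.times, b.times)
        assert np.allclose(a.survival, b.survival)
        assert a.survival_at(1.0) == pytest.approx(2 / 3)
        assert a.survival_at(2.0) == pytest.approx(1 / 3)

    def test_curve_nonincreasing_starts_at_one_greenwood_nonnegative(self, rng):
        t, e = simulate_survival(rng.normal(size=80), seed=9, censor_rate=0.4)
        km = km_estimate(t, e)
        assert km.survival[0] <= 1.0
        assert np.all(np.diff(km.survival) <= 1e-12)
        assert np.all(km.variance >= 0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.array([1, 0, 1, 1])
        res = logrank_test(np.r_[["a"] * 4, ["b"] * 4], np.r_[t, t], np.r_[e, e])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_six_subject_hand_computed_table(self):
        """O-E table computed by hand for a 6-subject example.

        Groups A={1,3,5 (all events)}, B={2,4,6 (events at 2,4; censored 6)}.
        Hand O-E for group A: sums to 0.95; variance 0.6875+extra terms.
        """
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 1, 1, 1, 0])
        groups = np.array(["A", "B", "A", "B", "A", "B"])
        # hand computation: at each event time t, O_A - E_A with E_A = d * nA/n
        o_minus_e = 0.0
        var = 0.0
        for t, grp in ((1, "A"), (2, "B"), (3, "A"), (4, "B"), (5, "A")):
            at_risk = times >= t
            n = at_risk.sum()
            n_a = (at_risk & (groups == "A")).sum()
            o_a = 1.0 if grp == "A" else 0.0
            e_a = n_a / n
            o_minus_e += o_a - e_a
            var += e_a * (1 - n_a / n)
        expected_chi2 = o_minus_e**2 / var
        res = logrank_test(groups, times, events)
        assert res.statistic == pytest.approx(expected_chi2, abs=1e-10)

    def test_type_one_error_calibrated(self, rng):
        rejections = 0
        n_rep = 1000
        for i in range(n_rep):
            t, e = simulate_survival(np.zeros(100), seed=50_000 + i, censor_rate=0.3)
            groups = np.r_[["a"] * 50, ["b"] * 50]
            rejections += logrank_test(groups, t, e).p_value < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.02


class TestCox:
    def test_tiny_dataset_matches_partial_likelihood_enumeration(self):
        x = np.array([0.0, 1.0, 0.0, 1.0, 1.0, 0.0])
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 0, 1, 1, 1])
        res = cox_fit(pd.DataFrame({"x": x}), t, e)
        opt = minimize_scalar(lambda b: -cox_partial_loglik(b * x, t, e),
                              bounds=(-6, 6), method="bounded")
        assert res.summary["coef"].iloc[0] == pytest.approx(opt.x, abs=1e-3)
        assert res.log_likelihood == pytest.approx(-opt.fun, abs=1e-6)

    def test_loglik_at_optimum_beats_null(self, rng):
        x = rng.normal(size=100)
        t, e = simulate_survival(0.5 * x, seed=2, censor_rate=0.3)
        res = cox_fit(pd.DataFrame({"x": x}), t, e)
        assert res.log_likelihood >= res.null_log_likelihood

    def test_null_p_values_uniform(self):
        ps = []
        for i in range(500):
            r = np.random.default_rng(i)
            x = r.normal(size=60)
            t, e = simulate_survival(np.zeros(60), seed=70_000 + i, censor_rate=0.3)
            ps.append(cox_fit(pd.DataFrame({"x": x}), t, e, warn_epv=False).summary["p"].iloc[0])
        from scipy import stats as st

        assert st.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1.0, 1.0, 1.0]}), [1, 2, 3], [1, 1, 1])

    def test_few_events_warns(self, rng):
        X = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        t = np.arange(1.0, 11.0)
        e = np.r_[1, np.zeros(9)].astype(int)
        with pytest.warns(UserWarning, match="fewer events"):
            cox_fit(X, t, e)


class TestScreening:
    def test_planted_covariate_enters_and_stays(self, rng):
        n = 300
        design = pd.DataFrame(rng.normal(size=(n, 4)), columns=["strong", "n1", "n2", "n3"])
        t, e = simulate_survival(design["strong"].to_numpy(), seed=5, censor_rate=0.3)
        res = screen_then_multivariable(design, t, e, {c: c for c in design.columns})
        assert "strong" in res.significant
        assert res.multivariable is not None
        assert res.multivariable.summary.loc["strong", "p"] < 0.05

    def test_alpha_zero_gives_empty_multivariable(self, rng):
        design = pd.DataFrame(rng.normal(size=(50, 2)), columns=["a", "b"])
        t, e = simulate_survival(design["a"].to_numpy(), seed=6, censor_rate=0.2)
        res = screen_then_multivariable(design, t, e, {"a": "a", "b": "b"}, alpha=0.0)
        assert res.significant == [] and res.multivariable is None

    def test_joint_risk_score_and_stage_pattern(self, rng):
        """A continuous risk score and a binary stage indicator, both with
        planted effects, are each retained in the joint model."""
        n = 400
        rrs = rng.normal(size=n)
        t3 = rng.integers(0, 2, n).astype(float)
        t, e = simulate_survival(1.0 * rrs + 0.8 * t3, seed=7, censor_rate=0.3)
        design = pd.DataFrame({"rrs": rrs, "T3": t3, "noise": rng.normal(size=n)})
        res = screen_then_multivariable(design, t, e, {c: c for c in design.columns})
        assert {"rrs", "T3"} <= set(res.significant)
        assert res.multivariable.summary.loc["rrs", "p"] < 0.05
        assert res.multivariable.summary.loc["T3", "p"] < 0.05


class TestSignatureSize:
    def _make(self, rng, n=250):
        X = pd.DataFrame(rng.normal(size=(n, 8)), columns=[f"f{i}" for i in range(8)])
        lp = 1.0 * X["f0"] + 0.5 * X["f1"]
        t, e = simulate_survival(lp.to_numpy(), seed=8, censor_rate=0.3)
        return X, t, e

    def test_single_candidate_returned_unchanged(self, rng):
        X, t, e = self._make(rng)
        m = RiskModel(["f0"], [1.0], cutoff=0.0)
        res = select_signature_size({1: m}, X, t, e)
        assert res.n == 1 and res.selected_model is m

    def test_argmax_validation_hr_selected_with_provenance_flag(self, rng):
        X, t, e = self._make(rng)
        res_l = lasso_cox(X, t, e, seed=0)
        cands = signature_candidates(res_l, X)
        sel = select_signature_size(cands, X, t, e)
        assert sel.provenance == "validation-selection"
        hrs = sel.table["hr"].dropna()
        assert sel.n == int(hrs.idxmax())

    def test_no_candidates_rejected(self, rng):
        X, t, e = self._make(rng)
        with pytest.raises(ValueError):
            select_signature_size({}, X, t, e)


class TestStratified:
    def test_single_stratum_equals_unstratified(self, rng):
        n = 120
        scores = rng.normal(size=n)
        t, e = simulate_survival(0.8 * scores, seed=9, censor_rate=0.3)
        clin = pd.DataFrame({"time_years": t, "event": e, "ajcc_stage": ["I"] * n})
        strat = stratified_km(clin, scores, 0.0, "ajcc_stage")
        groups, _ = median_split(scores, cutoff=0.0)
        direct = compare_risk_groups(groups, t, e)
        assert set(strat) == {"I"}
        assert strat["I"].hr == pytest.approx(direct.hr)
        assert strat["I"].logrank.p_value == pytest.approx(direct.logrank.p_value)

    def test_planted_stratum_hr_ordering_recovered(self, rng):
        rows = []
        for stage, loghr in (("I", 0.0), ("II", np.log(3.0))):
            n = 400
            scores = rng.normal(size=n)
            t, e = simulate_survival(loghr * (scores > 0), seed=10, censor_rate=0.2)
            rows.append(pd.DataFrame({
                "time_years": t, "event": e, "ajcc_stage": stage, "score": scores
            }))
        clin = pd.concat(rows, ignore_index=True)
        strat = stratified_km(clin, clin["score"].to_numpy(), 0.0, "ajcc_stage")
        assert strat["II"].hr > strat["I"].hr

    def test_tiny_stratum_not_evaluable(self, rng):
        clin = pd.DataFrame({
            "time_years": [1.0, 2.0, 3.0],
            "event": [1, 1, 0],
            "ajcc_stage": ["III"] * 3,
        })
        strat = stratified_km(clin, np.array([-1.0, -2.0, 5.0]), 0.0, "ajcc_stage")
        assert strat["III"] is None

    def test_missing_stratum_field_rejected(self):
        clin = pd.DataFrame({"time_years": [1.0], "event": [1]})
        with pytest.raises(KeyError):
            stratified_km(clin, np.array([0.0]), 0.0, "ajcc_stage")


def test_group_comparison_reports_both_hr_scales(rng):
    """Both per-group (median split) and per-unit (continuous score) hazard
    ratios are available and consistent in direction."""
    n = 300
    scores = rng.normal(size=n)
    t, e = simulate_survival(0.7 * scores, seed=11, censor_rate=0.3)
    groups, cutoff = median_split(scores)
    grp = compare_risk_groups(groups, t, e)
    per_unit = cox_fit(pd.DataFrame({"rrs": scores}), t, e).summary.loc["rrs", "hr"]
    assert grp.hr > 1.0 and per_unit > 1.0
    assert grp.hr_ci[0] < grp.hr < grp.hr_ci[1]
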