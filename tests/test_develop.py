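"""Cox development: partial-likelihood oracle checks, Breslow baseline,
parameter recovery on generator output, FP selection, LASSO selection."""

import numpy as np
import pandas as pd
import pytest

from ppcvd.cohort import generate_cohort, simulate_survival
from ppcvd.defaults import default_spec, truth_terms, TRUE_HAZARD_RATIOS
from ppcvd.develop import (
    breslow_baseline,
    fit_cox,
    lasso_select,
    partial_loglik,
    recalibrate_baseline,
    select_fp,
)
from ppcvd.riskeq import CoefficientSet, Term, predicted_risk


def brute_force_partial_loglik(beta, x, time, event):
    """Direct O(n^2) Breslow partial log-likelihood for a single covariate."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [j for j in range(len(time)) if time[j] >= time[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.asarray(x)[risk])))
    return ll


class TestFitCox:
    def test_matches_brute_force_grid_maximiser(self, six_subject_cohort):
        df = six_subject_cohort
        model = fit_cox(df, [Term("x", "linear", "x")])
        grid = np.linspace(-5, 5, 100_001)
        lls = [
            brute_force_partial_loglik(b, df["x"].to_numpy(), df["time"].to_numpy(),
                                       df["event"].to_numpy())
            for b in grid
        ]
        beta_star = grid[int(np.argmax(lls))]
        assert model.params["x"] == pytest.approx(beta_star, abs=1e-4)
        assert model.llf == pytest.approx(np.max(lls), abs=1e-6)

    def test_vectorised_partial_loglik_matches_brute_force(self, six_subject_cohort, rng):
        df = six_subject_cohort
        for beta in rng.normal(size=5):
            fast = partial_loglik(beta * df["x"].to_numpy(), df["time"].to_numpy(),
                                  df["event"].to_numpy())
            slow = brute_force_partial_loglik(beta, df["x"].to_numpy(),
                                              df["time"].to_numpy(), df["event"].to_numpy())
            assert fast == pytest.approx(slow, abs=1e-10)

    def test_zero_events_raise(self):
        df = pd.DataFrame({"x": [1, 0], "time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError, match="zero events"):
            fit_cox(df, [Term("x", "linear", "x")])

    def test_offset_only_null_fit(self, six_subject_cohort):
        df = six_subject_cohort
        model = fit_cox(df, [], offset=df["x"].to_numpy() * 0.5)
        assert len(model.params) == 0
        assert np.isfinite(model.llf)
        assert model.centering == pytest.approx(0.25)

    def test_separated_predictor_warns_and_caps(self):
        # every carrier has the event, early; every non-carrier is censored
        df = pd.DataFrame(
            {
                "x": [1] * 5 + [0] * 20,
                "time": [0.5, 0.6, 0.7, 0.8, 0.9] + [5.0] * 20,
                "event": [1] * 5 + [0] * 20,
            }
        )
        with pytest.warns(RuntimeWarning, match="separated"):
            model = fit_cox(df, [Term("x", "linear", "x")])
        assert np.isfinite(model.params["x"])

    def test_matches_independent_cox_implementation(self, rng):
        """Coefficients, SEs and baseline risk agree with lifelines (an
        independent partial-likelihood implementation) on censored data."""
        import lifelines

        n = 2_000
        df = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.binomial(1, 0.3, n)})
        lp = 0.6 * df["x1"] - 0.4 * df["x2"]
        time, event = simulate_survival(lp.to_numpy(), 0.05, None, 10.0, rng)
        df["time"], df["event"] = time, event
        model = fit_cox(df, [Term("x1", "linear", "x1"), Term("x2", "linear", "x2")])
        cph = lifelines.CoxPHFitter().fit(df, "time", "event")
        for name in ("x1", "x2"):
            assert model.params[name] == pytest.approx(cph.params_[name], abs=1e-5)
            assert model.bse[name] == pytest.approx(cph.standard_errors_[name], abs=1e-5)

    def test_recovers_generating_log_hazards_within_2_se(self, medium_cohort):
        """Binary, continuous-FP and ordinal effects all recovered."""
        model = fit_cox(medium_cohort, truth_terms())
        for name in ("preeclampsia", "migraine", "age_10", "sbp_100_sq",
                     "gravidity", "townsend", "smoke_current"):
            z = (model.params[name] - np.log(TRUE_HAZARD_RATIOS[name])) / model.bse[name]
            # seven simultaneous checks: 3 SE keeps the joint false-alarm
            # rate near 2% while still catching any real bias
            assert abs(z) < 3.0, f"{name}: z = {z:.2f}"


class TestBreslowBaseline:
    def test_null_model_equals_nelson_aalen_hand_example(self, five_subject_cohort):
        df = five_subject_cohort
        model = fit_cox(df, [], offset=np.zeros(len(df)))
        bl = breslow_baseline(model, horizon=5.0)
        # events at t=1 (5 at risk), t=3 (3 at risk), t=4 (2 at risk)
        expected = np.cumsum([1 / 5, 1 / 3, 1 / 2])
        assert np.allclose(bl.cumhaz, expected, atol=1e-12)
        assert bl.survival_at(0.0) == 1.0
        s = bl.survival_at(np.array([0.5, 1.5, 3.5, 4.5]))
        assert (np.diff(s) < 0).all()

    def test_mean_predicted_risk_matches_km_in_sample(self, medium_censored_cohort):
        df = medium_censored_cohort
        model = fit_cox(df, truth_terms(), estimate_baseline=True, horizon=10.0)
        cs = model.to_coefficient_set("m", 10.0)
        risk = predicted_risk(model.predict_lp(df), cs)
        from ppcvd.validate import km_incidence

        km, _ = km_incidence(df["time"].to_numpy(), df["event"].to_numpy(), 10.0)
        assert risk.mean() == pytest.approx(km, rel=0.05)

    def test_horizon_beyond_last_time_warns(self, five_subject_cohort):
        model = fit_cox(five_subject_cohort, [], offset=np.zeros(5))
        with pytest.warns(RuntimeWarning, match="beyond last observed"):
            breslow_baseline(model, horizon=99.0)


class TestRecalibrateBaseline:
    def test_self_consistency_on_development_data(self, medium_censored_cohort):
        df = medium_censored_cohort
        model = fit_cox(df, truth_terms(), estimate_baseline=True, horizon=10.0)
        cs = model.to_coefficient_set("m", 10.0)
        recal = recalibrate_baseline(model.predict_lp(df), df, cs, horizon=10.0)
        assert recal.baseline_survival == pytest.approx(cs.baseline_survival, abs=1e-6)

    def test_baseline_absorbs_systematic_lp_shift(self, medium_censored_cohort):
        from ppcvd.validate import km_incidence, oe_ratio

        df = medium_censored_cohort
        model = fit_cox(df, truth_terms(), estimate_baseline=True, horizon=10.0)
        cs = model.to_coefficient_set("m", 10.0)
        lp_shifted = model.predict_lp(df).to_numpy() + 0.7
        recal = recalibrate_baseline(lp_shifted, df, cs, horizon=10.0)
        risk = 1 - recal.baseline_survival ** np.exp(lp_shifted - recal.centering)
        oe = oe_ratio(risk, df["time"].to_numpy(), df["event"].to_numpy(), 10.0)
        assert oe.value == pytest.approx(1.0, abs=0.05)


class TestSelectFP:
    @staticmethod
    def _survival_frame(x, lp, seed, rate=0.02):
        time, event = simulate_survival(lp, rate, None, 10.0, np.random.default_rng(seed))
        return pd.DataFrame({"v": x, "time": time, "event": event})

    def test_linear_truth_selects_linear(self, rng):
        x = rng.uniform(1.0, 5.0, 2_500)
        df = self._survival_frame(x, 0.5 * x, seed=5, rate=0.003)
        spec = select_fp(df, "v", alpha=0.05)
        assert spec is not None and tuple(spec.powers) == (1.0,)

    def test_log_truth_selects_power_zero(self, rng):
        x = rng.uniform(0.5, 8.0, 2_500)
        df = self._survival_frame(x, 1.5 * np.log(x), seed=6, rate=0.004)
        spec = select_fp(df, "v", alpha=0.05)
        assert spec is not None and 0.0 in tuple(spec.powers)

    def test_null_effect_is_omitted(self, rng):
        x = rng.uniform(1.0, 5.0, 3_000)
        df = self._survival_frame(x, np.zeros(len(x)), seed=7, rate=0.005)
        assert select_fp(df, "v", alpha=0.05) is None

    def test_alpha_one_returns_full_fp2(self, rng):
        x = rng.uniform(1.0, 5.0, 1_500)
        df = self._survival_frame(x, 0.4 * x, seed=8, rate=0.005)
        spec = select_fp(df, "v", alpha=1.0)
        assert spec is not None and len(spec.powers) == 2

    def test_constant_variable_raises(self):
        df = pd.DataFrame({"v": [2.0] * 50, "time": np.arange(1, 51.0), "event": [1] * 50})
        with pytest.raises(ValueError, match="constant"):
            select_fp(df, "v")


class TestLassoSelect:
    @pytest.fixture(scope="class")
    def selection_cohort(self):
        rng = np.random.default_rng(99)
        n = 20_000
        df = pd.DataFrame(
            {
                "strong": rng.binomial(1, 0.10, n),
                "null1": rng.binomial(1, 0.20, n),
                "null2": rng.normal(size=n),
                "forced_null": rng.binomial(1, 0.30, n),
                "base": rng.normal(size=n),
            }
        )
        lp = 0.8 * df["strong"] + 0.5 * df["base"]
        time, event = simulate_survival(lp.to_numpy(), 0.01, None, 10.0, rng)
        df["time"], df["event"] = time, event
        return df

    def test_huge_penalty_keeps_forced_only(self, selection_cohort):
        forced = [Term("base", "linear", "base"), Term("forced_null", "linear", "forced_null")]
        cand = [Term("strong", "linear", "strong"), Term("null2", "linear", "null2")]
        res = lasso_select(
            selection_cohort, cand, forced, lambda_rule="fixed", alpha=1e6
        )
        assert res.selected == ["base", "forced_null"]

    def test_forced_null_predictor_stays_in_final_model(self, selection_cohort):
        forced = [Term("base", "linear", "base"), Term("forced_null", "linear", "forced_null")]
        cand = [Term("strong", "linear", "strong"), Term("null1", "linear", "null1"),
                Term("null2", "linear", "null2")]
        res = lasso_select(selection_cohort, cand, forced, n_folds=5, seed=3)
        assert "forced_null" in res.selected
        assert "strong" in res.selected  # true HR ~ 2.2 at 10% prevalence

    def test_final_model_is_unpenalised_refit(self, selection_cohort):
        forced = [Term("base", "linear", "base")]
        cand = [Term("strong", "linear", "strong"), Term("null2", "linear", "null2")]
        res = lasso_select(selection_cohort, cand, forced, n_folds=5, seed=3)
        refit = fit_cox(selection_cohort,
                        [t for t in forced + cand if t.name in res.selected])
        pd.testing.assert_series_equal(res.model.params, refit.params)

    def test_empty_candidates_returns_forced(self, selection_cohort):
        forced = [Term("base", "linear", "base")]
        res = lasso_select(selection_cohort, [], forced)
        assert res.selected == ["base"]
        assert res.rule == "no-candidates"

    def test_overlapping_sets_rejected(self, selection_cohort):
        t = Term("base", "linear", "base")
        with pytest.raises(ValueError, match="overlap"):
            lasso_select(selection_cohort, [t], [t])
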