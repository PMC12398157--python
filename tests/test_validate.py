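"""Validation metrics: pseudo-values, concordance, Royston's D, O/E,
pseudo-value calibration, calibration curves and decision curves — each
against an independent oracle or a closed-form/limit property."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ppcvd.cohort import simulate_survival
from ppcvd.validate import (
    calibration_curve,
    calibration_intercept_slope,
    d_to_r2,
    harrell_c,
    km_incidence,
    net_benefit,
    oe_ratio,
    performance_report,
    pseudo_values,
    royston_d,
    subgroup_performance,
    time_dependent_c,
)

# ---------------------------------------------------------------------------
# independent oracles


def km_cuminc_oracle(time, event, horizon):
    """Product-limit cumulative incidence by direct looping."""
    S = 1.0
    for u in np.unique(time[event == 1]):
        if u > horizon:
            break
        d = np.sum((time == u) & (event == 1))
        r = np.sum(time >= u)
        S *= 1 - d / r
    return 1 - S


def pseudo_values_oracle(time, event, horizon):
    """n explicit leave-one-out KM refits."""
    n = len(time)
    F = km_cuminc_oracle(time, event, horizon)
    out = np.empty(n)
    for i in range(n):
        F_i = km_cuminc_oracle(np.delete(time, i), np.delete(event, i), horizon)
        out[i] = n * F - (n - 1) * F_i
    return out


def harrell_oracle(lp, time, event):
    """Exhaustive enumeration over all subject pairs.

    A pair is comparable when the shorter time is an event; with tied
    times, an event subject is comparable against a censored one (the
    censored subject is known to have survived longer), while two tied
    events are excluded.
    """
    conc = disc = tied = 0
    for i, j in itertools.combinations(range(len(lp)), 2):
        a, b = (i, j) if time[i] <= time[j] else (j, i)
        if time[a] == time[b]:
            if event[i] == event[j]:
                continue
            a, b = (i, j) if event[i] == 1 else (j, i)
        elif event[a] == 0:
            continue
        if lp[a] == lp[b]:
            tied += 1
        elif lp[a] > lp[b]:
            conc += 1
        else:
            disc += 1
    return (conc + 0.5 * tied) / (conc + disc + tied)


# ---------------------------------------------------------------------------


class TestPseudoValues:
    def test_hand_example_four_subjects(self):
        # times 2, 4 (censored), 6, 12; horizon 10
        time = np.array([2.0, 4.0, 6.0, 12.0])
        event = np.array([1, 0, 1, 0])
        pv = pseudo_values(time, event, 10.0)
        assert np.allclose(pv, pseudo_values_oracle(time, event, 10.0), atol=1e-10)

    def test_no_censoring_collapses_to_indicator(self, rng):
        time = rng.exponential(6.0, 200)
        event = np.ones(200, dtype=int)
        pv = pseudo_values(time, event, 5.0)
        assert np.allclose(pv, (time <= 5.0).astype(float), atol=1e-12)

    def test_matches_jackknife_oracle_on_random_tied_data(self, rng):
        for _ in range(25):
            n = int(rng.integers(3, 35))
            time = rng.integers(1, 8, n).astype(float)
            event = rng.integers(0, 2, n)
            horizon = float(rng.uniform(1, 9))
            assert np.allclose(
                pseudo_values(time, event, horizon),
                pseudo_values_oracle(time, event, horizon),
                atol=1e-10,
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_mean_equals_km_cumulative_incidence(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(3, 60))
        time = r.exponential(5.0, n).round(1) + 0.1
        event = r.integers(0, 2, n)
        horizon = float(r.uniform(0.5, 12))
        F, _ = km_incidence(time, event, horizon)
        if F == 1.0:  # risk set exhausted by an event: KM degenerate
            return
        assert pseudo_values(time, event, horizon).mean() == pytest.approx(F, abs=1e-10)

    def test_horizon_before_first_time_gives_zeros(self):
        pv = pseudo_values(np.array([2.0, 3.0]), np.array([1, 0]), 1.0)
        assert (pv == 0).all()


class TestHarrellC:
    def test_perfectly_anti_ranked_lp_gives_one(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        lp = -time  # higher risk = shorter survival
        assert harrell_c(lp, time, np.ones(5, int)).value == 1.0

    def test_independent_lp_near_half(self, rng):
        n = 20_000
        time = rng.exponential(5, n)
        event = rng.integers(0, 2, n)
        c = harrell_c(rng.normal(size=n), time, event)
        assert c.value == pytest.approx(0.5, abs=0.02)
        assert c.lo < 0.5 < c.hi

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 30))
            lp = rng.normal(size=n).round(1)  # induce predictor ties
            time = rng.integers(1, 10, n).astype(float)
            event = rng.integers(0, 2, n)
            if not ((event == 1).any() and len(np.unique(time)) > 1):
                continue
            assert harrell_c(lp, time, event).value == pytest.approx(
                harrell_oracle(lp, time, event), abs=1e-12
            )

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c(np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([0, 0]))


class TestTimeDependentC:
    def test_equals_harrell_without_censoring_before_horizon(self, rng):
        n = 3_000
        lp = rng.normal(size=n)
        time, event = simulate_survival(lp, 0.05, None, 30.0, rng)
        horizon = 30.0
        c_td = time_dependent_c(lp, time, event, horizon)
        c_h = harrell_c(lp, time, event)
        assert c_td.value == pytest.approx(c_h.value, abs=0.005)

    def test_perfect_ranking_gives_one(self):
        time = np.linspace(1, 5, 20)
        assert time_dependent_c(-time, time, np.ones(20, int), 10.0).value == 1.0

    def test_all_censored_before_horizon_raises(self):
        with pytest.raises(ValueError, match="no events"):
            time_dependent_c(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                             np.array([0, 0]), 10.0)


class TestRoystonD:
    def test_constant_lp_returns_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            d, r2 = royston_d(np.ones(50), np.arange(1, 51.0), np.ones(50, int))
        assert d.value == 0.0 and r2 == 0.0

    def test_standard_normal_true_lp_gives_d_near_kappa(self, rng):
        # for a correctly specified normal(0,1) prognostic index the
        # expected separation is kappa = sqrt(8/pi) ~ 1.596
        n = 25_000
        lp = rng.normal(size=n)
        time, event = simulate_survival(lp, 0.01, None, 10.0, rng)
        d, r2 = royston_d(lp, time, event)
        assert d.value == pytest.approx(np.sqrt(8 / np.pi), abs=0.12)
        assert r2 == pytest.approx(d_to_r2(d.value))

    def test_r2_identity_properties(self):
        assert d_to_r2(0.0) == 0.0
        d = np.linspace(0, 5, 50)
        r2 = d_to_r2(d)
        assert (np.diff(r2) > 0).all() and (r2 < 1).all()


class TestOERatio:
    def test_equal_predictions_give_unity(self, five_subject_cohort):
        df = five_subject_cohort
        km = km_cuminc_oracle(df["time"].to_numpy(), df["event"].to_numpy(), 5.0)
        oe = oe_ratio(np.full(5, km), df["time"].to_numpy(), df["event"].to_numpy(), 5.0)
        assert oe.value == pytest.approx(1.0, abs=1e-12)

    def test_halving_predictions_doubles_ratio(self, five_subject_cohort):
        df = five_subject_cohort
        t, e = df["time"].to_numpy(), df["event"].to_numpy()
        base = oe_ratio(np.full(5, 0.4), t, e, 5.0).value
        assert oe_ratio(np.full(5, 0.2), t, e, 5.0).value == pytest.approx(2 * base)

    def test_hand_km_over_hand_mean(self, five_subject_cohort):
        df = five_subject_cohort
        t, e = df["time"].to_numpy(), df["event"].to_numpy()
        pred = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        # KM: events at 1 (5 at risk), 3 (3 at risk), 4 (2 at risk)
        km = 1 - (4 / 5) * (2 / 3) * (1 / 2)
        assert oe_ratio(pred, t, e, 5.0).value == pytest.approx(km / 0.3)

    def test_zero_expected_raises(self, five_subject_cohort):
        df = five_subject_cohort
        with pytest.raises(ValueError, match="zero"):
            oe_ratio(np.zeros(5), df["time"].to_numpy(), df["event"].to_numpy(), 5.0)


class TestCalibrationGLM:
    @staticmethod
    def _uncensored(rng, n=60_000):
        p = rng.uniform(0.01, 0.20, n)
        lam = -np.log1p(-p) / 10
        t = rng.exponential(1 / lam)
        e = (t <= 10).astype(int)
        t = np.minimum(t, 10.0)
        pv = pseudo_values(t, e, 10.0)
        return p, pv

    def test_true_predictions_give_identity_calibration(self, rng):
        p, pv = self._uncensored(rng)
        intercept, slope = calibration_intercept_slope(pv, p)
        assert intercept.value == pytest.approx(0.0, abs=0.03)
        assert slope.value == pytest.approx(1.0, abs=0.04)

    @pytest.mark.parametrize("shrink", [0.5, 1.0, 2.0])
    def test_slope_recovers_inverse_of_cloglog_shrinkage(self, rng, shrink):
        from ppcvd.riskeq import cloglog

        p, pv = self._uncensored(rng)
        x = cloglog(p)
        offered = 1 - np.exp(-np.exp(x.mean() + shrink * (x - x.mean())))
        _, slope = calibration_intercept_slope(pv, offered)
        assert slope.value == pytest.approx(1 / shrink, rel=0.08)

    def test_additive_cloglog_shift_moves_intercept(self, rng):
        from ppcvd.riskeq import cloglog

        p, pv = self._uncensored(rng)
        offered = 1 - np.exp(-np.exp(cloglog(p) + 0.3))
        intercept, _ = calibration_intercept_slope(pv, offered)
        # predictions made too high -> negative intercept
        assert intercept.value == pytest.approx(-0.3, abs=0.04)

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError, match="risks"):
            calibration_intercept_slope(np.array([0.0, 1.0]), np.array([-0.1, 0.5]))


class TestCalibrationCurve:
    def test_single_group_point_is_mean_vs_km(self, rng):
        p, pv = TestCalibrationGLM._uncensored(rng, 2_000)
        curve = calibration_curve(p, pv, n_groups=1)
        assert len(curve) == 1
        assert curve.loc[0, "mean_predicted"] == pytest.approx(p.mean())
        assert curve.loc[0, "observed"] == pytest.approx(pv.mean())

    def test_well_calibrated_points_near_diagonal(self, rng):
        p, pv = TestCalibrationGLM._uncensored(rng)
        curve = calibration_curve(p, pv, n_groups=10)
        assert len(curve) == 10
        assert (curve["n"].max() - curve["n"].min()) <= 1
        inside = (curve["obs_lo"] <= curve["mean_predicted"]) & (
            curve["mean_predicted"] <= curve["obs_hi"]
        )
        assert inside.sum() >= 8

    def test_heavy_ties_merge_groups_with_warning(self):
        p = np.repeat([0.1, 0.2], 50)
        pv = np.zeros(100)
        with pytest.warns(RuntimeWarning, match="merg"):
            curve = calibration_curve(p, pv, n_groups=10)
        assert len(curve) == 2


class TestNetBenefit:
    def test_treat_none_is_identically_zero(self, rng):
        p = rng.uniform(0, 0.2, 500)
        t = rng.exponential(8, 500)
        e = rng.integers(0, 2, 500)
        dc = net_benefit(p, t, e, 10.0)
        assert (dc.treat_none == 0).all()
        assert (np.diff(dc.thresholds) > 0).all()

    def test_treat_all_limit_is_km_incidence(self, rng):
        t = rng.exponential(8, 2_000)
        e = np.ones(2_000, int)
        p = rng.uniform(0, 1, 2_000)
        dc = net_benefit(p, t, e, 10.0, np.array([0.001]))
        km, _ = km_incidence(t, e, 10.0)
        assert dc.treat_all[0] == pytest.approx(km, abs=0.002)

    def test_perfect_binary_predictor_dominates_treat_all(self, rng):
        n = 30_000
        sick = rng.uniform(size=n) < 0.3
        lam = np.where(sick, 0.2, 0.002)
        t = np.minimum(rng.exponential(1 / lam), 10.0)
        e = (t < 10.0).astype(int)
        p = np.where(sick, 0.9, 0.01)
        km, _ = km_incidence(t, e, 10.0)
        grid = np.arange(0.05, 0.90, 0.05)
        dc = net_benefit(p, t, e, 10.0, grid)
        above = grid > km
        assert (dc.model[above] >= dc.treat_all[above]).all()
        assert (dc.model[above] > dc.treat_all[above]).any()

    def test_thresholds_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="strictly inside"):
            net_benefit(np.array([0.1]), np.array([1.0]), np.array([1]), 10.0,
                        np.array([0.0, 0.5]))


class TestSubgroupsAndReport:
    @pytest.fixture(scope="class")
    def scored_cohort(self):
        rng = np.random.default_rng(55)
        n = 8_000
        x = rng.normal(size=n)
        group = rng.choice(["a", "b"], n)
        time, event = simulate_survival(0.8 * x, 0.01, None, 10.0, rng)
        df = pd.DataFrame({"x": x, "group": group, "time": time, "event": event})
        risk = 1 - 0.99 ** np.exp(0.8 * x)
        return df, 0.8 * x, risk

    def test_single_group_equals_overall(self, scored_cohort):
        df, lp, risk = scored_cohort
        df = df.assign(all="everyone")
        sub = subgroup_performance(df, lp, risk, "all")
        overall = performance_report(df, lp, risk)
        assert sub["everyone"].harrell_c.value == overall.harrell_c.value
        assert sub["everyone"].oe.value == overall.oe.value

    def test_group_event_counts_partition_overall(self, scored_cohort):
        df, lp, risk = scored_cohort
        sub = subgroup_performance(df, lp, risk, "group")
        assert sum(r.n_events for r in sub.values()) == int(df["event"].sum())

    def test_small_group_flagged_low_information(self, scored_cohort):
        df, lp, risk = scored_cohort
        # engineer a group holding just a handful of events
        events_idx = df.index[df["event"] == 1][:4]
        label = np.where(df.index.isin(events_idx), "rare", "common")
        df2 = df.assign(group2=label)
        df2.loc[(df2["group2"] == "rare") & ~df2.index.isin(events_idx), "group2"] = "common"
        sub = subgroup_performance(df2, lp, risk, "group2")
        assert sub["rare"] is None or sub["rare"].low_information

    def test_metrics_invariant_to_row_order(self, scored_cohort):
        df, lp, risk = scored_cohort
        perm = np.random.default_rng(0).permutation(len(df))
        a = performance_report(df, lp, risk)
        b = performance_report(
            df.iloc[perm].reset_index(drop=True), lp[perm], risk[perm]
        )
        assert a.harrell_c.value == pytest.approx(b.harrell_c.value, abs=1e-12)
        assert a.oe.value == pytest.approx(b.oe.value, abs=1e-12)
        assert a.slope.value == pytest.approx(b.slope.value, abs=1e-8)
        assert a.royston_d.value == pytest.approx(b.royston_d.value, abs=1e-6)
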