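"""Threshold detection, spline fitting, aggregation and AUC."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from greendose.model import (
    GroupCurve,
    ThresholdResult,
    aggregate_group,
    compute_auc,
    detect_thresholds,
    detect_thresholds_on_grid,
    dose_grid,
    fit_curve,
    results_table,
    run_phe_analysis,
    trapezoid_auc,
)
from greendose.spectral import IndexSeries


def brute_force_thresholds(t, gain, dgain, kappa, delta):
    """Independent oracle: plain-loop grid search for ET and BT."""
    max_rate = max(dgain)
    max_gain = max(gain)
    et = bt = None
    for ti, d in zip(t, dgain):
        if d >= kappa * max_rate:
            et = ti
            break
    for ti, g in zip(t, gain):
        if et is not None and ti >= et and g >= (1 - delta) * max_gain:
            bt = ti
            break
    return et, bt


def make_series(values_by_participant, environment="UP", condition="OE",
                index="rel_alpha", valid=None):
    """IndexSeries stubs sharing a 40-window grid, one value stream each."""
    t = 0.25 + 0.5 * np.arange(40)
    out = []
    for p, vals in enumerate(values_by_participant):
        frame = pd.DataFrame({
            "window": np.arange(40), "t_mid_min": t,
            "phase": np.where(t < 4.0, "stress", "exposure"),
            "valid": True if valid is None else valid[p],
        })
        for name in ("rel_theta", "rel_alpha", "rel_beta", "beta_alpha",
                     "rel_alpha_theta"):
            frame[name] = vals if name == index else 0.5
        out.append(IndexSeries(participant=f"P{p}", environment=environment,
                               condition=condition, frame=frame))
    return out


class TestTrapezoidAuc:
    def test_constant_curve(self):
        t = dose_grid()
        assert trapezoid_auc(t, np.ones_like(t)) == pytest.approx(16.0)

    def test_linear_curve_is_exact(self):
        t = np.arange(0, 2.001, 0.5)
        assert trapezoid_auc(t, t) == pytest.approx(2.0, abs=1e-12)

    def test_quadratic_known_trapezoid_value(self):
        t = np.arange(0, 1.001, 0.25)
        assert trapezoid_auc(t, t**2) == pytest.approx(0.34375, abs=1e-12)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    def test_linearity(self, a, b):
        t = np.linspace(0, 5, 21)
        f, g = np.sin(t), np.cos(t)
        lhs = trapezoid_auc(t, a * f + b * g)
        rhs = a * trapezoid_auc(t, f) + b * trapezoid_auc(t, g)
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_interval_additivity(self):
        t = np.linspace(0, 8, 33)
        y = np.exp(-t / 3)
        whole = trapezoid_auc(t, y)
        split = trapezoid_auc(t[:17], y[:17]) + trapezoid_auc(t[16:], y[16:])
        assert whole == pytest.approx(split, abs=1e-12)

    @pytest.mark.parametrize("h", [0.5, 0.25, 0.125])
    def test_error_within_h_squared_bound(self, h):
        a, b = 0.0, 4.0
        t = np.arange(a, b + h / 2, h)
        est = trapezoid_auc(t, np.sin(t))
        exact = np.cos(a) - np.cos(b)
        assert abs(est - exact) <= (b - a) * h**2 * 1.0 / 12 + 1e-12

    def test_non_increasing_grid_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            trapezoid_auc([0, 0, 1], [1, 1, 1])


class TestDetectThresholds:
    def test_logistic_oracle_exact(self):
        """ET/BT on a logistic gain match plain-loop enumeration exactly."""
        t = dose_grid()
        sig = expit(t - 12.0)
        gain = sig - sig[0]
        dgain = sig * (1 - sig)
        et_bf, bt_bf = brute_force_thresholds(t, gain, dgain, 0.5, 0.05)
        assert (et_bf, bt_bf) == (10.5, 15.0)
        et, bt, flags = detect_thresholds_on_grid(t, gain, dgain, 0.5, 0.05)
        assert (et, bt) == (et_bf, bt_bf)
        assert "no_recovery" not in flags

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(t_mid=st.floats(6.0, 18.0), slope=st.floats(0.3, 4.0),
           kappa=st.floats(0.1, 0.9), delta=st.floats(0.01, 0.3))
    def test_matches_brute_force_for_any_logistic(self, t_mid, slope, kappa, delta):
        t = dose_grid()
        sig = expit(slope * (t - t_mid))
        gain = sig - sig[0]
        dgain = slope * sig * (1 - sig)
        expected = brute_force_thresholds(t, gain, dgain, kappa, delta)
        et, bt, _ = detect_thresholds_on_grid(t, gain, dgain, kappa, delta)
        assert (et, bt) == expected
        assert et <= bt

    def test_worsening_curve_flags_no_recovery(self):
        t = dose_grid()
        gain = -0.1 * (t - t[0])
        et, bt, flags = detect_thresholds_on_grid(t, gain, np.gradient(gain, t))
        assert (et, bt) == (None, None)
        assert flags == ("no_recovery",)

    def test_boundary_start_flagged(self):
        t = dose_grid()
        gain = 1 - np.exp(-(t - 4.0))  # steepest at the phase boundary
        dgain = np.exp(-(t - 4.0))
        et, _, flags = detect_thresholds_on_grid(t, gain, dgain)
        assert et == 4.0
        assert "et_at_boundary" in flags

    def test_invalid_kappa_delta(self):
        t = dose_grid()
        with pytest.raises(ValueError, match="kappa"):
            detect_thresholds_on_grid(t, t, t, kappa=1.5)
        with pytest.raises(ValueError, match="delta"):
            detect_thresholds_on_grid(t, t, t, delta=0.0)


class TestFitCurve:
    def _curve(self, values, index="rel_alpha", direction=+1):
        t = 0.25 + 0.5 * np.arange(40)
        return GroupCurve(environment="UP", condition="OE", index=index,
                          t=t, mean=np.asarray(values), sd=np.zeros(40),
                          n=np.full(40, 5), baseline=float(np.mean(values[:8])),
                          direction=direction)

    def test_noiseless_logistic_reproduced(self):
        t = 0.25 + 0.5 * np.arange(40)
        y = 0.25 + 0.2 * expit(t - 12.0)
        curve = fit_curve(self._curve(y))
        truth = 0.25 + 0.2 * expit(curve.grid - 12.0)
        assert np.max(np.abs(curve.fitted - truth)) < 0.01

    def test_constant_input_flat_fit(self):
        curve = fit_curve(self._curve(np.full(40, 0.3)))
        np.testing.assert_allclose(curve.fitted, 0.3, atol=1e-9)
        np.testing.assert_allclose(curve.derivative, 0.0, atol=1e-9)

    def test_linear_input_recovers_slope(self):
        t = 0.25 + 0.5 * np.arange(40)
        curve = fit_curve(self._curve(0.1 + 0.02 * t))
        interior = (curve.grid > 5) & (curve.grid < 19)
        np.testing.assert_allclose(curve.derivative[interior], 0.02, rtol=0.02)

    def test_too_few_exposure_points_rejected(self):
        t = np.array([1.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0])
        curve = GroupCurve(environment="UP", condition="OE", index="rel_alpha",
                           t=t, mean=np.zeros(7), sd=np.zeros(7), n=np.ones(7),
                           baseline=0.0, direction=+1)
        with pytest.raises(ValueError, match=">= 8"):
            fit_curve(curve)


class TestAggregateGroup:
    def test_identical_participants_average_to_themselves(self):
        t = 0.25 + 0.5 * np.arange(40)
        vals = 0.3 + 0.01 * t
        series = make_series([vals, vals])
        curve = aggregate_group(series, "UP", "OE", "rel_alpha")
        np.testing.assert_allclose(curve.mean, vals)
        assert np.all(curve.n == 2)

    def test_pointwise_exclusion_of_invalid_windows(self):
        t = 0.25 + 0.5 * np.arange(40)
        a, b = np.full(40, 0.2), np.full(40, 0.4)
        valid_a = np.ones(40, bool)
        valid_a[t == 6.25] = False
        series = make_series([a, b], valid=[valid_a, np.ones(40, bool)])
        curve = aggregate_group(series, "UP", "OE", "rel_alpha")
        i = int(np.nonzero(t == 6.25)[0][0])
        assert curve.n[i] == 1
        assert curve.mean[i] == pytest.approx(0.4)
        assert curve.mean[i - 1] == pytest.approx(0.3)

    def test_boundary_gap_is_an_error(self):
        bad = np.ones(40, bool)
        bad[0] = False
        series = make_series([np.full(40, 0.2)] * 2, valid=[bad, bad])
        with pytest.raises(ValueError, match="boundary"):
            aggregate_group(series, "UP", "OE", "rel_alpha")

    def test_single_participant_group_rejected(self):
        series = make_series([np.full(40, 0.2)])
        with pytest.raises(ValueError, match="at least 2"):
            aggregate_group(series, "UP", "OE", "rel_alpha")

    def test_baseline_is_stress_phase_mean(self):
        t = 0.25 + 0.5 * np.arange(40)
        vals = np.where(t < 4.0, 0.2, 0.6)
        curve = aggregate_group(make_series([vals, vals]), "UP", "OE", "rel_alpha")
        assert curve.baseline == pytest.approx(0.2)


class TestComputeAucAndSymmetry:
    def _fitted(self, values, direction=+1):
        curve = TestFitCurve()._curve(values, direction=direction)
        return fit_curve(curve)

    def test_constant_offset_auc(self):
        curve = self._fitted(np.full(40, 0.3))
        curve.baseline = -0.7  # fitted - baseline == 1 on [4, 20]
        assert compute_auc(curve) == pytest.approx(16.0, abs=1e-6)

    def test_out_of_grid_interval_rejected(self):
        curve = self._fitted(np.full(40, 0.3))
        with pytest.raises(ValueError, match="outside"):
            compute_auc(curve, 2.0, 20.0)

    def test_direction_symmetry(self):
        """Negating the indicator and flipping d preserves ET/BT, negates AUC."""
        t = 0.25 + 0.5 * np.arange(40)
        y = 0.25 + 0.2 * expit(t - 12.0)
        up = detect_thresholds(self._fitted(y, direction=+1))
        down = detect_thresholds(self._fitted(-y, direction=-1))
        assert up.et_min == down.et_min and up.bt_min == down.bt_min
        assert up.auc == pytest.approx(-down.auc, abs=1e-9)


class TestRunPheAnalysis:
    @pytest.fixture(scope="class")
    def cohort_series(self):
        t = 0.25 + 0.5 * np.arange(40)
        rng = np.random.default_rng(0)
        series = []
        for env, t_mid in (("UP", 8.0), ("RF", 12.0), ("WP", 10.0)):
            base = {
                "rel_alpha": 0.25 + 0.2 * expit(np.maximum(t, 4.0) - t_mid),
                "rel_beta": 0.60 - 0.25 * expit(np.maximum(t, 4.0) - t_mid),
            }
            base["beta_alpha"] = base["rel_beta"] / base["rel_alpha"]
            base["rel_alpha_theta"] = 1 - base["rel_beta"]
            for p in range(4):
                frame = pd.DataFrame({
                    "window": np.arange(40), "t_mid_min": t,
                    "phase": np.where(t < 4.0, "stress", "exposure"), "valid": True,
                })
                for k, v in base.items():
                    frame[k] = v + rng.normal(0, 0.003, 40)
                frame["rel_theta"] = 1 - frame["rel_alpha"] - frame["rel_beta"]
                series.append(IndexSeries(participant=f"{env}{p}", environment=env,
                                          condition="OE", frame=frame))
        return series

    def test_cardinality_three_envs_four_indices(self, cohort_series):
        results, _ = run_phe_analysis(cohort_series)
        assert len(results) == 12
        tab = results_table(results)
        assert set(tab["environment"]) == {"UP", "RF", "WP"}
        assert len(tab) == 12

    def test_et_never_after_bt(self, cohort_series):
        results, _ = run_phe_analysis(cohort_series)
        for r in results:
            if r.et_min is not None and r.bt_min is not None:
                assert r.et_min <= r.bt_min

    def test_environment_ordering_follows_recovery_midpoints(self, cohort_series):
        results, _ = run_phe_analysis(cohort_series)
        et = {r.environment: r.et_min for r in results if r.index == "rel_alpha"}
        assert et["UP"] < et["RF"]
        assert et["UP"] <= et["WP"] <= et["RF"]

    def test_deterministic(self, cohort_series):
        a, _ = run_phe_analysis(cohort_series)
        b, _ = run_phe_analysis(cohort_series)
        assert results_table(a).equals(results_table(b))


def test_threshold_result_invariants():
    with pytest.raises(ValueError, match="ET"):
        ThresholdResult("UP", "OE", "rel_alpha", et_min=10.0, bt_min=5.0,
                        auc=0.0, kappa=0.5, delta=0.05)
    with pytest.raises(ValueError, match="no_recovery"):
        ThresholdResult("UP", "OE", "rel_alpha", et_min=5.0, bt_min=None,
                        auc=0.0, kappa=0.5, delta=0.05, flags=("no_recovery",))
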