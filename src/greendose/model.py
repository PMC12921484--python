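"""Dose-response threshold model for stress-recovery trajectories.

The model takes group-level EEG index trajectories on the 30-s grid and asks
two questions about the exposure phase (4-20 min): *when does recovery become
efficient* and *when do benefits plateau*. Both thresholds are read off a
smooth fitted curve of the beneficial gain

    g(t) = d * (f(t) - f(t_0)),   t_0 = exposure start,

where ``d`` is the beneficial direction of the index (+1 when larger is
better, e.g. relative alpha; -1 when smaller is better, e.g. relative beta).

* Efficiency threshold (ET): earliest dose-grid point where the marginal gain
  g'(t) reaches a fraction ``kappa`` (default 0.5) of its maximum over the
  phase — the onset of rapid recovery.
* Benefit threshold (BT): earliest point at or after ET where the cumulative
  gain reaches ``(1 - delta)`` (default 0.95) of its maximum — the start of
  the plateau of diminishing returns.

The cumulative restoration volume is the signed trapezoidal area under the
baseline-subtracted indicator over the exposure window (AUC); the baseline is
the stress-phase (0-4 min) mean, so indices that stay below their stressed
level integrate to a negative area.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .spectral import INDEX_NAMES, IndexSeries

#: Beneficial direction per index: +1 = increase is restorative.
INDEX_DIRECTION = {
    "rel_alpha": +1,        # relaxation
    "rel_beta": -1,         # stress
    "beta_alpha": -1,       # alertness; lower = calmer
    "rel_alpha_theta": +1,  # cognitive depth
}

DOSE_GRID_STEP_MIN = 0.5


def dose_grid(start_min: float = 4.0, end_min: float = 20.0,
              step_min: float = DOSE_GRID_STEP_MIN) -> np.ndarray:
    """Uniform grid on which thresholds are searched (endpoints included)."""
    n = int(round((end_min - start_min) / step_min))
    return start_min + step_min * np.arange(n + 1)


@dataclasses.dataclass
class GroupCurve:
    """Aggregated trajectory of one index for one (environment, condition) group.

    ``t`` holds the 30-s window midpoints (minutes); ``mean``/``sd``/``n`` are
    the pointwise statistics over participants (invalid windows excluded
    pointwise). After :func:`fit_curve`, ``grid``/``fitted``/``derivative``
    hold the smooth curve on the uniform dose grid.
    """

    environment: str
    condition: str
    index: str
    t: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    baseline: float
    direction: int
    stress_end_min: float = 4.0
    session_min: float = 20.0
    interpolated: np.ndarray | None = None
    grid: np.ndarray | None = None
    fitted: np.ndarray | None = None
    derivative: np.ndarray | None = None
    smoothing_lam: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time grid must be strictly increasing")
        if self.direction not in (-1, +1):
            raise ValueError(f"direction must be +/-1, got {self.direction}")


@dataclasses.dataclass
class ThresholdResult:
    """ET/BT/AUC for one (environment, condition, index) cell."""

    environment: str
    condition: str
    index: str
    et_min: float | None
    bt_min: float | None
    auc: float
    kappa: float
    delta: float
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.et_min is not None and self.bt_min is not None:
            if not self.et_min <= self.bt_min:
                raise ValueError(f"ET={self.et_min} > BT={self.bt_min}")
        if "no_recovery" in self.flags and (self.et_min is not None or self.bt_min is not None):
            raise ValueError("no_recovery result must not carry thresholds")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["flags"] = list(self.flags)
        return d


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate_group(series: Iterable[IndexSeries], environment: str, condition: str,
                    index: str) -> GroupCurve:
    """Pointwise mean trajectory over participants of one group.

    Invalid windows are excluded per grid point (not per participant); interior
    points left with n = 0 are linearly interpolated and flagged, boundary
    points with n = 0 raise (no basis for extrapolation).
    """
    if index not in INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}; expected one of {INDEX_NAMES}")
    members = [s for s in series
               if s.environment == environment and s.condition == condition
               and not s.excluded]
    if not members:
        raise ValueError(f"no usable participants for group ({environment}, {condition})")
    if len(members) < 2:
        raise ValueError(
            f"group ({environment}, {condition}) has {len(members)} usable participant(s); "
            "need at least 2"
        )
    t = members[0].frame["t_mid_min"].to_numpy()
    for s in members[1:]:
        if not np.array_equal(s.frame["t_mid_min"].to_numpy(), t):
            raise ValueError("participants are not on a common window grid")
    values = np.full((len(members), len(t)), np.nan)
    for i, s in enumerate(members):
        v = s.frame[index].to_numpy(dtype=float)
        valid = s.frame["valid"].to_numpy(dtype=bool)
        values[i, valid] = v[valid]
    n = np.sum(~np.isnan(values), axis=0)
    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN / ddof slices
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1) if len(members) > 1 else np.zeros_like(mean)
    missing = n == 0
    if missing[0] or missing[-1]:
        raise ValueError(
            f"group ({environment}, {condition}, {index}): boundary grid point has no "
            "valid data; cannot extrapolate"
        )
    if missing.any():
        mean[missing] = np.interp(t[missing], t[~missing], mean[~missing])
        sd[missing] = np.nan
    stress_end = members[0].stress_end_min
    stress = t < stress_end
    if not stress.any():
        raise ValueError("no stress-phase windows; cannot form baseline")
    baseline = float(np.mean(mean[stress]))
    return GroupCurve(
        environment=environment, condition=condition, index=index,
        t=t, mean=mean, sd=sd, n=n, baseline=baseline,
        direction=INDEX_DIRECTION[index],
        stress_end_min=stress_end, session_min=members[0].session_min,
        interpolated=missing,
    )


# ---------------------------------------------------------------------------
# smooth fit
# ---------------------------------------------------------------------------

def fit_curve(curve: GroupCurve, lam: float | None = None) -> GroupCurve:
    """Fit a cubic smoothing spline to the exposure-phase trajectory.

    ``lam=None`` selects the smoothing penalty by generalized cross-validation.
    Fitted values and the analytic spline derivative are stored on the uniform
    0.5-min dose grid spanning the exposure phase; the spline extrapolates the
    quarter-window from the first/last midpoint to the phase boundaries.
    """
    exp = curve.t >= curve.stress_end_min
    t_exp, y_exp = curve.t[exp], curve.mean[exp]
    if len(t_exp) < 8:
        raise ValueError(f"need >= 8 exposure-phase grid points, got {len(t_exp)}")
    rng_y = float(np.ptp(y_exp))
    if rng_y < 1e-12:
        # constant trajectory: GCV is degenerate, the answer is exact anyway
        spline = make_smoothing_spline(t_exp, y_exp, lam=1.0)
    else:
        spline = make_smoothing_spline(t_exp, y_exp, lam=lam)
    grid = dose_grid(curve.stress_end_min, curve.session_min)
    fitted = spline(grid)
    deriv = spline.derivative()(grid)
    resid = y_exp - spline(t_exp)
    if rng_y > 1e-12 and abs(float(np.mean(resid))) > 0.01 * rng_y:
        raise RuntimeError("spline fit is biased: |mean residual| exceeds 1% of range")
    curve.grid, curve.fitted, curve.derivative = grid, fitted, deriv
    curve.smoothing_lam = lam
    return curve


# ---------------------------------------------------------------------------
# threshold detection
# ---------------------------------------------------------------------------

def detect_thresholds_on_grid(
    t: np.ndarray, gain: np.ndarray, dgain: np.ndarray,
    kappa: float = 0.5, delta: float = 0.05, min_gain: float = 0.0,
) -> tuple[float | None, float | None, tuple[str, ...]]:
    """Threshold rules on an explicit (already direction-applied) gain curve.

    Returns ``(et, bt, flags)``. ``gain`` must be zero at ``t[0]`` (the phase
    boundary); ``dgain`` is its derivative on the same grid. ``min_gain`` is a
    detection floor: a maximum gain at or below it counts as no recovery
    (callers working with noisy group curves pass a standard-error floor).
    """
    t = np.asarray(t, dtype=float)
    gain = np.asarray(gain, dtype=float)
    dgain = np.asarray(dgain, dtype=float)
    if not 0 < kappa < 1:
        raise ValueError(f"kappa must be in (0, 1), got {kappa}")
    if not 0 < delta < 1:
        raise ValueError(f"delta must be in (0, 1), got {delta}")
    flags: list[str] = []
    max_gain = float(np.max(gain))
    if max_gain <= max(min_gain, 0.0):
        return None, None, ("no_recovery",)
    max_rate = float(np.max(dgain))
    if max_rate <= 0:
        return None, None, ("no_recovery",)
    if np.min(dgain) < -0.05 * max_rate:
        flags.append("non_monotone")
    et_idx = int(np.argmax(dgain >= kappa * max_rate))
    et = float(t[et_idx])
    if et_idx == 0:
        flags.append("et_at_boundary")
    bt_candidates = np.nonzero((t >= et) & (gain >= (1.0 - delta) * max_gain))[0]
    bt = float(t[bt_candidates[0]]) if len(bt_candidates) else float(t[-1])
    return et, bt, tuple(flags)


def recovery_gain_floor(curve: GroupCurve, alpha: float = 0.01) -> float:
    """Null bound for the maximum beneficial gain of a flat trajectory.

    Under no recovery, the observed gain at each window is the difference of
    two noisy group means (variance 2.SE^2) and the detection takes a maximum
    over the m exposure windows; with SD estimated from n participants the
    normal quantile is further inflated to its Student-t counterpart. The
    floor is

        t_{1-alpha, n-1} / z_{1-alpha} . sqrt(2) . sqrt(2 ln m) . median SE

    and is zero when the group scatter is zero (noise-free input).
    """
    from scipy import stats

    exp = curve.t >= curve.stress_end_min
    with np.errstate(invalid="ignore", divide="ignore"):
        se = curve.sd[exp] / np.sqrt(np.maximum(curve.n[exp], 1))
    if not np.any(np.isfinite(se)):
        return 0.0
    med_se = float(np.nanmedian(se))
    m = max(int(exp.sum()), 2)
    n_min = max(int(np.min(curve.n[exp])), 2)
    t_infl = stats.t.ppf(1 - alpha, n_min - 1) / stats.norm.ppf(1 - alpha)
    return t_infl * np.sqrt(2.0) * np.sqrt(2.0 * np.log(m)) * med_se


def detect_thresholds(curve: GroupCurve, kappa: float = 0.5,
                      delta: float = 0.05) -> ThresholdResult:
    """Apply the ET/BT rules to a fitted group curve.

    A recovery is declared only when the maximum gain clears the statistical
    floor of :func:`recovery_gain_floor`; below it the curve is
    indistinguishable from a flat trajectory at the group's noise level.
    """
    if curve.fitted is None or curve.derivative is None:
        raise ValueError("curve has no fitted values; call fit_curve first")
    d = curve.direction
    gain = d * (curve.fitted - curve.fitted[0])
    dgain = d * curve.derivative
    et, bt, flags = detect_thresholds_on_grid(curve.grid, gain, dgain, kappa, delta,
                                              min_gain=recovery_gain_floor(curve))
    auc = compute_auc(curve)
    return ThresholdResult(
        environment=curve.environment, condition=curve.condition, index=curve.index,
        et_min=et, bt_min=bt, auc=auc, kappa=kappa, delta=delta, flags=flags,
    )


def trapezoid_auc(t: Sequence[float], y: Sequence[float]) -> float:
    """Signed trapezoidal integral of ``y`` over ``t`` (exact for linear data)."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t and y must be 1-D arrays of equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t must be strictly increasing")
    return float(np.trapezoid(y, t))


def compute_auc(curve: GroupCurve, a: float | None = None, b: float | None = None) -> float:
    """Trapezoidal area of the baseline-subtracted fitted curve over [a, b].

    Baseline is the stress-phase mean of the observed trajectory, so the sign
    records whether the index sat above (+) or below (-) its stressed level.
    """
    if curve.fitted is None:
        raise ValueError("curve has no fitted values; call fit_curve first")
    a = curve.stress_end_min if a is None else float(a)
    b = curve.session_min if b is None else float(b)
    if not a < b:
        raise ValueError(f"need a < b, got a={a}, b={b}")
    lo, hi = float(curve.grid[0]), float(curve.grid[-1])
    if a < lo - 1e-9 or b > hi + 1e-9:
        raise ValueError(f"[{a}, {b}] outside the fitted grid [{lo}, {hi}]")
    sel = (curve.grid >= a - 1e-9) & (curve.grid <= b + 1e-9)
    return trapezoid_auc(curve.grid[sel], curve.fitted[sel] - curve.baseline)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def run_phe_analysis(
    series: Sequence[IndexSeries],
    kappa: float = 0.5,
    delta: float = 0.05,
    lam: float | None = None,
    indices: Sequence[str] = INDEX_NAMES,
) -> tuple[list[ThresholdResult], dict[tuple[str, str, str], GroupCurve]]:
    """One ThresholdResult per (environment, condition, index) present in ``series``."""
    groups = sorted({(s.environment, s.condition) for s in series if not s.excluded})
    if not groups:
        raise ValueError("no usable (environment, condition) groups in input")
    results: list[ThresholdResult] = []
    curves: dict[tuple[str, str, str], GroupCurve] = {}
    for env, cond in groups:
        for index in indices:
            try:
                curve = aggregate_group(series, env, cond, index)
                fit_curve(curve, lam=lam)
                res = detect_thresholds(curve, kappa=kappa, delta=delta)
            except (ValueError, RuntimeError) as exc:
                raise RuntimeError(f"group ({env}, {cond}), index {index}: {exc}") from exc
            results.append(res)
            curves[(env, cond, index)] = curve
    return results, curves


def results_table(results: Sequence[ThresholdResult]) -> pd.DataFrame:
    """Long-format table: one row per (index, environment, condition) cell."""
    rows = []
    for r in results:
        rows.append({
            "index": r.index, "environment": r.environment, "condition": r.condition,
            "ET_min": r.et_min, "BT_min": r.bt_min, "AUC": r.auc,
            "kappa": r.kappa, "delta": r.delta, "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)


def results_wide_table(results: Sequence[ThresholdResult]) -> pd.DataFrame:
    """Report layout: rows = index, column triples (ET, BT, AUC) per environment."""
    long = results_table(results)
    wide = long.pivot_table(
        index=["index", "condition"], columns="environment",
        values=["ET_min", "BT_min", "AUC"], aggfunc="first", sort=False,
    )
    wide = wide.swaplevel(axis=1).sort_index(axis=1, level=0, sort_remaining=False)
    return wide


def write_results(results: Sequence[ThresholdResult], out_dir: str | Path,
                  stem: str = "thresholds") -> dict[str, Path]:
    """Serialize results as CSV (long), CSV (wide) and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    long = results_table(results)
    paths["csv"] = out_dir / f"{stem}.csv"
    long.to_csv(paths["csv"], index=False)
    paths["wide_csv"] = out_dir / f"{stem}_wide.csv"
    results_wide_table(results).to_csv(paths["wide_csv"])
    paths["json"] = out_dir / f"{stem}.json"
    paths["json"].write_text(json.dumps([r.to_dict() for r in results], indent=2))
    return paths


def export_curve_diagnostics(curves: dict[tuple[str, str, str], GroupCurve],
                             out_dir: str | Path) -> Path:
    """Per-curve grid/mean/fitted/derivative export for plotting."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (env, cond, index), c in curves.items():
        for i, t in enumerate(c.t):
            rows.append({"environment": env, "condition": cond, "index": index,
                         "kind": "observed", "t_min": t, "value": c.mean[i],
                         "sd": c.sd[i], "n": int(c.n[i])})
        if c.grid is not None:
            for i, t in enumerate(c.grid):
                rows.append({"environment": env, "condition": cond, "index": index,
                             "kind": "fitted", "t_min": t, "value": c.fitted[i],
                             "sd": np.nan, "n": np.nan,
                             "derivative": c.derivative[i]})
    path = Path(out_dir) / "curve_diagnostics.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
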