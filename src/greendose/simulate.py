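"""Synthetic EEG cohort generator with analytically known recovery dynamics.

Each simulated session reproduces the two-phase protocol: a stress-induction
phase (0-4 min) with elevated beta activity, then an exposure phase
(4-20 min) during which the relative band-power composition relaxes along a
logistic trajectory toward a recovered asymptote. The signal itself is a sum
of three band-limited Gaussian noise processes (4-8, 8-13, 13-32 Hz), each
amplitude-modulated so its instantaneous relative power tracks the band
envelope, plus optional artifacts: frontal raised-cosine blink transients,
50 Hz line noise and rare > 100 uV spikes.

Because the population envelope is analytic, ground-truth efficiency/benefit
thresholds and AUC are computed exactly (:func:`true_thresholds`) under the
*same* detection rules the model module applies to estimated curves — the
basis of every parameter-recovery test.

The exposure logistic is anchored at the phase boundary,

    g(t) = (sigma(s (t - t_mid)) - sigma_0) / (1 - sigma_0),
    sigma_0 = sigma(s (t_stress_end - t_mid)),

so the envelope is exactly continuous at 4 min, rises from the stress level
and approaches the asymptote; all three band envelopes share t_mid and slope,
hence sum to one at every instant by construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .model import (INDEX_DIRECTION, ThresholdResult, detect_thresholds_on_grid,
                    dose_grid, trapezoid_auc)
from .recording import DEFAULT_CHANNELS, FRONTAL_CHANNELS, RawRecording, SessionMeta
from .spectral import INDEX_NAMES

BAND_EDGES = {"theta": (4.0, 8.0), "alpha": (8.0, 13.0), "beta": (13.0, 32.0)}


@dataclasses.dataclass(frozen=True)
class TrajectoryParams:
    """Piecewise band-power envelope: constant stress level, logistic recovery.

    ``stress_levels`` and ``asymptote_levels`` are (theta, alpha, beta)
    fraction triples, each summing to 1; ``t_mid`` (min) and ``slope``
    (1/min) are shared across bands.
    """

    stress_levels: tuple[float, float, float] = (0.15, 0.25, 0.60)
    asymptote_levels: tuple[float, float, float] = (0.20, 0.45, 0.35)
    t_mid: float = 12.0
    slope: float = 1.0

    def __post_init__(self) -> None:
        for name, levels in (("stress", self.stress_levels),
                             ("asymptote", self.asymptote_levels)):
            if len(levels) != 3:
                raise ValueError(f"{name}_levels must be a (theta, alpha, beta) triple")
            if not all(0 < v < 1 for v in levels):
                raise ValueError(f"{name}_levels must lie in (0, 1), got {levels}")
            if abs(sum(levels) - 1.0) > 1e-9:
                raise ValueError(f"{name}_levels must sum to 1, got {sum(levels)!r}")
        if not (np.isfinite(self.t_mid) and np.isfinite(self.slope)):
            raise ValueError("t_mid and slope must be finite")
        if self.slope <= 0:
            raise ValueError(f"slope must be > 0, got {self.slope}")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Cohort-level generator parameters (the study conditions).

    Noise/jitter defaults emulate a realistic field recording: broadband
    sensor noise on a ~20 uV RMS scalp signal, between-participant spread in
    recovery timing and depth, ~8 blinks/min, mild 50 Hz pickup and rare
    motion spikes.
    """

    n_participants: int = 20
    environment: str = "UP"
    condition: str = "OE"
    sampling_rate: float = 128.0
    session_min: float = 20.0
    stress_end_min: float = 4.0
    trajectory: TrajectoryParams = TrajectoryParams()
    t_mid_jitter_sd: float = 1.5          # min
    level_jitter_sd: float = 0.10         # log-space SD on asymptote levels
    noise_sd_uv: float = 5.0              # additive broadband sensor noise
    signal_rms_uv: float = 20.0           # RMS of the structured EEG signal
    blink_rate_per_min: float = 8.0
    blink_amp_uv: float = 200.0
    line_noise_uv: float = 5.0
    line_noise_hz: float = 50.0
    spike_prob_per_window: float = 0.02
    spike_amp_uv: float = 150.0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.sampling_rate not in (128.0, 256.0, 128, 256):
            raise ValueError(f"unsupported sampling rate {self.sampling_rate}; use 128 or 256")
        if self.session_min <= self.stress_end_min:
            raise ValueError("session must extend past the stress phase")
        for name in ("t_mid_jitter_sd", "level_jitter_sd", "noise_sd_uv",
                     "blink_rate_per_min", "blink_amp_uv", "line_noise_uv",
                     "spike_prob_per_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.signal_rms_uv <= 0:
            raise ValueError("signal_rms_uv must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trajectory"] = dataclasses.asdict(self.trajectory)
        d["channel_names"] = list(self.channel_names)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        traj = d.pop("trajectory", {})
        for key in ("stress_levels", "asymptote_levels"):
            if key in traj:
                traj[key] = tuple(traj[key])
        d["trajectory"] = TrajectoryParams(**traj)
        if "channel_names" in d:
            d["channel_names"] = tuple(d["channel_names"])
        return cls(**d)


# ---------------------------------------------------------------------------
# analytic envelopes
# ---------------------------------------------------------------------------

def _anchored_logistic(t: np.ndarray, t_mid: float, slope: float,
                       stress_end: float) -> tuple[np.ndarray, np.ndarray]:
    """Transition function g in [0, 1) with g(stress_end) = 0, and its derivative."""
    t = np.asarray(t, dtype=float)
    sig = expit(slope * (t - t_mid))
    sig0 = expit(slope * (stress_end - t_mid))
    g = np.where(t <= stress_end, 0.0, (sig - sig0) / (1.0 - sig0))
    dg = np.where(t <= stress_end, 0.0, slope * sig * (1.0 - sig) / (1.0 - sig0))
    return g, dg


def band_envelope(params: TrajectoryParams, t, stress_end_min: float = 4.0,
                  session_min: float = 20.0) -> np.ndarray:
    """Band-fraction triple(s) at time(s) ``t`` (minutes).

    Returns shape (3,) for scalar ``t`` or (3, len(t)); rows are
    (theta, alpha, beta), each in (0, 1), summing to 1, constant over the
    stress phase and continuous at the phase boundary.
    """
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0) or np.any(t_arr > session_min):
        raise ValueError(
            f"t must lie within the session interval [0, {session_min}] min"
        )
    g, _ = _anchored_logistic(t_arr, params.t_mid, params.slope, stress_end_min)
    levels = np.asarray(params.stress_levels)[:, None]
    asym = np.asarray(params.asymptote_levels)[:, None]
    env = levels + (asym - levels) * g[None, :]
    return env[:, 0] if scalar else env


def band_envelope_derivative(params: TrajectoryParams, t, stress_end_min: float = 4.0,
                             session_min: float = 20.0) -> np.ndarray:
    """Time derivative (1/min) of each band envelope; same shape rules as above."""
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0) or np.any(t_arr > session_min):
        raise ValueError(f"t must lie within the session interval [0, {session_min}] min")
    _, dg = _anchored_logistic(t_arr, params.t_mid, params.slope, stress_end_min)
    levels = np.asarray(params.stress_levels)[:, None]
    asym = np.asarray(params.asymptote_levels)[:, None]
    denv = (asym - levels) * dg[None, :]
    return denv[:, 0] if scalar else denv


def index_envelope(params: TrajectoryParams, t, index: str,
                   stress_end_min: float = 4.0,
                   session_min: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Analytic (value, derivative) of one EEG index along the envelope."""
    if index not in INDEX_NAMES:
        raise ValueError(f"unknown index {index!r}")
    f = band_envelope(params, t, stress_end_min, session_min)
    df = band_envelope_derivative(params, t, stress_end_min, session_min)
    th, al, be = f
    dth, dal, dbe = df
    if index == "rel_alpha":
        return al, dal
    if index == "rel_beta":
        return be, dbe
    if index == "rel_alpha_theta":
        return th + al, dth + dal
    # beta/alpha ratio, quotient rule
    return be / al, (dbe * al - be * dal) / al**2


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _participant_rng(spec: CohortSpec, participant_index: int) -> np.random.Generator:
    """Substream derived from the master seed by participant offset only."""
    ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(participant_index,))
    return np.random.default_rng(ss)


def participant_trajectory(spec: CohortSpec, participant_index: int,
                           rng: np.random.Generator) -> TrajectoryParams:
    """Jittered per-participant trajectory: t_mid and asymptote levels only.

    Asymptote jitter acts multiplicatively in log space with renormalisation,
    which preserves positivity and the sum-to-one constraint.
    """
    traj = spec.trajectory
    t_mid = traj.t_mid + rng.normal(0.0, spec.t_mid_jitter_sd)
    t_mid = float(np.clip(t_mid, spec.stress_end_min + 0.5, spec.session_min - 0.5))
    asym = np.asarray(traj.asymptote_levels)
    if spec.level_jitter_sd > 0:
        asym = asym * np.exp(rng.normal(0.0, spec.level_jitter_sd, size=3))
        asym = asym / asym.sum()
    return TrajectoryParams(
        stress_levels=traj.stress_levels,
        asymptote_levels=tuple(float(v) for v in asym),
        t_mid=t_mid, slope=traj.slope,
    )


def _band_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise confined to ``band`` (per channel).

    Synthesized in the frequency domain (independent complex-Gaussian Fourier
    coefficients on the in-band bins, zero elsewhere), i.e. ideally filtered
    white noise — a stationary Gaussian process with a flat in-band spectrum.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    sel = (freqs >= band[0]) & (freqs < band[1])
    n_sel = int(sel.sum())
    if n_sel == 0:
        raise ValueError(f"band {band} contains no Fourier bins at fs={fs}, n={n}")
    coeffs = np.zeros((n_ch, len(freqs)), dtype=complex)
    draws = rng.standard_normal((n_ch, n_sel, 2))
    coeffs[:, sel] = draws[..., 0] + 1j * draws[..., 1]
    x = np.fft.irfft(coeffs, n=n, axis=-1)
    stds = x.std(axis=-1, keepdims=True)
    if np.any(stds < 1e-12):
        raise ValueError(f"zero-variance band process for band {band}")
    return x / stds


def synthesize_recording(spec: CohortSpec, participant_index: int,
                         return_artifacts: bool = False):
    """One participant's full-session multichannel recording in microvolts.

    Deterministic: the same (spec, participant_index) always yields the same
    matrix, independent of generation order. With ``return_artifacts=True``
    also returns a dict of injected artifact events (blink intervals in
    seconds, spike windows) for ground-truth artifact tests.
    """
    if not 0 <= participant_index < spec.n_participants:
        raise ValueError(
            f"participant_index {participant_index} out of range "
            f"[0, {spec.n_participants})"
        )
    fs = float(spec.sampling_rate)
    n = int(round(spec.session_min * 60 * fs))
    n_ch = len(spec.channel_names)
    rng = _participant_rng(spec, participant_index)
    traj = participant_trajectory(spec, participant_index, rng)
    t_min = np.arange(n) / fs / 60.0
    env = band_envelope(traj, t_min, spec.stress_end_min, spec.session_min)

    data = np.zeros((n_ch, n))
    for k, band in enumerate(BAND_EDGES.values()):
        noise = _band_noise(rng, n_ch, n, fs, band)
        data += noise * np.sqrt(env[k])[None, :]
    data *= spec.signal_rms_uv

    if spec.noise_sd_uv > 0:
        data += rng.normal(0.0, spec.noise_sd_uv, size=(n_ch, n))
    if spec.line_noise_uv > 0:
        phases = rng.uniform(0, 2 * np.pi, size=n_ch)
        t_s = np.arange(n) / fs
        data += spec.line_noise_uv * np.sin(
            2 * np.pi * spec.line_noise_hz * t_s[None, :] + phases[:, None]
        )
    artifacts = {"blinks_s": [], "spike_windows": []}
    if spec.blink_rate_per_min > 0 and spec.blink_amp_uv > 0:
        artifacts["blinks_s"] = _add_blinks(data, spec, rng, fs, n)
    if spec.spike_prob_per_window > 0 and spec.spike_amp_uv > 0:
        artifacts["spike_windows"] = _add_spikes(data, spec, rng, fs, n, n_ch)

    meta = SessionMeta(
        participant=f"{spec.environment}-{spec.condition}-P{participant_index:03d}",
        environment=spec.environment, condition=spec.condition,
        stress_end_min=spec.stress_end_min, session_min=spec.session_min,
    )
    rec = RawRecording(data=data, sampling_rate=fs,
                       channel_names=spec.channel_names, meta=meta)
    return (rec, artifacts) if return_artifacts else rec


def _add_blinks(data: np.ndarray, spec: CohortSpec, rng: np.random.Generator,
                fs: float, n: int) -> list[tuple[float, float]]:
    """Raised-cosine blink transients (0.2-0.5 s) on the frontal channels.

    Returns the (start_s, end_s) interval of every injected blink.
    """
    frontal_idx = [i for i, c in enumerate(spec.channel_names) if c in FRONTAL_CHANNELS]
    if not frontal_idx:
        return []
    events = []
    n_blinks = rng.poisson(spec.blink_rate_per_min * spec.session_min)
    for _ in range(n_blinks):
        dur_s = rng.uniform(0.2, 0.5)
        width = max(int(round(dur_s * fs)), 3)
        start = int(rng.integers(0, max(n - width, 1)))
        amp = spec.blink_amp_uv * rng.uniform(0.75, 1.25)
        shape = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / (width - 1)))
        gains = rng.uniform(0.8, 1.0, size=len(frontal_idx))
        for g, ch in zip(gains, frontal_idx):
            data[ch, start:start + width] += g * amp * shape
        events.append((start / fs, (start + width) / fs))
    return events


def _add_spikes(data: np.ndarray, spec: CohortSpec, rng: np.random.Generator,
                fs: float, n: int, n_ch: int, window_s: float = 30.0) -> list[int]:
    """Rare short transients exceeding the +/-100 uV rejection threshold.

    Returns the indices of the 30-s windows that received a spike.
    """
    per_win = int(round(window_s * fs))
    n_windows = int(np.ceil(n / per_win))
    shape = np.array([0.5, 1.0, 0.5])
    hit = []
    for w in range(n_windows):
        if rng.uniform() >= spec.spike_prob_per_window:
            continue
        ch = int(rng.integers(0, n_ch))
        lo = w * per_win
        hi = min((w + 1) * per_win, n) - len(shape)
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        # spike polarity follows the underlying sample so magnitudes add and
        # the window is guaranteed to exceed the threshold
        sign = 1.0 if data[ch, pos + 1] >= 0 else -1.0
        data[ch, pos:pos + 3] += sign * spec.spike_amp_uv * shape
        hit.append(w)
    return hit


def synthesize_cohort(spec: CohortSpec) -> list[RawRecording]:
    return [synthesize_recording(spec, i) for i in range(spec.n_participants)]


# ---------------------------------------------------------------------------
# analytic ground truth
# ---------------------------------------------------------------------------

def population_index_envelope(spec: CohortSpec, t: np.ndarray, index: str,
                              n_quad: int = 41) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free population envelope of an index: the expected participant
    trajectory under the cohort's between-participant t_mid jitter.

    The downstream estimator averages participant index values pointwise, so
    the quantity it estimates is E[I_i(t)] over the jitter distribution —
    computed here by Gauss-Hermite quadrature on t_mid (with the same clipping
    the generator applies). With zero jitter this reduces to the single
    analytic trajectory. Asymptote-level jitter is mean-preserving to second
    order in its (small) SD and is not marginalized.
    """
    if spec.t_mid_jitter_sd == 0:
        return index_envelope(spec.trajectory, t, index,
                              spec.stress_end_min, spec.session_min)
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    weights = weights / weights.sum()
    value = np.zeros_like(np.asarray(t, dtype=float))
    deriv = np.zeros_like(value)
    for x, w in zip(nodes, weights):
        t_mid = float(np.clip(spec.trajectory.t_mid + spec.t_mid_jitter_sd * x,
                              spec.stress_end_min + 0.5, spec.session_min - 0.5))
        traj = dataclasses.replace(spec.trajectory, t_mid=t_mid)
        v, dv = index_envelope(traj, t, index, spec.stress_end_min, spec.session_min)
        value += w * v
        deriv += w * dv
    return value, deriv


def true_thresholds(spec: CohortSpec, index: str, kappa: float = 0.5,
                    delta: float = 0.05, grid_step_min: float = 0.5) -> ThresholdResult:
    """Ground-truth ET/BT/AUC of the noise-free population envelope.

    Evaluates the analytic (jitter-marginalized) index envelope and its
    derivative on the uniform exposure dose grid and applies the identical
    detection rules used on fitted curves, so recovery tests compare like
    with like.
    """
    grid = dose_grid(spec.stress_end_min, spec.session_min, grid_step_min)
    value, deriv = population_index_envelope(spec, grid, index)
    d = INDEX_DIRECTION[index]
    gain = d * (value - value[0])
    dgain = d * deriv
    et, bt, flags = detect_thresholds_on_grid(grid, gain, dgain, kappa, delta)
    baseline, _ = population_index_envelope(spec, np.zeros(1), index)
    auc = trapezoid_auc(grid, value - float(baseline[0]))
    return ThresholdResult(
        environment=spec.environment, condition=spec.condition, index=index,
        et_min=et, bt_min=bt, auc=auc, kappa=kappa, delta=delta, flags=flags,
    )


# ---------------------------------------------------------------------------
# cohort export
# ---------------------------------------------------------------------------

def write_cohort(spec: CohortSpec, out_dir: str | Path,
                 indices: Sequence[str] = INDEX_NAMES) -> dict:
    """Write one delimited recording per participant plus a ground-truth sidecar.

    Returns a manifest dict (also written as ``manifest.json``) with SHA-256
    checksums of every file.
    """
    from .recording import write_delimited
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for i in range(spec.n_participants):
        rec = synthesize_recording(spec, i)
        path = out_dir / f"{rec.meta.participant}.tsv"
        write_delimited(rec, path)
        files.append(path)
        files.append(path.with_suffix(path.suffix + ".json"))
    truth = {idx: true_thresholds(spec, idx).to_dict() for idx in indices}
    sidecar = out_dir / "cohort_spec.json"
    sidecar.write_text(json.dumps(
        {"spec": spec.to_dict(), "ground_truth": truth}, indent=2))
    files.append(sidecar)
    manifest = {
        str(p.relative_to(out_dir)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in files
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
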