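"""Spectral feature extraction: band powers and EEG indices on the 30-s grid.

Band powers are estimated per 30-s window by an averaged tapered periodogram
(Welch, 4-s Hann segments, 50% overlap; a raw single-FFT periodogram is kept
behind ``method="fft"``). Relative power of a band is its integrated density
divided by the total over 4-32 Hz, with half-open band bins [low, high) so
that 13 Hz counts as beta. Four indices are derived per window:

* ``rel_alpha``   — relative alpha power (relaxation),
* ``rel_beta``    — relative beta power (stress),
* ``beta_alpha``  — beta/alpha ratio (alertness; band fractions share the
  total-power denominator, so the fraction ratio equals the power ratio),
* ``rel_alpha_theta`` — relative alpha+theta power (cognitive depth). Under
  the default 4-32 Hz total this is identically ``1 - rel_beta``; the
  identity is asserted, not hidden, and changing the total band in
  :class:`BandDefinition` breaks it deliberately.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import RejectionMask
from .recording import RawRecording, SessionMeta

logger = logging.getLogger(__name__)

INDEX_NAMES = ("rel_alpha", "rel_beta", "beta_alpha", "rel_alpha_theta")
BAND_NAMES = ("theta", "alpha", "beta")


@dataclasses.dataclass(frozen=True)
class BandDefinition:
    """Frequency-band layout. Bands must tile [total_low, total_high) exactly."""

    theta: tuple[float, float] = (4.0, 8.0)
    alpha: tuple[float, float] = (8.0, 13.0)
    beta: tuple[float, float] = (13.0, 32.0)

    def __post_init__(self) -> None:
        edges = [*self.theta, *self.alpha, *self.beta]
        if self.theta[1] != self.alpha[0] or self.alpha[1] != self.beta[0]:
            raise ValueError(f"bands must tile contiguously, got {edges}")
        for lo, hi in (self.theta, self.alpha, self.beta):
            if not lo < hi:
                raise ValueError(f"band low must be < high, got ({lo}, {hi})")

    @property
    def total(self) -> tuple[float, float]:
        return (self.theta[0], self.beta[1])

    def items(self):
        return zip(BAND_NAMES, (self.theta, self.alpha, self.beta))


def window_psd(rec: RawRecording, window_index: int, window_s: float = 30.0,
               method: str = "welch", segment_s: float = 4.0,
               mask: RejectionMask | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Power spectral density of one 30-s window, per channel.

    Returns ``(freqs, psd)`` with ``psd`` of shape (channels, freqs) in
    uV^2/Hz. Satisfies Parseval approximately: the integrated density matches
    the window variance to within a few percent.
    """
    if mask is not None and mask.flags[window_index]:
        raise ValueError(
            f"window {window_index} was rejected ({mask.reasons[window_index]}); skip it"
        )
    fs = rec.sampling_rate
    per_win = int(round(window_s * fs))
    start = window_index * per_win
    stop = min(start + per_win, rec.n_samples)
    if start >= rec.n_samples:
        raise IndexError(f"window {window_index} outside recording")
    x = rec.data[:, start:stop]
    if method == "welch":
        nperseg = min(int(round(segment_s * fs)), x.shape[1])
        freqs, psd = signal.welch(x, fs=fs, window="hann", nperseg=nperseg,
                                  noverlap=nperseg // 2, detrend="constant", axis=-1)
    elif method == "fft":
        freqs, psd = signal.periodogram(x, fs=fs, window="boxcar",
                                        detrend="constant", axis=-1)
    else:
        raise ValueError(f"unknown PSD method {method!r}; use 'welch' or 'fft'")
    return freqs, psd


def relative_band_powers(freqs: np.ndarray, psd: np.ndarray,
                         bands: BandDefinition = BandDefinition()) -> np.ndarray:
    """Band-fraction triple (theta, alpha, beta) from a PSD.

    2-D ``psd`` (channels x freqs) is aggregated by averaging absolute band
    powers across channels before normalising. Half-open bins [low, high).
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.atleast_2d(np.asarray(psd, dtype=float))
    lo, hi = bands.total
    if freqs[0] > lo or freqs[-1] < hi - (freqs[1] - freqs[0]):
        raise ValueError(f"PSD grid [{freqs[0]}, {freqs[-1]}] does not cover {bands.total}")
    powers = np.empty(3)
    for k, (_, (b_lo, b_hi)) in enumerate(bands.items()):
        sel = (freqs >= b_lo) & (freqs < b_hi)
        powers[k] = float(np.mean(np.sum(psd[:, sel], axis=1)))
    total = powers.sum()
    if total <= 0:
        raise ValueError("total 4-32 Hz power is zero; relative power undefined")
    return powers / total


def compute_indices(fractions: Sequence[float]) -> dict[str, float]:
    """The four EEG indices from a (theta, alpha, beta) fraction triple."""
    f_theta, f_alpha, f_beta = (float(v) for v in fractions)
    for v in (f_theta, f_alpha, f_beta):
        if not 0 <= v <= 1 or not math.isfinite(v):
            raise ValueError(f"band fractions must lie in [0, 1], got {fractions}")
    if abs(f_theta + f_alpha + f_beta - 1.0) > 1e-6:
        raise ValueError(f"band fractions must sum to 1, got {fractions}")
    if f_alpha == 0 and f_beta > 0:
        raise ValueError("alpha power is zero; beta/alpha ratio undefined")
    return {
        "rel_alpha": f_alpha,
        "rel_beta": f_beta,
        "beta_alpha": f_beta / f_alpha if f_alpha > 0 else 0.0,
        "rel_alpha_theta": f_alpha + f_theta,
    }


@dataclasses.dataclass
class IndexSeries:
    """Per-participant index trajectory on the 30-s grid.

    ``frame`` has one row per window: t_mid_min, phase, valid, the three band
    fractions and the four indices (NaN on invalid windows).
    """

    participant: str
    environment: str
    condition: str
    frame: pd.DataFrame
    stress_end_min: float = 4.0
    session_min: float = 20.0
    excluded: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.frame)

    def valid_fraction(self) -> float:
        return float(self.frame["valid"].mean())

    def to_long(self) -> pd.DataFrame:
        """Long-format export: one row per (window, index)."""
        rows = self.frame.melt(
            id_vars=["t_mid_min", "phase", "valid"],
            value_vars=list(INDEX_NAMES), var_name="index", value_name="value",
        )
        rows.insert(0, "participant", self.participant)
        rows.insert(1, "environment", self.environment)
        rows.insert(2, "condition", self.condition)
        return rows


def series_to_csv(series: Sequence[IndexSeries], path: str | Path) -> Path:
    path = Path(path)
    pd.concat([s.to_long() for s in series], ignore_index=True).to_csv(path, index=False)
    return path


def series_from_csv(path: str | Path, stress_end_min: float = 4.0,
                    session_min: float = 20.0) -> list[IndexSeries]:
    long = pd.read_csv(path)
    out = []
    for (part, env, cond), sub in long.groupby(
            ["participant", "environment", "condition"], sort=False):
        wide = sub.pivot(index="t_mid_min", columns="index", values="value")
        labels = sub.drop_duplicates("t_mid_min")[["t_mid_min", "phase", "valid"]]
        frame = labels.merge(wide.reset_index(), on="t_mid_min")
        frame = frame.sort_values("t_mid_min").reset_index(drop=True)
        frame.insert(0, "window", np.arange(len(frame)))
        # band fractions are derivable but not round-tripped; keep index columns
        s = IndexSeries(participant=str(part), environment=env, condition=cond,
                        frame=frame, stress_end_min=stress_end_min,
                        session_min=session_min)
        s.excluded = s.valid_fraction() < 0.5
        out.append(s)
    return out


def build_index_series(rec: RawRecording, mask: RejectionMask | None = None,
                       bands: BandDefinition = BandDefinition(),
                       window_s: float = 30.0, method: str = "welch",
                       channels: Sequence[str] | None = None) -> IndexSeries:
    """Window-by-window indices for one recording (channel-averaged).

    Invalid windows (amplitude-rejected, or degenerate spectra) are flagged,
    not dropped, so every participant stays on the same rectangular grid. A
    participant with more than half the windows invalid is marked ``excluded``.
    """
    fs = rec.sampling_rate
    n_windows = math.ceil(rec.n_samples / (window_s * fs))
    if mask is not None and len(mask.flags) != n_windows:
        raise ValueError(
            f"rejection mask covers {len(mask.flags)} windows, recording has {n_windows}"
        )
    sub = rec
    if channels is not None:
        idx = [rec.channel_index(c) for c in channels]
        sub = RawRecording(rec.data[idx], fs, tuple(channels), rec.meta)
    meta: SessionMeta = rec.meta
    # batch the PSDs of all complete windows in one call; a partial tail
    # window (if any) goes through the per-window path
    per_win = int(round(window_s * fs))
    n_full = sub.n_samples // per_win
    batch_psd = None
    if n_full > 0 and method == "welch":
        stacked = sub.data[:, :n_full * per_win].reshape(sub.n_channels, n_full, per_win)
        nperseg = min(int(round(4.0 * fs)), per_win)
        batch_freqs, batch_psd = signal.welch(
            stacked, fs=fs, window="hann", nperseg=nperseg,
            noverlap=nperseg // 2, detrend="constant", axis=-1)
    rows = []
    for w in range(n_windows):
        t_mid = (w + 0.5) * window_s / 60.0
        phase = "stress" if t_mid < meta.stress_end_min else "exposure"
        row = {"window": w, "t_mid_min": t_mid, "phase": phase, "valid": True,
               "rel_theta": np.nan, "rel_alpha": np.nan, "rel_beta": np.nan,
               "beta_alpha": np.nan, "rel_alpha_theta": np.nan}
        if mask is not None and mask.flags[w]:
            row["valid"] = False
            rows.append(row)
            continue
        try:
            if batch_psd is not None and w < n_full:
                freqs, psd = batch_freqs, batch_psd[:, w, :]
            else:
                freqs, psd = window_psd(sub, w, window_s=window_s, method=method)
            fr = relative_band_powers(freqs, psd, bands)
            indices = compute_indices(fr)
        except (ValueError, IndexError):
            row["valid"] = False
            rows.append(row)
            continue
        row.update(rel_theta=fr[0], **indices)
        rows.append(row)
    frame = pd.DataFrame(rows)
    series = IndexSeries(
        participant=meta.participant, environment=meta.environment,
        condition=meta.condition, frame=frame,
        stress_end_min=meta.stress_end_min, session_min=meta.session_min,
    )
    if series.valid_fraction() < 0.5:
        series.excluded = True
        logger.warning("participant %s: %.0f%% of windows invalid; flagged for exclusion",
                       meta.participant, 100 * (1 - series.valid_fraction()))
    return series
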