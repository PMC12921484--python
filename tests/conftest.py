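"""Shared fixtures: small synthetic recordings and cohort specs."""

import numpy as np
import pytest

from greendose.recording import DEFAULT_CHANNELS, RawRecording, SessionMeta
from greendose.simulate import CohortSpec, TrajectoryParams


def make_sine_recording(freq_hz: float, amp_uv: float = 1.0, fs: float = 128.0,
                        duration_s: float = 60.0, n_channels: int = 2,
                        phase: float = 0.0) -> RawRecording:
    t = np.arange(int(duration_s * fs)) / fs
    x = amp_uv * np.sin(2 * np.pi * freq_hz * t + phase)
    data = np.tile(x, (n_channels, 1))
    return RawRecording(
        data=data, sampling_rate=fs,
        channel_names=DEFAULT_CHANNELS[:n_channels],
        meta=SessionMeta(session_min=duration_s / 60.0),
    )


@pytest.fixture(scope="session")
def clean_spec() -> CohortSpec:
    """Noise-, jitter- and artifact-free cohort: the analytic envelope is the
    only structure in the signal."""
    return CohortSpec(
        n_participants=2, environment="UP", condition="OE",
        t_mid_jitter_sd=0.0, level_jitter_sd=0.0, noise_sd_uv=0.0,
        blink_rate_per_min=0.0, line_noise_uv=0.0, spike_prob_per_window=0.0,
        channel_names=DEFAULT_CHANNELS[:4], seed=11,
    )


@pytest.fixture(scope="session")
def default_traj() -> TrajectoryParams:
    return TrajectoryParams()
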