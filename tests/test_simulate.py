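"""Synthetic cohort generator: envelopes, determinism, artifacts, ground truth."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from greendose.model import dose_grid
from greendose.preprocess import FilterConfig, reject_amplitude_windows
from greendose.simulate import (
    CohortSpec,
    TrajectoryParams,
    band_envelope,
    synthesize_recording,
    true_thresholds,
    write_cohort,
)
from greendose.spectral import build_index_series


class TestBandEnvelope:
    def test_stress_phase_is_constant_at_stress_levels(self):
        params = TrajectoryParams(stress_levels=(0.15, 0.25, 0.60))
        for t in (0.0, 1.0, 3.9):
            np.testing.assert_allclose(band_envelope(params, t), (0.15, 0.25, 0.60))

    def test_logistic_midpoint_near_midway(self):
        params = TrajectoryParams(asymptote_levels=(0.20, 0.45, 0.35), t_mid=12.0, slope=1.0)
        alpha_mid = band_envelope(params, 12.0)[1]
        midway = (params.stress_levels[1] + 0.45) / 2
        assert abs(alpha_mid - midway) < 1e-3

    def test_logistic_tail_reaches_asymptote(self):
        params = TrajectoryParams(t_mid=10.0, slope=2.0)
        alpha_end = band_envelope(params, 20.0)[1]
        assert abs(alpha_end - params.asymptote_levels[1]) < 1e-8

    def test_continuous_at_phase_boundary(self):
        params = TrajectoryParams(t_mid=6.0, slope=3.0)
        left = band_envelope(params, 4.0 - 1e-9)
        right = band_envelope(params, 4.0 + 1e-9)
        np.testing.assert_allclose(left, right, atol=1e-6)

    def test_out_of_session_time_names_interval(self):
        with pytest.raises(ValueError, match=r"\[0, 20"):
            band_envelope(TrajectoryParams(), 25.0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(t_mid=st.floats(5.0, 18.0), slope=st.floats(0.2, 5.0))
    def test_fractions_sum_to_one_on_any_grid(self, t_mid, slope):
        params = TrajectoryParams(t_mid=t_mid, slope=slope)
        t = np.linspace(0, 20, 101)
        env = band_envelope(params, t)
        np.testing.assert_allclose(env.sum(axis=0), 1.0, atol=1e-9)
        assert np.all((env > 0) & (env < 1))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            TrajectoryParams(stress_levels=(0.2, 0.2, 0.2))
        with pytest.raises(ValueError, match="slope"):
            TrajectoryParams(slope=0.0)


class TestSynthesizeRecording:
    def test_determinism_bit_identical(self, clean_spec):
        a = synthesize_recording(clean_spec, 1)
        b = synthesize_recording(clean_spec, 1)
        assert np.array_equal(a.data, b.data)

    def test_different_participants_differ(self, clean_spec):
        a = synthesize_recording(clean_spec, 0)
        b = synthesize_recording(clean_spec, 1)
        assert not np.array_equal(a.data, b.data)

    def test_shape_and_units(self, clean_spec):
        rec = synthesize_recording(clean_spec, 0)
        assert rec.data.shape == (4, int(20 * 60 * 128))
        assert np.all(np.isfinite(rec.data))
        assert 5 < rec.data.std() < 60  # plausible scalp-EEG amplitude

    def test_envelope_recovered_by_spectral_chain(self, clean_spec):
        """Round trip: windowed relative band powers track the analytic envelope."""
        rec = synthesize_recording(clean_spec, 0)
        series = build_index_series(rec)
        mid = series.frame["t_mid_min"].to_numpy()
        env = band_envelope(clean_spec.trajectory, mid)
        for k, col in enumerate(("rel_theta", "rel_alpha", "rel_beta")):
            mae = np.mean(np.abs(series.frame[col].to_numpy() - env[k]))
            assert mae < 0.05, f"{col}: MAE {mae:.3f}"

    def test_forced_spikes_exceed_rejection_threshold(self):
        spec = CohortSpec(n_participants=1, spike_prob_per_window=1.0,
                          blink_rate_per_min=0.0, line_noise_uv=0.0,
                          channel_names=("AF3", "AF4"), seed=5)
        rec = synthesize_recording(spec, 0)
        mask = reject_amplitude_windows(rec, FilterConfig())
        assert mask.flags.all()

    def test_artifact_log_matches_signal(self):
        spec = CohortSpec(n_participants=1, blink_rate_per_min=4.0,
                          spike_prob_per_window=0.0, noise_sd_uv=0.0,
                          line_noise_uv=0.0, seed=3)
        rec, artifacts = synthesize_recording(spec, 0, return_artifacts=True)
        assert len(artifacts["blinks_s"]) > 0
        fs = rec.sampling_rate
        frontal = rec.channel_index("AF3")
        for start_s, end_s in artifacts["blinks_s"][:10]:
            seg = rec.data[frontal, int(start_s * fs):int(end_s * fs)]
            assert np.max(np.abs(seg)) > 100  # blink transient dominates

    def test_participant_index_out_of_range(self, clean_spec):
        with pytest.raises(ValueError, match="out of range"):
            synthesize_recording(clean_spec, 99)

    def test_unsupported_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling rate"):
            CohortSpec(sampling_rate=100.0)


class TestTrueThresholds:
    def test_matches_brute_force_on_jitter_free_logistic(self, clean_spec):
        """Frozen oracle: grid enumeration of the logistic derivative gives
        ET = 10.5 and BT = 15.0 for t_mid = 12, s = 1, kappa 0.5, delta 0.05."""
        res = true_thresholds(clean_spec, "rel_alpha", kappa=0.5, delta=0.05)
        assert res.et_min == 10.5
        assert res.bt_min == 15.0

    def test_constant_envelope_has_zero_auc_and_no_recovery(self):
        flat = TrajectoryParams(stress_levels=(0.15, 0.25, 0.60),
                                asymptote_levels=(0.15, 0.25, 0.60))
        spec = CohortSpec(trajectory=flat, t_mid_jitter_sd=0.0)
        res = true_thresholds(spec, "rel_alpha")
        assert res.auc == pytest.approx(0.0, abs=1e-12)
        assert "no_recovery" in res.flags
        assert res.et_min is None and res.bt_min is None

    @pytest.mark.parametrize("index", ["rel_alpha", "rel_beta", "beta_alpha",
                                       "rel_alpha_theta"])
    def test_et_not_after_bt_on_monotone_logistic(self, clean_spec, index):
        res = true_thresholds(clean_spec, index)
        assert res.et_min is not None and res.et_min <= res.bt_min

    def test_jitter_marginalisation_widens_transition(self, clean_spec):
        """Between-participant t_mid spread flattens the population curve, so
        its plateau (BT) arrives later than the single-participant one."""
        import dataclasses
        jittered = dataclasses.replace(clean_spec, t_mid_jitter_sd=2.0)
        bt_sharp = true_thresholds(clean_spec, "rel_alpha").bt_min
        bt_wide = true_thresholds(jittered, "rel_alpha").bt_min
        assert bt_wide >= bt_sharp

    def test_thresholds_lie_on_dose_grid(self, clean_spec):
        grid = dose_grid()
        res = true_thresholds(clean_spec, "beta_alpha")
        assert res.et_min in grid and res.bt_min in grid


class TestWriteCohort:
    def test_files_and_manifest(self, tmp_path):
        spec = CohortSpec(n_participants=3, session_min=5.0,
                          channel_names=("AF3", "AF4"), seed=2)
        manifest = write_cohort(spec, tmp_path)
        tsvs = sorted(tmp_path.glob("*.tsv"))
        assert len(tsvs) == 3
        assert (tmp_path / "cohort_spec.json").exists()
        assert (tmp_path / "manifest.json").exists()
        # identical spec => identical checksums
        manifest2 = write_cohort(spec, tmp_path / "again")
        assert manifest == manifest2

    def test_roundtrip_through_delimited_text(self, tmp_path):
        from greendose.recording import read_delimited
        spec = CohortSpec(n_participants=1, session_min=5.0,
                          channel_names=("AF3", "AF4"), seed=2)
        write_cohort(spec, tmp_path)
        rec = synthesize_recording(spec, 0)
        back = read_delimited(next(tmp_path.glob("*.tsv")))
        assert back.channel_names == rec.channel_names
        assert back.sampling_rate == rec.sampling_rate
        assert back.meta.environment == rec.meta.environment
        np.testing.assert_allclose(back.data, rec.data, atol=5e-4)  # %.4f text
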