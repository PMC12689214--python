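"""Epoch cleaning: detrending, ocular rejection, bad channels, CSD."""

import numpy as np
import pytest

from tagshift import _sphspline
from tagshift.preprocess import (
    clean_epochs,
    csd_transform,
    detect_and_interpolate_bad_channels,
    detrend_epochs,
    reject_ocular,
)
from tagshift.simulate import inject_artifacts


class TestDetrend:
    def test_pure_line_maps_to_zero(self):
        t = np.arange(100, dtype=float)
        epochs = np.stack([[2.0 + 0.3 * t, -1.0 + 0.05 * t]])
        out = detrend_epochs(epochs)
        assert np.abs(out).max() < 1e-10

    def test_full_period_tag_sinusoid_nearly_preserved(self):
        # a full-period sinusoid is close to orthogonal to a line; the
        # residual coupling of the discrete fit scales as 1/frequency and
        # stays below 2 % at the lowest tag frequency
        t = np.arange(768, dtype=float) / 256.0
        sig = np.sin(2 * np.pi * 18 * t)
        out = detrend_epochs(sig[None, None, :])
        assert np.abs(out[0, 0] - sig).max() < 0.02

    def test_removed_slope_matches_least_squares_oracle(self):
        rng = np.random.default_rng(0)
        t = np.arange(200, dtype=float)
        sig = rng.normal(size=200)
        out = detrend_epochs(sig[None, None, :])
        removed = sig - out[0, 0]
        slope_oracle = np.polyfit(t, sig, 1)[0]
        slope_removed = np.polyfit(t, removed, 1)[0]
        assert slope_removed == pytest.approx(slope_oracle, rel=1e-9)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            detrend_epochs(np.ones((1, 1, 1)))


class TestOcularRejection:
    def test_zero_eog_yields_no_rejections(self, montage):
        data = np.zeros((10, 68, 948))
        times = -1.5 + np.arange(948) / 256.0
        mask = reject_ocular(data, times, 256.0, montage)
        assert (mask["reason"] == "").all()

    def test_injected_saccades_and_blinks_are_flagged(self, noisy_recording, montage):
        rec, labels = inject_artifacts(
            noisy_recording,
            dict(n_blink_trials=10, n_saccade_trials=20,
                 blink_amp_uv=200.0, saccade_step_uv=40.0),
            seed=7,
        )
        mask = reject_ocular(rec.data, rec.times, rec.fs, montage)
        flagged = mask.set_index("trial")["reason"]
        assert (flagged.loc[labels["saccade_trials"]] != "").all()
        assert (flagged.loc[labels["blink_trials"]] == "blink").all()

    def test_subthreshold_drift_is_not_flagged(self, montage):
        times = -1.5 + np.arange(948) / 256.0
        data = np.zeros((5, 68, 948))
        drift = 10.0 * (times - times[0]) / (times[-1] - times[0])
        data[:, montage.index("HEOG_L")] = drift
        mask = reject_ocular(data, times, 256.0, montage)
        assert (mask["reason"] == "").all()

    def test_missing_eog_channel_raises(self, montage):
        import dataclasses

        broken = dataclasses.replace(
            montage, names=[n.replace("VEOG_U", "XX") for n in montage.names]
        )
        with pytest.raises(ValueError, match="VEOG_U"):
            reject_ocular(np.zeros((1, 68, 948)),
                          -1.5 + np.arange(948) / 256.0, 256.0, broken)


class TestBadChannels:
    def test_identical_channels_are_never_flagged(self, montage):
        data = np.tile(np.sin(np.arange(948) / 10.0), (5, 68, 1))
        _, interp, discard = detect_and_interpolate_bad_channels(data, montage)
        assert all(len(lst) == 0 for lst in interp)
        assert (discard == "").all()

    def test_high_variance_channel_is_flagged_and_interpolated(
        self, noisy_recording, montage
    ):
        rng = np.random.default_rng(8)
        data = noisy_recording.data[:40].copy()
        ch = montage.index("C3")
        data[:, ch] += rng.standard_normal(data[:, ch].shape) * 12.0
        cleaned, interp, discard = detect_and_interpolate_bad_channels(data, montage)
        hit = sum("C3" in lst for lst in interp)
        assert hit >= 0.95 * 40
        # interpolation replaced the corrupted signal with a scalp estimate
        assert cleaned[:, ch].std() < data[:, ch].std()

    def test_sixteen_corrupted_channels_discard_the_trial(
        self, noisy_recording, montage
    ):
        rng = np.random.default_rng(9)
        data = noisy_recording.data[:5].copy()
        data[2, :16] += rng.standard_normal((16, data.shape[2])) * 60.0
        _, _, discard = detect_and_interpolate_bad_channels(data, montage)
        assert discard[2] == "too_many_bad_channels"

    def test_majority_bad_gets_distinct_reason(self, noisy_recording, montage):
        rng = np.random.default_rng(10)
        data = noisy_recording.data[:3].copy()
        data[1, :40] += rng.standard_normal((40, data.shape[2])) * 60.0
        _, _, discard = detect_and_interpolate_bad_channels(data, montage)
        assert discard[1] == "majority_bad_channels"


class TestCSD:
    def test_uniform_potential_maps_to_zero(self, montage):
        data = np.ones((2, 68, 10))
        out = csd_transform(data, montage)
        assert np.abs(out[:, :64]).max() < 1e-6

    def test_linearity(self, montage):
        rng = np.random.default_rng(11)
        x = rng.normal(size=(1, 68, 20))
        y = rng.normal(size=(1, 68, 20))
        lhs = csd_transform(2.0 * x + 3.0 * y, montage)
        rhs = 2.0 * csd_transform(x, montage) + 3.0 * csd_transform(y, montage)
        assert np.abs(lhs - rhs).max() < 1e-10 * np.abs(rhs).max()

    def test_matches_reference_spherical_spline_implementation(self, montage):
        """Independent oracle: the MNE spherical-spline CSD on identical coordinates."""
        mne = pytest.importorskip("mne")
        mne.set_log_level("ERROR")
        rng = np.random.default_rng(12)
        v = rng.normal(size=(64, 30)) * 1e-6  # volts
        lap = _sphspline.csd_matrix(montage.scalp_positions, head_radius_m=0.095)
        ours = lap @ v
        ch_pos = {n: p * 0.095 for n, p in
                  zip(montage.scalp_names, montage.scalp_positions)}
        dig = mne.channels.make_dig_montage(ch_pos=ch_pos, coord_frame="head")
        info = mne.create_info(montage.scalp_names, 256.0, "eeg")
        ev = mne.EvokedArray(v, info)
        ev.set_montage(dig)
        ref = mne.preprocessing.compute_current_source_density(
            ev, sphere=(0, 0, 0, 0.095), stiffness=4, lambda2=1e-5,
            n_legendre_terms=50,
        ).data
        assert np.abs(ours - ref).max() <= 1e-6 * np.abs(ref).max()

    def test_preserves_oscillation_frequency_content(self, montage):
        t = np.arange(768) / 256.0
        sig = np.outer(np.linspace(0.2, 1.0, 68), np.sin(2 * np.pi * 21 * t))
        out = csd_transform(sig[None], montage)[0]
        spec = np.abs(np.fft.rfft(out[:64], axis=-1)).mean(axis=0)
        freqs = np.fft.rfftfreq(768, 1 / 256.0)
        assert freqs[np.argmax(spec)] == pytest.approx(21.0)

    def test_coincident_electrodes_raise(self):
        pos = np.ones((40, 3)) / np.sqrt(3.0)
        with pytest.raises(ValueError, match="degenerate|coincident"):
            _sphspline.csd_matrix(pos)


class TestCleaningChain:
    def test_clean_data_passes_through(self, noisy_recording):
        clean = clean_epochs(noisy_recording)
        assert clean.n_retained == noisy_recording.n_trials
        assert clean.csd_applied
        assert len(clean.interpolated) == clean.n_retained

    def test_rejections_track_injected_contamination(self, noisy_recording):
        rec, labels = inject_artifacts(
            noisy_recording,
            dict(n_blink_trials=8, n_saccade_trials=12,
                 blink_amp_uv=200.0, saccade_step_uv=40.0),
            seed=13,
        )
        clean = clean_epochs(rec, apply_csd=False)
        contaminated = set(labels["blink_trials"]) | set(labels["saccade_trials"])
        rejected = set(clean.rejection_log["trial"])
        assert contaminated <= rejected
        assert len(rejected) <= len(contaminated) + 0.05 * rec.n_trials

    def test_retained_plus_removed_partition_the_trials(self, noisy_recording):
        rec, _ = inject_artifacts(
            noisy_recording, dict(n_blink_trials=5, n_saccade_trials=5), seed=14
        )
        clean = clean_epochs(rec)
        removed = set(clean.rejection_log["trial"])
        assert removed.isdisjoint(clean.retained)
        assert len(removed) + clean.n_retained == rec.n_trials
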