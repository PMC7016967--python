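"""EEG preprocessing, mutual-information features and topomap encoding."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from driversense.eeg import (BANDS, MutualInfoEstimate, amplitude_reject,
                             band_psd, bandpass_eeg,
                             conditional_entropy_vector, montage_positions,
                             mutual_information, topomap_rgb,
                             topomap_sequence, trial_topomap)
from driversense.io import EEG_CHANNELS, EEG_RATE_HZ, SignalStream
from driversense.synth import gen_eeg


def _stream(samples, rate=EEG_RATE_HZ, names=None, modality="eeg"):
    samples = np.atleast_2d(samples)
    if names is None:
        names = EEG_CHANNELS[:samples.shape[0]]
    return SignalStream(samples, rate, names, modality)


def brute_force_mi_bits(joint: np.ndarray) -> float:
    """Independent oracle: plug-in MI by the literal double sum over bins."""
    p = joint / joint.sum()
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return total


class TestBandpass:
    def test_in_band_sinusoid_amplitude_preserved(self):
        t = np.arange(0, 8, 1 / EEG_RATE_HZ)
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass_eeg(_stream(x)).samples[0]
        mid = y[len(y) // 4: -len(y) // 4]
        assert abs(mid.max() - 1.0) < 0.05

    def test_dc_removed(self):
        y = bandpass_eeg(_stream(np.full(1024, 3.0))).samples[0]
        assert np.max(np.abs(y)) < 1e-3 * 3.0

    def test_out_of_band_attenuated_20db(self):
        t = np.arange(0, 8, 1 / EEG_RATE_HZ)
        x = np.sin(2 * np.pi * 60 * t)
        y = bandpass_eeg(_stream(x)).samples[0]
        mid = y[len(y) // 4: -len(y) // 4]
        assert 20 * np.log10(np.abs(mid).max()) < -20

    def test_hi_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_eeg(_stream(np.zeros(256)), hi_hz=64.0)


class TestAmplitudeReject:
    def test_clean_sinusoid_untouched(self):
        t = np.arange(1024) / EEG_RATE_HZ
        s = _stream(np.sin(2 * np.pi * 5 * t))
        cleaned, mask = amplitude_reject(s, z_thresh=5.0)
        assert not mask.any()
        np.testing.assert_array_equal(cleaned.samples, s.samples)

    def test_injected_spike_flagged_exactly(self, rng):
        x = rng.standard_normal(1000)
        x[500] = 20.0 * x.std()
        cleaned, mask = amplitude_reject(_stream(x), z_thresh=5.0)
        assert list(np.flatnonzero(mask[0])) == [500]
        # repaired value interpolates its neighbours
        assert abs(cleaned.samples[0, 500]
                   - 0.5 * (x[499] + x[501])) < 1e-12

    def test_all_flagged_degenerate_fails(self):
        x = np.array([-1.0, 1.0] * 50)     # every |z| = 1 > 0.5
        with pytest.raises(ValueError, match="every sample"):
            amplitude_reject(_stream(x), z_thresh=0.5)


class TestMutualInformation:
    def test_identical_signals_zero_conditional_entropy(self, rng):
        x = rng.standard_normal(500)
        est = mutual_information(x, x, 16)
        assert est.H_y_given_x == pytest.approx(0.0, abs=1e-9)
        assert est.I_xy == pytest.approx(est.H_y, abs=1e-9)

    def test_matches_brute_force_double_sum(self, rng):
        x = rng.uniform(size=10_000)
        y = rng.uniform(size=10_000)
        est = mutual_information(x, y, 16)
        assert est.I_xy == pytest.approx(brute_force_mi_bits(est.joint_hist),
                                         abs=1e-12)
        # independent uniforms: MI within plug-in estimator bias of zero
        assert est.I_xy < 3 * 16 ** 2 / (2 * 10_000 * np.log(2))

    def test_two_bin_diagonal_joint_gives_one_bit(self):
        # p(x,y) = [[0.5, 0], [0, 0.5]]: closed form I = 1 bit
        x = np.array([0.0, 1.0] * 50)
        est = mutual_information(x, x, 2)
        assert est.I_xy == pytest.approx(1.0, abs=1e-12)
        assert est.H_y == pytest.approx(1.0, abs=1e-12)
        assert est.H_y_given_x == pytest.approx(0.0, abs=1e-12)

    def test_constant_input_zero_entropy_without_nan(self):
        est = mutual_information(np.ones(64), np.ones(64), 16)
        assert est.I_xy == 0.0 and est.H_y == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="2\\*bin_count"):
            mutual_information(np.arange(10), np.arange(10), 16)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=20, deadline=None)
    def test_symmetry_and_identity_properties(self, seed):
        r = np.random.default_rng(seed)
        x = r.standard_normal(200)
        y = 0.5 * x + r.standard_normal(200)
        a = mutual_information(x, y, 8)
        b = mutual_information(y, x, 8)
        assert abs(a.I_xy - b.I_xy) < 1e-9
        assert abs(a.H_y_given_x - (a.H_y - a.I_xy)) < 1e-9
        assert a.I_xy >= -1e-9

    def test_permutation_null_within_bias_bound(self, rng):
        """MI against permuted copies stays below 3x the analytic plug-in
        bias bound bins^2 / (2 n ln 2)."""
        n, bins = 4096, 16
        x = rng.standard_normal(n)
        vals = []
        for _ in range(100):
            y = rng.permutation(x)
            vals.append(mutual_information(x, y, bins).I_xy)
        assert np.mean(vals) < 3 * bins ** 2 / (2 * n * np.log(2))

    def test_estimate_invariants_enforced(self):
        with pytest.raises(ValueError, match="identity"):
            MutualInfoEstimate(I_xy=0.5, H_y=1.0, H_y_given_x=0.9,
                               bin_count=4, joint_hist=np.ones((4, 4)))


class TestConditionalEntropyVector:
    def test_full_montage_gives_91_features(self, eeg_noise_stream):
        block = conditional_entropy_vector(eeg_noise_stream)
        assert len(block.values) == 91 == len(list(
            itertools.combinations(range(14), 2)))
        assert block.names[0] == "ce_AF3_AF4"

    def test_two_channel_debug_montage_gives_one(self, rng):
        s = _stream(rng.standard_normal((2, 256)), names=("AF3", "AF4"))
        assert len(conditional_entropy_vector(s).values) == 1

    def test_identical_channels_give_zero(self, rng):
        x = rng.standard_normal(512)
        s = _stream(np.tile(x, (14, 1)))
        block = conditional_entropy_vector(s)
        np.testing.assert_allclose(block.values, 0.0, atol=1e-9)

    def test_non_eeg_stream_rejected(self, rng):
        s = _stream(rng.standard_normal((1, 256)), rate=51.2,
                    names=("ppg",), modality="ppg")
        with pytest.raises(ValueError, match="EEG"):
            conditional_entropy_vector(s)


class TestBandPsd:
    def test_alpha_sinusoid_dominates_alpha_band(self):
        t = np.arange(0, 8, 1 / EEG_RATE_HZ)
        s = _stream(np.sin(2 * np.pi * 10 * t))
        alpha = band_psd(s, "alpha")[0]
        assert alpha / band_psd(s, "theta")[0] > 100
        assert alpha / band_psd(s, "beta")[0] > 100

    def test_zero_signal_zero_power(self):
        np.testing.assert_array_equal(
            band_psd(_stream(np.zeros((14, 512))), "alpha"), 0.0)

    def test_white_noise_spectrum_flat_across_bands(self, rng):
        """Mean in-band PSD of white noise is band-independent (so the
        integrated power is proportional to bandwidth)."""
        s = _stream(rng.standard_normal(10_000))
        means = {b: band_psd(s, b)[0] for b in BANDS}
        for a, b in itertools.combinations(means.values(), 2):
            assert abs(a / b - 1) < 0.2

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            band_psd(_stream(np.zeros(512)), (30.0, 70.0))


class TestTopomap:
    def test_zero_beta_gives_zero_blue_channel(self, rng):
        v = rng.uniform(0.5, 1.0, 14)
        img = topomap_rgb(v, v, np.zeros(14))
        assert np.all(img.pixels[:, :, 2] == 0.0)
        assert img.pixels[:, :, 0].max() > 0

    def test_equal_bands_give_identical_channels(self, rng):
        v = rng.uniform(0.5, 1.0, 14)
        img = topomap_rgb(v, v, v)
        np.testing.assert_array_equal(img.pixels[:, :, 0], img.pixels[:, :, 1])
        np.testing.assert_array_equal(img.pixels[:, :, 0], img.pixels[:, :, 2])

    def test_hot_electrode_peak_at_its_position(self):
        pos = montage_positions()
        for hot in (0, 10, 13):
            v = np.zeros(14)
            v[hot] = 1.0
            img = topomap_rgb(v, np.ones(14), np.ones(14))
            red = img.pixels[:, :, 0]
            iy, ix = np.unravel_index(np.argmax(red), red.shape)
            # map pixel back to unit-disc coordinates
            gx = ix / 223 * 2 - 1
            gy = iy / 223 * 2 - 1
            assert np.hypot(gx - pos[hot, 0], gy - pos[hot, 1]) < 0.15

    def test_common_scaling_invariance(self, rng):
        v1, v2, v3 = (rng.uniform(0.1, 1.0, 14) for _ in range(3))
        a = topomap_rgb(v1, v2, v3)
        b = topomap_rgb(7.3 * v1, 7.3 * v2, 7.3 * v3)
        np.testing.assert_allclose(a.pixels, b.pixels, atol=1e-12)

    def test_all_zero_input_fails(self):
        with pytest.raises(ValueError, match="normalization"):
            topomap_rgb(np.zeros(14), np.zeros(14), np.zeros(14))

    def test_outside_head_disc_is_zero(self, rng):
        img = trial_topomap(bandpass_eeg(
            _stream(rng.standard_normal((14, 512)))))
        assert np.all(img.pixels[0, 0] == 0)        # corner outside disc
        assert np.all(img.pixels[-1, -1] == 0)


class TestTopomapSequence:
    def test_35s_trial_one_per_second_gives_35(self):
        s, _ = gen_eeg(False, 0.0, 1.0, 35.0, np.random.default_rng(0))
        assert len(topomap_sequence(bandpass_eeg(s), 1.0)) == 35

    def test_incident_30_per_second_gives_60(self):
        s, _ = gen_eeg(False, 0.0, 1.0, 2.0, np.random.default_rng(0))
        assert len(topomap_sequence(bandpass_eeg(s), 30.0)) == 60

    def test_single_window_equals_whole_trial_map(self):
        s, _ = gen_eeg(False, 0.0, 1.0, 1.0, np.random.default_rng(0))
        f = bandpass_eeg(s)
        (img,) = topomap_sequence(f, 1.0)
        np.testing.assert_allclose(img.pixels, trial_topomap(f).pixels)

    def test_non_integer_window_count_rejected(self):
        s, _ = gen_eeg(False, 0.0, 1.0, 2.5, np.random.default_rng(0))
        with pytest.raises(ValueError, match="integer"):
            topomap_sequence(bandpass_eeg(s), 0.7)
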