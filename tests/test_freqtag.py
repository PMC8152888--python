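"""Spectral machinery: segmentation, averaging, noise subtraction, extraction,
z-scoring."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meterlab import freqtag as ft
from meterlab.sequences import build_sequence, event_envelope, invert_sequence

RATE = 500.0  # 14.4 s = 7200 samples exactly: resolution is exactly 1/14.4 Hz
RES = 1.0 / 14.4


def sinusoid(freq, rate, duration, amp=1.0, phase=0.0):
    t = np.arange(int(round(duration * rate))) / rate
    return amp * np.cos(2 * np.pi * freq * t + phase)


class TestSegmentation:
    def test_padded_trial_yields_seven_segments(self):
        x = np.zeros(int(58.4 * RATE))
        seg = ft.segment_signal(x, RATE, core_start_offset=0.4)
        assert seg.segments.shape == (7, 1, 7200)

    def test_exact_core_offset_zero(self):
        x = np.zeros((3, int(57.6 * RATE)))
        seg = ft.segment_signal(x, RATE)
        assert seg.segments.shape == (7, 3, 7200)

    def test_segments_start_on_hop_grid(self):
        n = int(57.6 * RATE)
        x = np.arange(n, dtype=float)[None, :]
        seg = ft.segment_signal(x, RATE)
        for k in range(7):
            assert seg.segments[k, 0, 0] == k * int(7.2 * RATE)

    def test_short_input_raises(self):
        with pytest.raises(ValueError, match="need"):
            ft.segment_signal(np.zeros(int(10 * RATE)), RATE)

    def test_unknown_origin_rejected(self):
        with pytest.raises(ValueError):
            ft.segment_signal(np.zeros(int(57.6 * RATE)), RATE, origin="mystery")


class TestAverageTrials:
    def test_mean_of_copies_is_identity(self, rng):
        x = rng.standard_normal((2, int(57.6 * RATE)))
        seg = ft.segment_signal(x, RATE)
        avg = ft.average_trials([seg] * 5)
        assert np.allclose(avg.segments, seg.segments)

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            ft.average_trials([])

    def test_shape_mismatch_raises(self, rng):
        a = ft.segment_signal(rng.standard_normal((1, 28800)), RATE)
        b = ft.segment_signal(rng.standard_normal((2, 28800)), RATE)
        with pytest.raises(ValueError):
            ft.average_trials([a, b])

    def test_noise_floor_shrinks_as_sqrt_n(self, rng):
        """Phase-locked sinusoid survives averaging; independent noise drops
        by about 1/sqrt(n_trials)."""
        n_trials = 100
        sig = sinusoid(2.5, RATE, 57.6)
        trials = [
            ft.segment_signal(sig + rng.standard_normal(sig.shape), RATE)
            for _ in range(n_trials)
        ]
        avg = ft.average_trials(trials)
        residual = avg.segments[0, 0] - ft.segment_signal(sig, RATE).segments[0, 0]
        single = trials[0].segments[0, 0] - ft.segment_signal(sig, RATE).segments[0, 0]
        ratio = np.std(residual) / np.std(single)
        expected = 1 / np.sqrt(n_trials)
        assert expected / 2 < ratio < expected * 2
        # the locked component is preserved
        spec = ft.magnitude_spectrum(avg.segments[0], RATE)
        bin_25 = int(round(2.5 / spec.resolution))
        assert spec.amplitudes[0, bin_25] == pytest.approx(0.5, rel=0.05)


class TestMagnitudeSpectrum:
    def test_resolution(self):
        spec = ft.magnitude_spectrum(np.zeros((1, 7200)), RATE)
        assert spec.resolution == pytest.approx(RES)

    def test_pure_tone_occupies_single_bin(self):
        x = sinusoid(2.5, RATE, 14.4)
        spec = ft.magnitude_spectrum(x[None, :], RATE)
        k = int(round(2.5 / spec.resolution))
        assert spec.amplitudes[0, k] == pytest.approx(0.5, rel=1e-9)
        others = np.delete(spec.amplitudes[0], k)
        assert np.max(others) < 1e-10

    def test_zero_signal_zero_spectrum(self):
        spec = ft.magnitude_spectrum(np.zeros((2, 7200)), RATE)
        assert np.all(spec.amplitudes == 0)


class TestSubtractNoise:
    def test_flat_spectrum_becomes_zero(self):
        spec = ft.MagnitudeSpectrum(np.full(50, 3.7), RES)
        assert np.allclose(ft.subtract_noise(spec).amplitudes, 0)

    def test_isolated_peak(self):
        a = np.zeros(51)
        a[25] = 2.0
        out = ft.subtract_noise(ft.MagnitudeSpectrum(a, RES)).amplitudes
        assert out[25] == pytest.approx(2.0)
        assert out[23] == pytest.approx(-1.0)
        assert out[27] == pytest.approx(-1.0)

    def test_peak_on_constant_background(self):
        a = np.full(51, 0.4)
        a[25] += 2.0
        out = ft.subtract_noise(ft.MagnitudeSpectrum(a, RES)).amplitudes
        assert out[25] == pytest.approx(2.0)

    def test_boundary_bins_use_single_neighbor(self):
        a = np.array([5.0, 0.0, 1.0, 0.0, 3.0])
        out = ft.subtract_noise(ft.MagnitudeSpectrum(a, RES)).amplitudes
        assert out[0] == pytest.approx(5.0 - 1.0)   # only k+2 available
        assert out[4] == pytest.approx(3.0 - 1.0)   # only k-2 available
        assert out[2] == pytest.approx(1.0 - 4.0)   # both sides averaged

    def test_double_subtraction_rejected(self):
        spec = ft.subtract_noise(ft.MagnitudeSpectrum(np.ones(20), RES))
        with pytest.raises(ValueError):
            ft.subtract_noise(spec)

    @given(
        a=st.lists(st.floats(-10, 10), min_size=10, max_size=10),
        b=st.lists(st.floats(-10, 10), min_size=10, max_size=10),
        ca=st.floats(-3, 3),
        cb=st.floats(-3, 3),
    )
    @settings(max_examples=50, deadline=None)
    def test_linearity(self, a, b, ca, cb):
        a, b = np.asarray(a), np.asarray(b)
        lhs = ft.subtract_noise(ft.MagnitudeSpectrum(ca * a + cb * b, RES)).amplitudes
        rhs = (
            ca * ft.subtract_noise(ft.MagnitudeSpectrum(a, RES)).amplitudes
            + cb * ft.subtract_noise(ft.MagnitudeSpectrum(b, RES)).amplitudes
        )
        assert np.allclose(lhs, rhs, atol=1e-9)


class TestTargetFrequencies:
    def test_default_set_size_and_exact_bins(self):
        fs = ft.build_target_frequencies(RES)
        assert len(fs.frequencies) == 24
        assert sum(fs.exact_bin) == 16

    def test_contains_cycle_fundamentals(self):
        fs = ft.build_target_frequencies(RES)
        assert any(abs(f - 5 / 12) < 1e-9 for f in fs.frequencies)
        assert any(abs(f - 0.3125) < 1e-9 for f in fs.frequencies)

    def test_meter_subset(self):
        fs = ft.build_target_frequencies(RES)
        assert tuple(fs.frequencies[i] for i in fs.meter_indices) == (1.25, 2.5, 5.0)
        assert max(fs.frequencies) <= 5.0
        assert len(set(fs.frequencies)) == len(fs.frequencies)

    def test_explicit_frequency_list_override(self):
        fs = ft.build_target_frequencies(RES, frequencies=[1.25, 2.5, 5.0, 0.7])
        assert len(fs.frequencies) == 4

    def test_meter_subset_must_be_included(self):
        with pytest.raises(ValueError):
            ft.build_target_frequencies(RES, frequencies=[2.5, 5.0])


class TestExtraction:
    def test_exact_bin_arithmetic(self):
        # 2.5 Hz at resolution 1/14.4: bin 2.5 * 14.4 = 36, exactly
        a = np.zeros(100)
        a[36] = 7.25
        fs = ft.build_target_frequencies(RES, frequencies=[1.25, 2.5, 5.0])
        spec = ft.MagnitudeSpectrum(a, RES, noise_subtracted=True)
        out = ft.extract_amplitudes(spec, fs)
        assert out[1] == 7.25

    def test_off_bin_takes_max_of_two_closest(self):
        # 0.3125 Hz * 14.4 = 4.5: bins 4 and 5
        a = np.zeros(100)
        a[4], a[5] = 1.0, 3.0
        fs = ft.build_target_frequencies(RES, frequencies=[0.3125, 1.25, 2.5, 5.0])
        out = ft.extract_amplitudes(ft.MagnitudeSpectrum(a, RES, noise_subtracted=True), fs)
        assert out[0] == 3.0

    def test_injected_values_returned_verbatim(self, rng):
        fs = ft.build_target_frequencies(RES)
        a = rng.uniform(1, 2, 200)
        out = ft.extract_amplitudes(ft.MagnitudeSpectrum(a, RES, noise_subtracted=True), fs)
        for f, exact, v in zip(fs.frequencies, fs.exact_bin, out):
            x = f / RES
            if exact:
                assert v == a[int(round(x))]
            else:
                assert v == max(a[int(np.floor(x))], a[int(np.ceil(x))])

    def test_above_nyquist_rejected(self):
        fs = ft.build_target_frequencies(RES)
        with pytest.raises(ValueError):
            ft.extract_amplitudes(ft.MagnitudeSpectrum(np.ones(10), RES), fs)


class TestZScores:
    def test_mean_zero_sd_one(self, rng):
        fs = ft.build_target_frequencies(RES)
        z = ft.zscore_amplitudes(rng.uniform(0, 5, 24), fs)
        assert np.mean(z.z) == pytest.approx(0, abs=1e-12)
        assert np.std(z.z, ddof=1) == pytest.approx(1)

    def test_toy_vector_fixes_sd_convention(self):
        # {1,2,3} with sample (n-1) SD = 1 gives exactly {-1,0,1}
        fs = ft.build_target_frequencies(RES, frequencies=[1.25, 2.5, 5.0])
        z = ft.zscore_amplitudes(np.array([1.0, 2.0, 3.0]), fs)
        assert np.allclose(z.z, [-1.0, 0.0, 1.0])

    def test_single_outlier_carries_positive_z(self):
        fs = ft.build_target_frequencies(RES)
        amps = np.full(24, 2.0)
        amps[11] = 5.0  # 2.5 Hz
        z = ft.zscore_amplitudes(amps, fs)
        assert z.z[11] > 0
        assert np.sum(z.z > 0) == 1

    def test_zero_variance_rejected(self):
        fs = ft.build_target_frequencies(RES)
        with pytest.raises(ValueError):
            ft.zscore_amplitudes(np.ones(24), fs)

    def test_scale_invariance(self, rng):
        fs = ft.build_target_frequencies(RES)
        amps = rng.uniform(0, 3, 24)
        z1 = ft.zscore_amplitudes(amps, fs)
        z2 = ft.zscore_amplitudes(17.3 * amps, fs)
        assert np.allclose(z1.z, z2.z)
        assert z1.meter_mean_z == pytest.approx(z2.meter_mean_z)


class TestMeterZDifference:
    def test_identical_inputs_zero(self, rng):
        fs = ft.build_target_frequencies(RES)
        z = ft.zscore_amplitudes(rng.uniform(0, 3, 24), fs)
        assert ft.meter_z_difference(z, z) == 0

    def test_amplified_meter_response_negative(self, rng):
        fs = ft.build_target_frequencies(RES)
        amps = rng.uniform(1, 2, 24)
        boosted = amps.copy()
        for i in fs.meter_indices:
            boosted[i] *= 3
        d = ft.meter_z_difference(
            ft.zscore_amplitudes(amps, fs), ft.zscore_amplitudes(boosted, fs)
        )
        assert d < 0

    def test_mismatched_sets_rejected(self, rng):
        fs1 = ft.build_target_frequencies(RES)
        fs2 = ft.build_target_frequencies(RES, frequencies=[1.25, 2.5, 5.0])
        z1 = ft.zscore_amplitudes(rng.uniform(0, 3, 24), fs1)
        z2 = ft.zscore_amplitudes(np.array([1.0, 2.0, 3.0]), fs2)
        with pytest.raises(ValueError):
            ft.meter_z_difference(z1, z2)


class TestEndToEndEnvelope:
    def test_direction_matched_segments_identical(self):
        """The engine applied to a sequence's gate envelope and its
        inversion's gives identical z vectors for direction-matched segments."""
        s = build_sequence(5)
        inv = invert_sequence(s)
        rate = 100.0
        z_fwd = ft.segments_to_zscores(
            ft.segment_signal(event_envelope(s.core_events, rate), rate, origin="envelope")
        )
        z_bwd = ft.segments_to_zscores(
            ft.segment_signal(event_envelope(inv.core_events, rate), rate, origin="envelope")
        )
        for k in range(7):
            assert np.allclose(z_fwd[k].z, z_bwd[6 - k].z, atol=1e-9)
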