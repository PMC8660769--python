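"""Pattern generation and Floyd-Steinberg halftoning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import gaussian_filter

from halftone_sfdi import (
    PatternImage,
    PatternSpec,
    halftone_error_diffusion,
    pattern_sequence,
    sinusoid_pattern,
)


class TestSinusoid:
    def test_phase_zero_peaks_at_origin(self):
        p = sinusoid_pattern(PatternSpec(shape=(4, 64), fx=0.1, pixel_pitch=0.1, phase=0.0))
        assert p.values[0, 0] == 1.0

    def test_mean_over_integer_periods_is_half(self):
        # 100-pixel period, 4 full periods
        p = sinusoid_pattern(PatternSpec(shape=(8, 400), fx=0.1, pixel_pitch=0.1, phase=0.0))
        assert p.values.mean() == pytest.approx(0.5, abs=1 / 255)

    def test_zero_frequency_degenerates_to_planar(self):
        spec = PatternSpec(shape=(8, 32), fx=0.0, pixel_pitch=0.1, phase=0.0)
        planar = sinusoid_pattern(PatternSpec(shape=(8, 32), pixel_pitch=0.1, kind="planar"))
        assert np.array_equal(sinusoid_pattern(spec).values, planar.values)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            PatternSpec(shape=(8, 32), fx=6.0, pixel_pitch=0.1)

    def test_eight_bit_quantization_levels(self):
        p = sinusoid_pattern(PatternSpec(shape=(4, 128), fx=0.05, pixel_pitch=0.1))
        assert np.allclose(p.values * 255, np.round(p.values * 255))


class TestHalftone:
    def test_saturated_endpoints_pass_through(self):
        ones = PatternImage(np.ones((32, 32)))
        zeros = PatternImage(np.zeros((32, 32)))
        assert np.all(halftone_error_diffusion(ones).values == 1)
        assert np.all(halftone_error_diffusion(zeros).values == 0)

    def test_constant_half_tone_preserved(self):
        p = PatternImage(np.full((256, 256), 0.5))
        out = halftone_error_diffusion(p)
        assert out.bit_depth == 1
        assert 0.49 <= out.values.mean() <= 0.51

    def test_deterministic(self):
        p = sinusoid_pattern(PatternSpec(shape=(64, 128), fx=0.1, pixel_pitch=0.05))
        a = halftone_error_diffusion(p)
        b = halftone_error_diffusion(p)
        assert np.array_equal(a.values, b.values)

    def test_out_of_range_input_rejected(self):
        bad = PatternImage.__new__(PatternImage)
        bad.values = np.full((8, 8), 1.5)
        bad.bit_depth = 8
        bad.spec = None
        with pytest.raises(ValueError):
            halftone_error_diffusion(bad)

    def test_lowpass_filtered_halftone_matches_continuous(self):
        # 100 px/period sinusoid; blur both with a one-period Gaussian
        spec = PatternSpec(shape=(300, 400), fx=0.1, pixel_pitch=0.1, phase=0.0)
        cont = sinusoid_pattern(spec)
        half = halftone_error_diffusion(cont)
        period_px = 1.0 / (spec.fx * spec.pixel_pitch)
        lp_c = gaussian_filter(cont.values, period_px)
        lp_h = gaussian_filter(half.values, period_px)
        interior = (slice(100, -100), slice(100, -100))
        rms = np.sqrt(np.mean((lp_c[interior] - lp_h[interior]) ** 2))
        assert rms <= 0.01

    def test_first_harmonic_amplitude_within_two_percent(self):
        # period 50 px: the fundamental of the halftone must match the
        # continuous pattern's fundamental to within 2%
        spec = PatternSpec(shape=(256, 500), fx=0.4, pixel_pitch=0.05, phase=0.0)
        cont = sinusoid_pattern(spec)
        half = halftone_error_diffusion(cont)
        k = 10  # 500 px / 50 px per period
        amp_c = np.abs(np.fft.fft(cont.values, axis=1)[:, k]).mean()
        amp_h = np.abs(np.fft.fft(half.values, axis=1)[:, k]).mean()
        assert abs(amp_h - amp_c) / amp_c < 0.02

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1.0, allow_nan=False))
    def test_mean_preservation_for_constant_inputs(self, level):
        n = 64
        out = halftone_error_diffusion(PatternImage(np.full((n, n), level)))
        assert abs(out.values.mean() - level) <= 1.0 / n  # 1/sqrt(N_pixels)


class TestSequence:
    def test_five_patterns_per_wavelength_in_order(self):
        seq = pattern_sequence([650.0], 0.1, (16, 64), 0.05)
        assert len(seq) == 5
        kinds = [p.spec.kind for p in seq]
        assert kinds == ["planar", "dark", "sinusoid", "sinusoid", "sinusoid"]
        assert [p.spec.phase for p in seq[2:]] == [0.0, 120.0, 240.0]

    def test_dark_is_all_zero_in_both_modes(self):
        for halftone in (False, True):
            seq = pattern_sequence([650.0], 0.1, (16, 64), 0.05, halftone=halftone)
            assert np.all(seq[1].values == 0)

    def test_halftone_mode_is_fully_binary(self):
        seq = pattern_sequence([650.0, 850.0], 0.1, (16, 64), 0.05, halftone=True)
        assert len(seq) == 10
        for p in seq:
            assert p.bit_depth == 1
            assert np.all((p.values == 0) | (p.values == 1))
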