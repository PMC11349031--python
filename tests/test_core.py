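"""Estimator unit tests: windowed correlation, SSB modulation, cutoff rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssbswpc import (
    AliasingError,
    WindowSpec,
    choose_modulation_frequency,
    hp_cutoff,
    ssb_modulate,
    ssb_swpc,
    swpc,
    upsample,
)
from ssbswpc.simulate import bandlimit

from .conftest import brickwall_bandpass


class TestSwpc:
    def test_matches_per_window_pearson_oracle(self, rng):
        """Each output equals an independently coded Pearson over that window."""
        x, y = rng.standard_normal((2, 60))
        delta = 3
        est = swpc(x, y, WindowSpec(half_width=delta))
        for i, t in enumerate(range(delta, 60 - delta)):
            xw = x[t - delta : t + delta + 1]
            yw = y[t - delta : t + delta + 1]
            expected = np.corrcoef(xw, yw)[0, 1]
            assert est[i] == pytest.approx(expected, abs=1e-12)

    def test_full_window_equals_global_pearson(self, random_pair):
        x, y = random_pair
        est = swpc(x, y, WindowSpec(half_width=(len(x) - 1) // 2))
        assert est.shape == (1,)
        assert est[0] == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(50)
        assert np.allclose(swpc(x, x, 4), 1.0, atol=1e-12)

    def test_output_length_and_bounds(self, rng):
        x, y = rng.standard_normal((2, 100))
        est = swpc(x, y, 7)
        assert est.shape == (100 - 14,)
        assert np.all(est >= -1) and np.all(est <= 1)

    def test_zero_variance_window_flagged_with_warning(self, rng):
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        x[10:20] = 5.0  # constant stretch longer than the window
        with pytest.warns(RuntimeWarning, match="zero variance"):
            est = swpc(x, y, 2)
        assert np.isnan(est).any()
        assert not np.isnan(est).all()

    def test_errors(self, rng):
        x = rng.standard_normal(20)
        with pytest.raises(ValueError, match="mismatch"):
            swpc(x, x[:-1], 2)
        with pytest.raises(ValueError, match="exceeds"):
            swpc(x, x, 15)


class TestSsbModulate:
    def test_zero_modulation_is_identity(self, rng):
        x = rng.standard_normal(128)
        assert np.array_equal(ssb_modulate(x, 0.0, 2.0), x)

    def test_cosine_peak_shifts_by_f_m(self):
        fs = 2.0
        t = np.arange(2000) / fs
        x = np.cos(2 * np.pi * 0.05 * t)
        out = ssb_modulate(x, 0.1, fs)
        f = np.fft.rfftfreq(len(t), 1 / fs)
        assert f[np.argmax(np.abs(np.fft.rfft(out)))] == pytest.approx(0.15, abs=1e-3)

    def test_power_preserved_for_bandlimited_input(self, rng):
        x = bandlimit(rng.standard_normal(4000), 0.1, 2.0)
        out = ssb_modulate(x, 0.5, 2.0, band_high=0.13)
        assert out.var() / x.var() == pytest.approx(1.0, abs=0.01)

    def test_spectrum_shifts_outward(self, rng):
        """Magnitude spectrum of the output is the input's shifted up by f_m."""
        fs = 2.0
        n = 4096
        f_m = 0.25  # an exact number of FFT bins at this (n, fs)
        x = brickwall_bandpass(rng.standard_normal(n), 0.1, 0.3, fs)
        out = ssb_modulate(x, f_m, fs)
        mag_in = np.abs(np.fft.rfft(x))
        mag_out = np.abs(np.fft.rfft(out))
        shift = int(round(f_m * n / fs))
        hi = len(mag_in) - 10
        assert np.allclose(
            mag_out[shift + 10 : hi], mag_in[10 : hi - shift], atol=1e-8 * mag_in.max()
        )

    def test_aliasing_guard(self, rng):
        x = rng.standard_normal(100)
        with pytest.raises(AliasingError):
            ssb_modulate(x, 0.95, 2.0, band_high=0.1)
        with pytest.warns(RuntimeWarning, match="aliasing"):
            ssb_modulate(x, 0.95, 2.0, band_high=0.1, allow_alias=True)

    def test_complex_input_rejected(self):
        with pytest.raises(TypeError):
            ssb_modulate(np.ones(10) + 1j, 0.1, 2.0)


class TestSsbSwpc:
    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_zero_modulation_reduces_to_swpc(self, seed):
        x, y = np.random.default_rng(seed).standard_normal((2, 64))
        assert np.allclose(ssb_swpc(x, y, 5, 0.0, 2.0), swpc(x, y, 5), atol=1e-12)

    def test_equals_swpc_of_modulated_pair(self, rng):
        x, y = rng.standard_normal((2, 200))
        fm, fs = 0.3, 2.0
        direct = ssb_swpc(x, y, 4, fm, fs)
        manual = swpc(ssb_modulate(x, fm, fs), ssb_modulate(y, fm, fs), 4)
        assert np.allclose(direct, manual, atol=1e-14)

    def test_cross_spectrum_equivalence_below_twice_band_floor(self, rng):
        """Coupling spectra of original and modulated pairs agree below 2a.

        The windowed product is the coupling step; its spectrum is the
        circular convolution of the two series' spectra, which SSB leaves
        unchanged at frequencies below twice the band's lower edge.
        """
        fs, n, a, b, fm = 2.0, 4096, 0.1, 0.3, 0.2
        x = brickwall_bandpass(rng.standard_normal(n), a, b, fs)
        y = brickwall_bandpass(rng.standard_normal(n), a, b, fs)
        xm = ssb_modulate(x, fm, fs, band_high=b)
        ym = ssb_modulate(y, fm, fs, band_high=b)
        f = np.fft.rfftfreq(n, 1 / fs)
        spec = np.fft.rfft(x * y)
        spec_mod = np.fft.rfft(xm * ym)
        scale = np.abs(spec[f < 2 * a]).max()
        low = f < 2 * a - 0.02
        assert np.abs(spec[low] - spec_mod[low]).max() < 0.02 * scale
        high = (f > 2 * a + 0.05) & (f < 2 * (b + fm))
        assert np.abs(spec[high] - spec_mod[high]).max() > 0.1 * scale


class TestCutoffRules:
    def test_printed_worked_value(self):
        assert hp_cutoff(7, 0.5) == pytest.approx(0.0635, abs=5e-5)

    def test_monotone_decreasing_to_zero(self):
        fs = 0.5
        vals = [hp_cutoff(n, fs) for n in range(2, 200)]
        assert np.all(np.diff(vals) < 0)
        assert vals[-1] < 0.003

    def test_against_numerical_frequency_response(self):
        """Formula within 10% of the dense −3 dB point of 1 − MA.

        Centered moving-average subtraction is zero-phase, so its response
        is 1 minus the real Dirichlet kernel; the −3 dB point is taken
        relative to the high-pass response's peak gain.
        """
        n, fs = 5, 2.0
        f = np.linspace(1e-6, fs / 2, 200000)
        dirichlet = np.sin(n * np.pi * f / fs) / (n * np.sin(np.pi * f / fs))
        hp = np.abs(1 - dirichlet)
        target = hp.max() / np.sqrt(2)
        empirical = f[np.argmax(hp >= target)]
        assert hp_cutoff(n, fs) == pytest.approx(empirical, rel=0.10)

    def test_rejects_degenerate_window(self):
        with pytest.raises(ValueError):
            hp_cutoff(1, 0.5)


class TestChooseModulationFrequency:
    def test_lifts_band_floor_to_cutoff(self):
        plan = choose_modulation_frequency(WindowSpec.from_length(7), 0.5, (0.01, 0.15))
        assert plan.f_m == pytest.approx(hp_cutoff(7, 0.5) - 0.01, abs=1e-12)
        assert plan.valid

    def test_no_modulation_needed_above_cutoff(self):
        plan = choose_modulation_frequency(WindowSpec.from_length(31), 0.5, (0.05, 0.15))
        assert plan.f_m == 0.0

    def test_infeasible_band_raises(self):
        with pytest.raises(AliasingError, match="f_m"):
            choose_modulation_frequency(WindowSpec.from_length(5), 2.0, (0.0, 0.95))


class TestUpsample:
    def test_factor_one_identity(self, rng):
        x = rng.standard_normal(50)
        out, fs = upsample(x, 1, 2.0)
        assert np.array_equal(out, x) and fs == 2.0

    def test_spectral_peak_preserved(self):
        t = np.arange(1000)
        x = np.cos(2 * np.pi * 0.1 * t)
        out, fs = upsample(x, 4, 1.0)
        assert len(out) == 4000 and fs == 4.0
        f = np.fft.rfftfreq(4000, 1 / fs)
        assert f[np.argmax(np.abs(np.fft.rfft(out)))] == pytest.approx(0.1, abs=1e-3)

    def test_content_confined_to_original_band(self, rng):
        x = rng.standard_normal(500)
        out, fs = upsample(x, 4, 1.0)
        f = np.fft.rfftfreq(len(out), 1 / fs)
        spec = np.abs(np.fft.rfft(out))
        assert spec[f > 0.55].max() < 1e-8 * spec.max()

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            upsample(np.ones(10), 1.5, 1.0)
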