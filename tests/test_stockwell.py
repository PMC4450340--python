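"""Transform correctness: marginal identity, oracle agreement, CM algebra."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import direct_s_transform, s1_like_signal, s2_like_signal
from stresspcg import (
    DegenerateInputError,
    DomainError,
    InvalidInputError,
    STMatrix,
    TimeSignal,
    concentration_measure,
    optimize_alpha,
    s_transform,
)
from stresspcg.stockwell import DEFAULT_ALPHA_GRID


def _unit_matrix(values: np.ndarray) -> STMatrix:
    """Wrap a magnitude array as an STMatrix on a unit-spaced grid."""
    n_f, n_t = values.shape
    return STMatrix(
        values.astype(complex),
        np.arange(1.0, n_f + 1),
        np.arange(float(n_t)),
        alpha=1.0,
    )


class TestSTransform:
    def test_time_marginal_identity(self):
        """Summing every voice over time reproduces the signal's DFT."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(64, 4096))
            fs = float(rng.uniform(100, 4000))
            x = rng.standard_normal(n)
            st_mat = s_transform(TimeSignal(x, fs), float(rng.uniform(0.5, 2.0)),
                                 None, include_dc=False)
            dft = np.fft.fft(x)
            idx = np.round(st_mat.freqs * n / fs).astype(int)
            rel = np.abs(st_mat.time_marginal() - dft[idx]) / np.abs(dft[idx])
            assert rel.max() < 1e-6

    @pytest.mark.parametrize("n,fs,alpha", [(128, 128.0, 1.2), (256, 200.0, 0.7),
                                            (100, 50.0, 1.0), (64, 64.0, 2.0)])
    def test_matches_direct_integration(self, n, fs, alpha):
        """The FFT voice algorithm equals direct numerical integration of
        the defining integral (periodized window) within 1%."""
        rng = np.random.default_rng(n)
        x = rng.standard_normal(n)
        st_mat = s_transform(TimeSignal(x, fs), alpha, None, include_dc=False)
        ref = direct_s_transform(x, fs, alpha, st_mat.freqs)
        err = np.abs(st_mat.coefficients - ref).max() / np.abs(ref).max()
        assert err < 0.01

    def test_constant_signal_has_no_oscillatory_content(self):
        sig = TimeSignal(np.full(256, 3.7), 100.0)
        st_mat = s_transform(sig, 1.0, None)
        assert np.abs(st_mat.coefficients[st_mat.freqs > 0]).max() < 1e-9 * 3.7
        # DC row carries the mean
        assert np.allclose(st_mat.coefficients[0], 3.7)

    def test_sinusoid_peaks_at_its_frequency(self):
        """Every interior time column of a 10 Hz tone peaks at the 10 Hz voice."""
        t = np.arange(200) / 200.0
        sig = TimeSignal(np.sin(2 * np.pi * 10 * t), 200.0)
        st_mat = s_transform(sig, 1.0, None, include_dc=False)
        peak_freqs = st_mat.freqs[np.abs(st_mat.coefficients).argmax(axis=0)]
        assert set(peak_freqs[20:-20]) == {10.0}

    def test_max_freq_restricts_rows(self):
        sig = TimeSignal(np.random.default_rng(0).standard_normal(400), 400.0)
        st_mat = s_transform(sig, 1.0, 80.0, include_dc=False)
        assert st_mat.freqs.max() <= 80.0
        with pytest.raises(InvalidInputError):
            s_transform(sig, 1.0, 500.0)  # above Nyquist

    def test_input_validation(self):
        sig = TimeSignal(np.ones(16), 10.0)
        with pytest.raises(DomainError):
            s_transform(sig, -1.0)
        with pytest.raises(InvalidInputError):
            TimeSignal(np.array([1.0, np.nan]), 10.0)
        with pytest.raises(InvalidInputError):
            TimeSignal(np.array([1.0]), 10.0)


class TestConcentrationMeasure:
    def test_single_cell_is_maximally_concentrated(self):
        m = np.zeros((4, 5))
        m[2, 3] = 7.0
        assert concentration_measure(_unit_matrix(m)) == pytest.approx(1.0)

    def test_uniform_matrix_closed_form(self):
        m = np.full((4, 5), 2.0)
        assert concentration_measure(_unit_matrix(m)) == pytest.approx(
            1.0 / np.sqrt(20.0)
        )

    def test_impulse_beats_broadband_noise(self):
        """An impulse-like transient concentrates better than noise of
        equal energy on the same grid."""
        fs = 500.0
        rng = np.random.default_rng(1)
        t = np.arange(500) / fs
        impulse = np.exp(-0.5 * ((t - 0.5) / 0.01) ** 2) * np.sin(2 * np.pi * 60 * t)
        noise = rng.standard_normal(500)
        noise *= np.sqrt(np.sum(impulse**2) / np.sum(noise**2))
        cm_i = concentration_measure(s_transform(TimeSignal(impulse, fs), 1.0, None))
        cm_n = concentration_measure(s_transform(TimeSignal(noise, fs), 1.0, None))
        assert cm_i > cm_n

    @given(st.floats(min_value=1e-3, max_value=1e3).filter(lambda k: k != 0))
    def test_scale_invariance(self, k):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(128)
        cm1 = concentration_measure(s_transform(TimeSignal(x, 100.0), 1.0, None))
        cm2 = concentration_measure(s_transform(TimeSignal(k * x, 100.0), 1.0, None))
        assert cm2 == pytest.approx(cm1, rel=1e-9)

    def test_zero_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            concentration_measure(_unit_matrix(np.zeros((3, 3))))


class TestOptimizeAlpha:
    def test_default_grid_is_inclusive_16_points(self):
        grid = np.asarray(DEFAULT_ALPHA_GRID)
        assert grid.size == 16
        assert grid[0] == pytest.approx(0.5)
        assert grid[-1] == pytest.approx(2.0)
        assert np.allclose(np.diff(grid), 0.1)

    def test_profile_invariants(self):
        sig = s1_like_signal()
        prof = optimize_alpha(sig)
        assert prof.alpha_grid.size == prof.cm_values.size == 16
        assert np.all(prof.cm_values > 0)
        assert prof.alpha_opt in prof.alpha_grid
        assert prof.cm_values[prof.alpha_grid == prof.alpha_opt] == prof.cm_values.max()

    def test_amplitude_scaling_leaves_profile_unchanged(self):
        sig = s2_like_signal()
        scaled = TimeSignal(-5.0 * sig.samples, sig.sampling_rate)
        p1, p2 = optimize_alpha(sig), optimize_alpha(scaled)
        assert p1.alpha_opt == p2.alpha_opt
        assert np.allclose(p1.cm_values, p2.cm_values)

    def test_grid_order_does_not_matter(self):
        sig = s2_like_signal()
        grid = [1.3, 0.5, 2.0, 0.9, 0.7]
        p1 = optimize_alpha(sig, grid)
        p2 = optimize_alpha(sig, list(reversed(grid)))
        assert p1.alpha_opt == p2.alpha_opt
        assert np.allclose(p1.cm_values, p2.cm_values)

    def test_s1_like_prefers_wider_window_than_s2_like(self):
        """The booming multi-component sound needs finer frequency
        resolution (larger alpha) than the short high-pitched snap."""
        a_s1 = optimize_alpha(s1_like_signal()).alpha_opt
        a_s2 = optimize_alpha(s2_like_signal()).alpha_opt
        assert a_s1 > a_s2

    def test_error_cases(self):
        sig = s1_like_signal()
        with pytest.raises(InvalidInputError):
            optimize_alpha(sig, [])
        with pytest.raises(DomainError):
            optimize_alpha(sig, [0.5, -1.0])
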