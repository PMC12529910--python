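"""Windowing, Fourier transform, Pade refinement, peaks, scaling exponents."""

import numpy as np
import pytest

from rtbse.spectra import (
    SpectrumConfig,
    WindowSpec,
    field_spectrum,
    fit_peaks,
    fourier_dipole,
    pade_refine,
    polarizability,
    scaling_analysis,
)
from rtbse.system import FieldSpec, Trajectory
from rtbse.units import HARTREE_EV, fs_to_au


def _trajectory(times_au, mu_x):
    mu = np.zeros((3, times_au.size))
    mu[0] = mu_x
    return Trajectory(times=times_au, dipole=mu,
                      field_trace=np.zeros_like(times_au), diagnostics={})


class TestWindow:
    def test_exponential_attenuation_e_minus_4_at_20fs(self):
        """gamma = 0.2 / fs reduces the 20 fs sample by exactly e^-4."""
        w = WindowSpec(kind="exponential", gamma_fs=0.2)
        val = w.values(np.array([fs_to_au(20.0)]))[0]
        assert val == pytest.approx(np.exp(-4.0), rel=1e-12)

    def test_zero_damping_leaves_series_unchanged(self):
        w = WindowSpec(kind="exponential", gamma_fs=0.0)
        t = fs_to_au(np.linspace(0, 20, 64))
        np.testing.assert_array_equal(w.values(t), np.ones(64))

    def test_gaussian_window_is_unity_at_center(self):
        w = WindowSpec(kind="gaussian", center_fs=32.6, spread_fs=4.0)
        assert w.values(np.array([fs_to_au(32.6)]))[0] == pytest.approx(1.0)


class TestFourier:
    def test_single_mode_peaks_at_nearest_grid_frequency(self):
        dt = 0.5
        t = dt * np.arange(4096)
        om0 = 0.21
        sig = np.cos(om0 * t) * np.exp(-0.002 * t)
        omega, s = fourier_dipole(sig, dt)
        i = np.argmax(np.abs(s))
        assert abs(omega[i] - om0) <= omega[1] - omega[0]

    def test_constant_signal_has_weight_only_at_zero(self):
        omega, s = fourier_dipole(np.ones(512), 0.3)
        mag = np.abs(s)
        assert np.argmax(mag) == 0
        assert mag[1:].max() < 1e-10 * mag[0]

    def test_damped_cosine_matches_lorentzian_closed_form(self):
        dt = 0.2
        n = 20000
        t = dt * np.arange(n)
        om0, gamma = 0.25, 0.002  # gamma * T = 8
        sig = np.cos(om0 * t) * np.exp(-gamma * t)
        omega, s = fourier_dipole(sig, dt)
        sel = (omega > 0.1) & (omega < 0.4)
        expected = 0.5 / (gamma - 1j * (omega[sel] - om0)) \
            + 0.5 / (gamma - 1j * (omega[sel] + om0))
        err = np.max(np.abs(s[sel] - expected)) / np.max(np.abs(expected))
        assert err < 0.01


class TestPadeRefine:
    def test_exact_recovery_of_lower_degree_rational(self):
        """Samples from a low-degree rational in the fit variable are
        reproduced exactly at off-sample points."""
        cfg = SpectrumConfig(pade_fit_max_energy=200.0, n_pade_params=8)
        wmax = 200.0 / HARTREE_EV
        tau = np.pi / wmax
        # real coefficients keep f(-w) = conj(f(w)), matching a real signal
        a = np.array([0.3, -0.2, 0.05, 0.01])
        b = np.array([1.0, 0.2, 0.1, -0.02])

        def f(w):
            z = np.exp(1j * tau * w)
            return np.polyval(a[::-1], z) / np.polyval(b[::-1], z)

        w_coarse = np.linspace(0.0, wmax, 40)
        w_out = np.linspace(0.013, 0.6, 57)
        _, vals, info = pade_refine(w_coarse, f(w_coarse), cfg, w_out)
        assert not info["fallback"]
        expected = f(w_out)
        assert np.max(np.abs(vals - expected)) / np.max(np.abs(expected)) < 1e-8

    def test_two_close_lorentzians_resolved_on_fine_grid(self):
        """A 20 fs two-mode trajectory: refined peak positions land within one
        20 meV output step of the true mode energies."""
        dt = fs_to_au(1e-3)
        n = 20000
        t = dt * np.arange(n)
        e1, e2 = 6.0 / HARTREE_EV, 6.5 / HARTREE_EV
        gamma = 0.2 / fs_to_au(1.0)
        sig = (np.cos(e1 * t) + 0.7 * np.cos(e2 * t)) * np.exp(-gamma * t)
        omega, s = fourier_dipole(sig, dt)
        cfg = SpectrumConfig()
        grid_au, vals, info = pade_refine(omega, s, cfg)
        assert not info["fallback"]
        # cosine modes transform to true Lorentzians in the real part
        peaks = fit_peaks(grid_au * HARTREE_EV, np.real(vals),
                          min_rel_intensity=0.2)
        positions = [p.position for p in peaks]
        assert min(abs(p - 6.0) for p in positions) <= 0.021
        assert min(abs(p - 6.5) for p in positions) <= 0.021

    def test_reality_condition_on_refined_spectrum(self):
        dt = fs_to_au(1e-3)
        t = dt * np.arange(8000)
        sig = np.cos(0.2 * t) * np.exp(-0.001 * t)
        omega, s = fourier_dipole(sig, dt)
        cfg = SpectrumConfig()
        w_test = np.linspace(0.05, 0.5, 31)
        _, plus, _ = pade_refine(omega, s, cfg, w_test)
        _, minus, _ = pade_refine(omega, s, cfg, -w_test)
        np.testing.assert_allclose(minus, np.conj(plus), rtol=1e-6, atol=1e-8)

    def test_parseval_consistency_of_transform(self):
        # discrete Parseval: time-domain energy equals spectral energy with
        # the documented x dt normalization
        dt = 0.3
        sig = np.cos(0.4 * dt * np.arange(4096)) * np.exp(
            -0.004 * dt * np.arange(4096))
        full = np.fft.fft(sig) * dt
        assert np.sum(sig**2) * dt == pytest.approx(
            np.sum(np.abs(full) ** 2) / (sig.size * dt), rel=1e-12)


class TestPolarizability:
    def test_flat_response_recovers_constant(self):
        omega = np.linspace(0, 1, 11)
        e = np.full(11, 2.0, dtype=complex)
        mu = 3.5 * e
        np.testing.assert_allclose(polarizability(mu, e), 3.5)

    def test_vanishing_field_is_masked(self):
        omega = np.linspace(0, 1, 5)
        e = np.array([1.0, 0.0, 1.0, 1.0, 0.0], dtype=complex)
        alpha = polarizability(np.ones(5, dtype=complex), e)
        assert np.isnan(alpha[1]) and np.isnan(alpha[4])
        assert alpha[0] == 1.0

    def test_pulse_field_spectrum_matches_numerical_transform(self):
        # center the pulse late enough that the envelope is negligible at t=0
        f = FieldSpec.pulse(amplitude=0.01, carrier=6.0 / HARTREE_EV,
                            center=fs_to_au(22.0), width=fs_to_au(4.2))
        dt = fs_to_au(2e-3)
        n = int(fs_to_au(60.0) / dt)
        t = dt * np.arange(n)
        from rtbse.hamiltonian import pulse_amplitude

        e_t = np.array([pulse_amplitude(ti, f) for ti in t])
        omega, e_num = fourier_dipole(e_t, dt)
        sel = (omega * HARTREE_EV > 4) & (omega * HARTREE_EV < 8)
        e_ana = field_spectrum(omega[sel], f)
        err = np.max(np.abs(e_num[sel] - e_ana)) / np.max(np.abs(e_ana))
        assert err < 1e-6


class TestFitPeaks:
    def _lor(self, x, a, x0, g):
        return a * g**2 / ((x - x0) ** 2 + g**2)

    def test_single_lorentzian_position_recovered(self):
        x = np.arange(0.0, 20.0, 0.02)
        y = self._lor(x, 2.0, 6.0, 0.13)
        peaks = fit_peaks(x, y)
        assert len(peaks) == 1
        assert peaks[0].position == pytest.approx(6.0, abs=1e-3)
        assert peaks[0].width == pytest.approx(0.13, rel=0.05)

    def test_two_equal_lorentzians_both_found(self):
        x = np.arange(0.0, 20.0, 0.02)
        y = self._lor(x, 1.0, 5.0, 0.1) + self._lor(x, 1.0, 9.0, 0.1)
        peaks = fit_peaks(x, y)
        assert len(peaks) == 2
        assert peaks[0].relative_intensity == pytest.approx(1.0, abs=0.02)
        assert peaks[1].relative_intensity == pytest.approx(1.0, abs=0.02)

    def test_overlapping_peaks_stable_under_grid_shift(self):
        """Two peaks 0.1 eV apart with 0.13 eV widths merge; the merged count
        and position must not depend on the grid offset."""
        counts, positions = [], []
        for shift in (0.0, 0.01):
            x = np.arange(0.0, 12.0, 0.02) + shift
            y = self._lor(x, 1.0, 6.0, 0.13) + self._lor(x, 0.9, 6.1, 0.13)
            peaks = fit_peaks(x, y, min_rel_intensity=0.05)
            counts.append(len(peaks))
            positions.append(peaks[0].position)
        assert counts[0] == counts[1]
        assert abs(positions[0] - positions[1]) < 0.02

    def test_no_peaks_returns_empty(self):
        assert fit_peaks(np.linspace(0, 1, 50), np.zeros(50)) == []


class TestScaling:
    def test_quadratic_magnitudes_give_slope_two(self):
        e0 = np.array([1e-4, 2e-4, 4e-4])
        fits = scaling_analysis(e0, {"shg": 3.0 * e0**2})
        assert fits["shg"].exponent == pytest.approx(2.0, abs=1e-12)

    def test_linear_magnitudes_give_slope_one(self):
        e0 = np.array([1e-4, 2e-4, 4e-4])
        fits = scaling_analysis(e0, {"lin": 0.7 * e0})
        assert fits["lin"].exponent == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_magnitudes_excluded_and_reported(self):
        e0 = np.array([1.0, 2.0, 4.0, 8.0])
        fits = scaling_analysis(e0, {"f": np.array([1.0, 4.0, 0.0, 64.0])})
        assert fits["f"].excluded == [2]
        assert fits["f"].n_used == 3
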