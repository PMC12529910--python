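"""Integrator correctness and conservation laws of the propagation."""

import numpy as np
import pytest
import scipy.optimize

from rtbse import (
    FieldSpec,
    PropagationConfig,
    PropagationError,
    delta_kick,
    initial_density,
    make_two_level,
    propagate,
    similarity_propagate,
)
from rtbse.propagator import OverlapFactors, etrs_step
from rtbse.hamiltonian import HamiltonianEngine
from rtbse.units import HARTREE_EV, fs_to_au

from conftest import random_hermitian, random_spd

DT_1AS = fs_to_au(1e-3)


class TestSimilarityPropagate:
    def test_zero_hamiltonian_is_identity(self, rng):
        rho = random_hermitian(rng, 3)
        out = similarity_propagate(rho, np.zeros((3, 3)), np.eye(3), 0.5)
        np.testing.assert_allclose(out, rho, atol=1e-15)

    def test_commuting_density_is_stationary(self, rng):
        h = random_hermitian(rng, 3).real
        rho = scipy.linalg.expm(-h)  # function of h commutes with it
        for method in ("bch", "diag"):
            out = similarity_propagate(rho, h, np.eye(3), 0.7, method=method)
            np.testing.assert_allclose(out, rho, atol=1e-9)

    def test_bch_and_diag_agree(self, rng):
        for _ in range(3):
            n = 4
            h = random_hermitian(rng, n)
            s = random_spd(rng, n)
            rho = random_hermitian(rng, n)
            a = similarity_propagate(rho, h, s, DT_1AS, method="bch",
                                     threshold=1e-14)
            b = similarity_propagate(rho, h, s, DT_1AS, method="diag")
            assert np.max(np.abs(a - b)) < 1e-10

    def test_bch_nonconvergence_raises(self, rng):
        h = 100.0 * random_hermitian(rng, 3)
        rho = random_hermitian(rng, 3)
        with pytest.raises(PropagationError, match="time step"):
            similarity_propagate(rho, h, np.eye(3), 10.0, method="bch")


class TestDeltaKick:
    def test_zero_strength_is_identity(self, random_bundle):
        rho0 = initial_density(random_bundle)
        out = delta_kick(rho0, random_bundle, 0.0, (1, 0, 0))
        np.testing.assert_allclose(out.rho, rho0.rho, atol=1e-15)

    def test_preserves_trace_and_idempotency(self, random_bundle):
        rho0 = initial_density(random_bundle)
        out = delta_kick(rho0, random_bundle, 0.4, (0, 1, 0))
        s = random_bundle.overlap
        assert abs(out.trace_s(s) - random_bundle.n_occ) < 1e-12
        assert out.idempotency_error(s) < 1e-12

    def test_weak_kick_response_is_linear(self, two_level_ip):
        amps = []
        for strength in (1e-3, 5e-4):
            traj = propagate(two_level_ip, FieldSpec.kick(strength),
                             PropagationConfig(n_steps=1500))
            amps.append(np.ptp(traj.induced_dipole()[0]))
        assert amps[0] / amps[1] == pytest.approx(2.0, rel=1e-3)


class TestEtrsStep:
    def test_noninteracting_sc_converges_immediately(self, two_level_ip):
        rho0 = initial_density(two_level_ip).rho
        rho = delta_kick(rho0, two_level_ip, 0.1, (1, 0, 0)).rho
        engine = HamiltonianEngine(two_level_ip)
        sf = OverlapFactors(two_level_ip.overlap)
        _, iters = etrs_step(rho, 0.0, DT_1AS, two_level_ip, FieldSpec.none(),
                             PropagationConfig(), engine, sf, rho0)
        assert iters == 1

    def test_two_level_phase_evolution_closed_form(self):
        """Off-diagonal element acquires exp(-i(e_a - e_i) dt) per step."""
        sys = make_two_level(6.0, 1.0, "none")
        gap = 6.0 / HARTREE_EV
        rho0 = initial_density(sys).rho
        rho = delta_kick(rho0, sys, 0.01, (1, 0, 0)).rho
        engine = HamiltonianEngine(sys)
        sf = OverlapFactors(sys.overlap)
        cfg = PropagationConfig()
        z0 = rho[0, 1]
        r = rho
        n_steps = 1000
        for _ in range(n_steps):
            r, _ = etrs_step(r, 0.0, DT_1AS, sys, FieldSpec.none(), cfg,
                             engine, sf, rho0)
        expected = z0 * np.exp(1j * gap * DT_1AS * n_steps)
        assert abs(r[0, 1] - expected) < 1e-10


class TestPropagate:
    def test_equilibrium_is_stationary(self, random_bundle):
        traj = propagate(random_bundle, FieldSpec.none(),
                         PropagationConfig(n_steps=500))
        assert np.max(np.abs(traj.induced_dipole())) < 1e-12

    def test_kick_frequency_matches_gap(self, two_level_ip):
        traj = propagate(two_level_ip, FieldSpec.kick(1e-3),
                         PropagationConfig(n_steps=4000))
        mu = traj.induced_dipole()[0]

        def model(t, a, w, phi, c):
            return a * np.cos(w * t + phi) + c

        gap = 6.0 / HARTREE_EV
        popt, _ = scipy.optimize.curve_fit(
            model, traj.times, mu, p0=(mu.max(), gap * 1.01, 0.0, 0.0))
        assert abs(popt[1] - gap) / gap < 1e-4

    def test_conservation_diagnostics_interacting(self, random_bundle):
        traj = propagate(random_bundle, FieldSpec.kick(5e-3),
                         PropagationConfig(n_steps=1000))
        d = traj.diagnostics
        assert np.max(np.abs(d["trace_s"] - d["trace_s"][0])) < 1e-12
        assert np.max(d["idempotency"]) < 1e-10
        assert np.ptp(d["energy"]) < 1e-9

    def test_time_grid_uniform(self, two_level_ip):
        traj = propagate(two_level_ip, FieldSpec.none(),
                         PropagationConfig(n_steps=10))
        np.testing.assert_allclose(np.diff(traj.times), traj.dt, rtol=1e-12)

    def test_time_reversal_noninteracting(self):
        sys = make_two_level(6.0, 1.0, "none")
        rho0 = initial_density(sys).rho
        rho = delta_kick(rho0, sys, 0.05, (1, 0, 0)).rho
        engine = HamiltonianEngine(sys)
        sf = OverlapFactors(sys.overlap)
        cfg = PropagationConfig()
        fwd, _ = etrs_step(rho, 0.0, DT_1AS, sys, FieldSpec.none(), cfg,
                           engine, sf, rho0)
        back, _ = etrs_step(fwd, 0.0, -DT_1AS, sys, FieldSpec.none(), cfg,
                            engine, sf, rho0)
        assert np.max(np.abs(back - rho)) < 1e-10

    def test_dt_convergence_of_peak_position(self, two_level_ip):
        """Halving the step from 1 as leaves the spectral peak in place."""
        from rtbse.pipelines import kick_absorption_spectrum
        from rtbse.spectra import SpectrumConfig, fit_peaks

        positions = []
        for dt_scale, steps in ((1.0, 6000), (0.5, 12000)):
            cfg = PropagationConfig(dt=DT_1AS * dt_scale, n_steps=steps)
            spec = kick_absorption_spectrum(
                two_level_ip, cfg, SpectrumConfig(), directions=(0,))
            peaks = fit_peaks(spec.omega_ev, np.imag(spec.alpha_iso))
            positions.append(peaks[0].position)
        assert abs(positions[0] - positions[1]) < 1e-3
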