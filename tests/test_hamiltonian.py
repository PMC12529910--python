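"""Mean-field contractions, field coupling, effective-Hamiltonian assembly."""

import numpy as np
import pytest

from rtbse import (
    ElectronicSystem,
    FieldSpec,
    HamiltonianEngine,
    PairKernel,
    build_heff,
    field_matrix,
    hartree_matrix,
    make_random_bundle,
    pulse_amplitude,
    sex_matrix,
)
from rtbse.units import HARTREE_EV, fs_to_au

from conftest import random_hermitian


def _one_basis_system(v_val, w_val):
    return ElectronicSystem(
        n_ao=1, n_occ=1,
        overlap=np.eye(1), h_qp=np.zeros((1, 1)),
        dipole=np.zeros((3, 1, 1)),
        coulomb=PairKernel.from_dense(np.full((1, 1, 1, 1), v_val)),
        screened=PairKernel.from_dense(np.full((1, 1, 1, 1), w_val)),
        occupations=np.array([1.0]),
    )


def _hartree_loop_oracle(v, rho):
    n = rho.shape[0]
    out = np.zeros((n, n), dtype=complex)
    for m in range(n):
        for nu in range(n):
            for s in range(n):
                for l in range(n):
                    out[m, nu] += v[m, nu, s, l] * rho[l, s]
    return 2.0 * out


def _exchange_loop_oracle(w, rho):
    n = rho.shape[0]
    out = np.zeros((n, n), dtype=complex)
    for m in range(n):
        for nu in range(n):
            for l in range(n):
                for s in range(n):
                    out[m, nu] -= w[m, l, s, nu] * rho[l, s]
    return out


class TestHartree:
    def test_zero_density_gives_zero(self, random_bundle):
        assert np.all(hartree_matrix(np.zeros((4, 4)), random_bundle) == 0)

    def test_single_term_contraction_with_spin_factor(self):
        sys = _one_basis_system(0.625, 0.0)
        vh = hartree_matrix(np.array([[1.0]]), sys)
        np.testing.assert_allclose(vh, [[1.25]], rtol=1e-14)

    def test_ri_path_matches_quadruple_loop_oracle(self, rng):
        sys = make_random_bundle(3, 1, 9, seed=4)
        rho = random_hermitian(rng, 3)
        v_dense = sys.coulomb.dense()
        expected = _hartree_loop_oracle(v_dense, rho)
        got = hartree_matrix(rho, sys)
        np.testing.assert_allclose(got, expected, atol=1e-12)
        # explicit dense path on the reconstructed tensor agrees too
        sys_dense = make_random_bundle(3, 1, 9, seed=4)
        sys_dense.coulomb = PairKernel.from_dense(v_dense)
        np.testing.assert_allclose(hartree_matrix(rho, sys_dense), expected,
                                   atol=1e-12)


class TestScreenedExchange:
    def test_zero_density_gives_zero(self, random_bundle):
        assert np.all(sex_matrix(np.zeros((4, 4)), random_bundle) == 0)

    def test_single_term_sign(self):
        sys = _one_basis_system(0.0, 0.37)
        sx = sex_matrix(np.array([[1.0]]), sys)
        np.testing.assert_allclose(sx, [[-0.37]], rtol=1e-14)

    def test_w_equal_v_reproduces_negative_hf_exchange(self, rng):
        """With W = V the SEX contraction is minus Hartree-Fock exchange."""
        sys = make_random_bundle(3, 1, 9, seed=4)
        sys.screened = PairKernel.from_ri(sys.coulomb.factors,
                                          sys.coulomb.metric)
        rho = random_hermitian(rng, 3)
        expected = _exchange_loop_oracle(sys.coulomb.dense(), rho)
        np.testing.assert_allclose(sex_matrix(rho, sys), expected, atol=1e-12)

    def test_ri_path_matches_quadruple_loop_oracle(self, rng):
        sys = make_random_bundle(3, 1, 9, seed=6)
        rho = random_hermitian(rng, 3)
        expected = _exchange_loop_oracle(sys.screened.dense(), rho)
        np.testing.assert_allclose(sex_matrix(rho, sys), expected, atol=1e-12)

    def test_hermiticity_preserved(self, rng, random_bundle):
        for _ in range(5):
            rho = random_hermitian(rng, 4)
            sx = sex_matrix(rho, random_bundle)
            vh = hartree_matrix(rho, random_bundle)
            assert np.max(np.abs(sx - sx.conj().T)) < 1e-12
            assert np.max(np.abs(vh - vh.conj().T)) < 1e-12


class TestEngine:
    def test_engine_matches_module_functions(self, rng, random_bundle):
        eng = HamiltonianEngine(random_bundle)
        rho = random_hermitian(rng, 4)
        np.testing.assert_allclose(eng.hartree(rho),
                                   hartree_matrix(rho, random_bundle),
                                   atol=1e-13)
        np.testing.assert_allclose(eng.sex(rho),
                                   sex_matrix(rho, random_bundle), atol=1e-13)


class TestPulse:
    def test_envelope_maximum(self):
        f = FieldSpec.pulse(amplitude=0.02, carrier=0.0, center=100.0, width=30.0)
        assert pulse_amplitude(100.0, f) == pytest.approx(0.02)

    def test_gaussian_width_definition(self):
        f = FieldSpec.pulse(amplitude=1.0, carrier=0.0, center=100.0, width=30.0)
        assert pulse_amplitude(130.0, f) == pytest.approx(np.exp(-0.5))
        assert pulse_amplitude(70.0, f) == pytest.approx(np.exp(-0.5))

    def test_reference_pulse_envelope_shape(self):
        """t0 = 12.6 fs, sigma = 4.2 fs, hw0 = 6 eV: maximum near t0 and a
        strongly suppressed amplitude at t = 0."""
        f = FieldSpec.pulse(
            amplitude=1.0, carrier=6.0 / HARTREE_EV,
            center=fs_to_au(12.6), width=fs_to_au(4.2),
        )
        t = np.arange(0.0, fs_to_au(25.0), fs_to_au(1e-3))
        e = np.array([pulse_amplitude(ti, f) for ti in t])
        t_max = t[np.argmax(np.abs(e))]
        assert abs(t_max - fs_to_au(12.6)) < fs_to_au(0.3)
        assert abs(pulse_amplitude(0.0, f)) <= np.exp(-4.5)


class TestFieldMatrix:
    def test_zero_field_zero_matrix(self, random_bundle):
        f = FieldSpec.none()
        assert np.all(field_matrix(5.0, f, random_bundle) == 0)

    def test_polarized_coupling_scales_dipole(self, random_bundle):
        f = FieldSpec.pulse(amplitude=0.03, carrier=0.0, center=0.0, width=1e6,
                            polarization=(1, 0, 0))
        u = field_matrix(0.0, f, random_bundle)
        np.testing.assert_allclose(u, 0.03 * random_bundle.dipole[0], rtol=1e-12)

    def test_diagonal_polarization_combination(self, random_bundle):
        e0 = 0.02
        f = FieldSpec.pulse(amplitude=e0, carrier=0.0, center=0.0, width=1e6,
                            polarization=np.array([1, 1, 0]) / np.sqrt(2))
        u = field_matrix(0.0, f, random_bundle)
        expected = (e0 / np.sqrt(2)) * (random_bundle.dipole[0]
                                        + random_bundle.dipole[1])
        np.testing.assert_allclose(u, expected, rtol=1e-12)


class TestBuildHeff:
    def test_equilibrium_density_reduces_to_core(self, random_bundle):
        from rtbse import initial_density

        rho0 = initial_density(random_bundle)
        h = build_heff(0.0, rho0, rho0, random_bundle, FieldSpec.none())
        np.testing.assert_allclose(h.total, random_bundle.h_qp, atol=1e-14)
        assert np.all(h.hartree_delta == 0) and np.all(h.sex_delta == 0)

    def test_contraction_linearity(self, rng, random_bundle):
        from rtbse import initial_density

        rho0 = initial_density(random_bundle).rho
        r1 = rho0 + random_hermitian(rng, 4) * 0.01
        r2 = rho0 + random_hermitian(rng, 4) * 0.01
        f = FieldSpec.none()
        h_sum = build_heff(0.0, r1 + r2 - rho0, rho0, random_bundle, f)
        h1 = build_heff(0.0, r1, rho0, random_bundle, f)
        h2 = build_heff(0.0, r2, rho0, random_bundle, f)
        np.testing.assert_allclose(h_sum.hartree_delta,
                                   h1.hartree_delta + h2.hartree_delta,
                                   atol=1e-12)
        np.testing.assert_allclose(h_sum.sex_delta,
                                   h1.sex_delta + h2.sex_delta, atol=1e-12)

    def test_total_recomposes_from_blocks(self, rng, random_bundle):
        rho0 = np.zeros((4, 4), dtype=complex)
        rho = random_hermitian(rng, 4)
        f = FieldSpec.pulse(amplitude=0.01, carrier=0.1, center=0.0, width=50.0)
        h = build_heff(3.0, rho, rho0, random_bundle, f)
        total = (random_bundle.h_qp + field_matrix(3.0, f, random_bundle)
                 + hartree_matrix(rho, random_bundle)
                 + sex_matrix(rho, random_bundle))
        np.testing.assert_allclose(h.total, total, atol=1e-13)
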