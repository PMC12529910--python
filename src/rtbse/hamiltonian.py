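"""Assembly of the time-dependent effective one-particle Hamiltonian.

The Hamiltonian driving the density-matrix propagation is

    H_eff(t) = h_qp + U(t) + V_H[rho(t) - rho(0)] + Sigma_SEX[rho(t) - rho(0)]

where ``h_qp`` holds the quasiparticle energies, ``U(t)`` couples the
length-gauge electric field through the dipole matrices, ``V_H`` is the
Hartree potential contracted from the bare Coulomb tensor, and ``Sigma_SEX``
is the screened-exchange self-energy contracted from the statically screened
Coulomb tensor ``W``.  Only *changes* of the density relative to the ground
state enter the mean-field terms, so the equilibrium density is stationary by
construction.

Spin convention (closed shell, one propagated spin channel, occupations in
{0, 1}): the Hartree contraction carries a factor 2 because the total density
of both channels screens, while screened exchange couples same-spin pairs
only and carries factor 1.  The same factor 2 multiplies the dipole
expectation value in :mod:`rtbse.propagator`.

Index pairing of the two contractions (real basis functions):

    V_H[rho]_{mu nu}      =  2 * sum_{lambda sigma} (mu nu|sigma lambda) rho_{lambda sigma}
    Sigma_SEX[rho]_{mu nu} = -  sum_{lambda sigma} W_{mu lambda, sigma nu} rho_{lambda sigma}

Hartree pairs the two indices of the *same* density; screened exchange pairs
one index of each, which is what makes it an exchange term.  Setting W equal
to the bare Coulomb tensor reproduces minus the Hartree-Fock exchange matrix
(a unit test holds this limit as the sign oracle).
"""

from __future__ import annotations

import numpy as np

from .system import (
    DensityMatrix,
    EffectiveHamiltonian,
    ElectronicSystem,
    FieldSpec,
    _spd_inverse,
)

__all__ = [
    "SPIN_FACTOR",
    "hartree_matrix",
    "sex_matrix",
    "pulse_amplitude",
    "field_matrix",
    "build_heff",
    "HamiltonianEngine",
]

#: Closed-shell spin degeneracy applied to Hartree and to dipole expectations.
SPIN_FACTOR = 2.0

# Below this basis size the engine precomputes dense pair-space matrices,
# turning each mean-field build into a single matrix-vector product.
_DENSE_PRECOMPUTE_MAX_N = 32


def _as_rho(rho) -> np.ndarray:
    return rho.rho if isinstance(rho, DensityMatrix) else np.asarray(rho)


def hartree_matrix(rho, system: ElectronicSystem) -> np.ndarray:
    """Hartree potential ``2 * sum (mu nu|sigma lambda) rho_{lambda sigma}``."""
    r = _as_rho(rho)
    kern = system.coulomb
    if kern.form == "dense":
        vh = np.einsum("mnsl,ls->mn", kern.tensor, r)
    else:
        t = kern.factors
        w = np.einsum("slq,ls->q", t, r)
        vh = np.einsum("mnp,p->mn", t, _spd_inverse(kern.metric) @ w)
    return SPIN_FACTOR * vh


def sex_matrix(rho, system: ElectronicSystem) -> np.ndarray:
    """Screened exchange ``- sum W_{mu lambda, sigma nu} rho_{lambda sigma}``."""
    r = _as_rho(rho)
    kern = system.screened
    if kern.form == "dense":
        sx = np.einsum("mlsn,ls->mn", kern.tensor, r)
    else:
        u = kern.factors
        a = np.einsum("mlp,ls->msp", u, r)
        b = a @ _spd_inverse(kern.metric)
        sx = np.einsum("msq,snq->mn", b, u)
    return -sx


def pulse_amplitude(t: float, field: FieldSpec) -> float:
    """Gaussian-enveloped carrier ``E0 cos(w0 t) exp(-(t-t0)^2/(2 sigma^2))``."""
    if field.kind != "pulse":
        return 0.0
    env = np.exp(-((t - field.center) ** 2) / (2.0 * field.width**2))
    return float(field.pulse_amplitude * np.cos(field.carrier * t) * env)


def field_matrix(t: float, field: FieldSpec, system: ElectronicSystem) -> np.ndarray:
    """Length-gauge coupling ``U(t) = E(t) * sum_j eps_j D_j`` (e = 1 a.u.)."""
    n = system.n_ao
    if field.kind != "pulse":
        return np.zeros((n, n))
    e_t = pulse_amplitude(t, field)
    if e_t == 0.0:
        return np.zeros((n, n))
    return e_t * system.dipole_along(field.polarization)


class HamiltonianEngine:
    """Precomputed contraction operators for repeated mean-field builds.

    For small basis sizes the bare and screened kernels are flattened once
    into pair-space matrices so that Hartree and SEX become matrix-vector
    products; otherwise the RI factors are pre-multiplied by the inverse
    auxiliary metric and contracted on the fly.  The screened tensor is never
    mutated: it enters only through read-only precomputed operators, mirroring
    the fact that W is computed once at the start of a simulation.
    """

    def __init__(self, system: ElectronicSystem):
        self.system = system
        n = system.n_ao
        self._n = n
        self._dense = n <= _DENSE_PRECOMPUTE_MAX_N
        if self._dense:
            v = system.coulomb.dense()
            w = system.screened.dense()
            # V_H row (mu nu), column (lambda sigma): V[m, n, s, l] -> [mn, ls]
            self._v_op = v.transpose(0, 1, 3, 2).reshape(n * n, n * n).copy()
            # SEX row (mu nu), column (lambda sigma): W[m, l, s, n] -> [mn, ls]
            self._w_op = w.transpose(0, 3, 1, 2).reshape(n * n, n * n).copy()
        else:
            if system.coulomb.form != "ri" or system.screened.form != "ri":
                raise ValueError(
                    "dense 4-index kernels beyond the precompute size limit; "
                    "supply RI-form tensors"
                )
            kv = system.coulomb
            self._tv = kv.factors.reshape(n * n, kv.factors.shape[2])
            self._tv_minv = self._tv @ _spd_inverse(kv.metric)
            kw = system.screened
            self._uw = kw.factors
            self._uw_minv = _spd_inverse(kw.metric)

    def hartree(self, rho: np.ndarray) -> np.ndarray:
        n = self._n
        if self._dense:
            return SPIN_FACTOR * (self._v_op @ rho.ravel()).reshape(n, n)
        w = self._tv.T @ rho.T.ravel()
        return SPIN_FACTOR * (self._tv_minv @ w).reshape(n, n)

    def sex(self, rho: np.ndarray) -> np.ndarray:
        n = self._n
        if self._dense:
            return -(self._w_op @ rho.ravel()).reshape(n, n)
        a = np.einsum("mlp,ls->msp", self._uw, rho)
        return -np.einsum("msq,snq->mn", a @ self._uw_minv, self._uw)

    def potential(self, delta_rho: np.ndarray) -> np.ndarray:
        """Hartree plus screened exchange of a density change."""
        return self.hartree(delta_rho) + self.sex(delta_rho)


def build_heff(
    t: float,
    rho,
    rho0,
    system: ElectronicSystem,
    field: FieldSpec,
    engine: HamiltonianEngine | None = None,
) -> EffectiveHamiltonian:
    """Assemble the four blocks of H_eff(t) for a given density."""
    r = _as_rho(rho)
    r0 = _as_rho(rho0)
    delta = r - r0
    if engine is None:
        hartree = hartree_matrix(delta, system)
        sex = sex_matrix(delta, system)
    else:
        hartree = engine.hartree(delta)
        sex = engine.sex(delta)
    return EffectiveHamiltonian(
        core=system.h_qp,
        field=field_matrix(t, field, system),
        hartree_delta=hartree,
        sex_delta=sex,
    )
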