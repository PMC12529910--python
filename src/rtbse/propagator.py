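"""Density-matrix propagation with the enforced time-reversal-symmetry scheme.

The equation of motion in a nonorthogonal basis,

    d rho / dt = -i (S^-1 H(t) rho - rho H(t) S^-1),

is integrated with the time-symmetric split step

    rho(t + dt/2) = exp(-i S^-1 H(t)    dt/2) rho(t)        exp(+i H(t)    S^-1 dt/2)
    rho(t + dt)   = exp(-i S^-1 H(t+dt) dt/2) rho(t + dt/2) exp(+i H(t+dt) S^-1 dt/2)

where H(t+dt) depends on rho(t+dt) itself; that implicit dependence is
resolved by self-consistent iteration on the density matrix.  Because every
update is a similarity transform by an S-unitary exponential, the scheme
conserves Hermiticity, the electron number Tr(rho S), and idempotency
rho S rho = rho exactly up to the exponential truncation threshold.  The
equation of motion carries no phenomenological damping.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.linalg

from .hamiltonian import (
    SPIN_FACTOR,
    HamiltonianEngine,
    field_matrix,
    pulse_amplitude,
)
from .system import (
    DensityMatrix,
    ElectronicSystem,
    FieldSpec,
    PropagationConfig,
    Trajectory,
    initial_density,
)

__all__ = [
    "PropagationError",
    "OverlapFactors",
    "similarity_propagate",
    "etrs_step",
    "delta_kick",
    "propagate",
]

BCH_ORDER_CAP = 40
OVERLAP_CONDITION_WARN = 1e10
TRACE_DRIFT_ABORT = 1e-6


class PropagationError(RuntimeError):
    pass


class OverlapFactors:
    """S^-1 and S^(+/-1/2), computed once per run by symmetric eigendecomposition."""

    def __init__(self, overlap: np.ndarray):
        self.s = overlap
        ev, vec = np.linalg.eigh(overlap)
        cond = ev[-1] / ev[0]
        if ev[0] <= 0:
            raise PropagationError("overlap not positive-definite")
        if cond > OVERLAP_CONDITION_WARN:
            warnings.warn(
                f"overlap condition number {cond:.2e} exceeds "
                f"{OVERLAP_CONDITION_WARN:.0e}; the inverse may be inaccurate",
                RuntimeWarning,
            )
        self.inv = (vec / ev) @ vec.T
        self.inv_sqrt = (vec / np.sqrt(ev)) @ vec.T
        self.sqrt = (vec * np.sqrt(ev)) @ vec.T
        self.identity = bool(np.allclose(overlap, np.eye(overlap.shape[0]),
                                         atol=1e-14))


def _ensure_factors(overlap) -> OverlapFactors:
    return overlap if isinstance(overlap, OverlapFactors) else OverlapFactors(np.asarray(overlap, dtype=float))


def similarity_propagate(
    rho: np.ndarray,
    heff_total: np.ndarray,
    overlap,
    dt_half: float,
    method: str = "bch",
    threshold: float = 1e-14,
) -> np.ndarray:
    """Apply ``exp(-i S^-1 H tau) rho exp(+i H S^-1 tau)`` for tau = dt_half.

    ``method="bch"`` sums the nested-commutator (Baker-Campbell-Hausdorff)
    series term by term until the largest element of the current term falls
    below ``threshold``; ``method="diag"`` builds the exponential exactly from
    the eigendecomposition of the symmetrized Hamiltonian
    S^(-1/2) H S^(-1/2).
    """
    sf = _ensure_factors(overlap)
    h = heff_total
    if method == "bch":
        m = h if sf.identity else sf.inv @ h
        md = m.conj().T
        term = np.asarray(rho, dtype=complex)
        out = term.copy()
        for k in range(1, BCH_ORDER_CAP + 1):
            term = (-1j * dt_half / k) * (m @ term - term @ md)
            out += term
            if np.max(np.abs(term)) < threshold:
                return out
        raise PropagationError(
            "BCH series did not reach the threshold within the order cap; "
            "reduce the time step"
        )
    elif method == "diag":
        h_sym = sf.inv_sqrt @ h @ sf.inv_sqrt
        ev, vec = np.linalg.eigh(0.5 * (h_sym + h_sym.conj().T))
        u = sf.inv_sqrt @ (vec * np.exp(-1j * dt_half * ev)) @ vec.conj().T @ sf.sqrt
        return u @ rho @ u.conj().T
    raise ValueError(f"unknown exponential method {method!r}")


def delta_kick(
    rho0,
    system: ElectronicSystem,
    kick_strength: float,
    polarization,
) -> DensityMatrix:
    """Impulsive boost ``exp(-i I S^-1 D_eps) rho(0) exp(+i I D_eps S^-1)``.

    Equivalent to the field ``E(t) = I eps delta(t)``; being an S-unitary
    conjugation it preserves Tr(rho S) and idempotency exactly.
    """
    r = rho0.rho if isinstance(rho0, DensityMatrix) else np.asarray(rho0, dtype=complex)
    d_eps = system.dipole_along(np.asarray(polarization, dtype=float))
    out = similarity_propagate(r, d_eps, system.overlap, kick_strength,
                               method="diag")
    return DensityMatrix(out)


def etrs_step(
    rho_t: np.ndarray,
    t: float,
    dt: float,
    system: ElectronicSystem,
    field: FieldSpec,
    config: PropagationConfig,
    engine: HamiltonianEngine,
    overlap_factors: OverlapFactors,
    rho0: np.ndarray,
) -> tuple[np.ndarray, int]:
    """One enforced-time-reversal-symmetry step; returns (rho(t+dt), SC count).

    The half step uses H(t); the final half step uses H(t+dt), iterated to
    self-consistency on the max-abs change of the density matrix.
    """

    def heff_total(rho: np.ndarray, time: float) -> np.ndarray:
        return system.h_qp + field_matrix(time, field, system) + engine.potential(rho - rho0)

    prop = lambda r, h: similarity_propagate(
        r, h, overlap_factors, 0.5 * dt, config.exp_method, config.bch_threshold
    )

    h_t = heff_total(rho_t, t)
    rho_half = prop(rho_t, h_t)

    # initial candidate from H built with the half-step density as guess
    cand = prop(rho_half, heff_total(rho_half, t + dt))
    for it in range(1, config.max_sc_iters + 1):
        h_next = heff_total(cand, t + dt)
        rho_new = prop(rho_half, h_next)
        residual = np.max(np.abs(rho_new - cand))
        cand = rho_new
        if residual < config.sc_threshold:
            return rho_new, it
    raise PropagationError(
        f"self-consistent ETRS loop did not converge in {config.max_sc_iters} "
        f"iterations (last residual {residual:.3e})"
    )


def propagate(
    system: ElectronicSystem,
    field: FieldSpec,
    config: PropagationConfig,
    rho_start: DensityMatrix | None = None,
) -> Trajectory:
    """Run the full real-time simulation and record the dipole trajectory.

    A kick field is applied once at t = 0 as a unitary boost of the
    equilibrium density; a pulse field enters the Hamiltonian continuously.
    Each recorded sample carries the spin-summed electronic dipole
    ``mu_j = -2 Tr(rho D_j)``, the applied field amplitude, and conservation
    diagnostics (electron number, idempotency, energy functional, SC counts).
    """
    rho0_dm = initial_density(system) if rho_start is None else rho_start
    rho0 = rho0_dm.rho
    sf = OverlapFactors(system.overlap)
    engine = HamiltonianEngine(system)

    rho = rho0.copy()
    if field.kind == "kick":
        rho = delta_kick(rho, system, field.kick_strength, field.polarization).rho

    n_samples = config.n_steps + 1
    times = config.dt * np.arange(n_samples)
    dipole = np.empty((3, n_samples))
    field_trace = np.empty(n_samples)
    trace_s = np.empty(n_samples)
    idem = np.empty(n_samples)
    herm = np.empty(n_samples)
    energy = np.empty(n_samples)
    sc_iters = np.zeros(n_samples, dtype=int)

    dips = system.dipole
    s_mat = system.overlap
    n_occ = float(system.n_occ)

    def record(i: int, r: np.ndarray, t: float):
        for j in range(3):
            dipole[j, i] = -SPIN_FACTOR * np.real(np.trace(r @ dips[j]))
        field_trace[i] = pulse_amplitude(t, field)
        tr = float(np.real(np.trace(r @ s_mat)))
        trace_s[i] = tr
        idem[i] = float(np.max(np.abs(r @ s_mat @ r - r)))
        herm[i] = float(np.max(np.abs(r - r.conj().T)))
        delta = r - rho0
        u_t = field_matrix(t, field, system)
        vh = engine.hartree(delta)
        sx = engine.sex(delta)
        energy[i] = float(np.real(
            np.trace(r @ (system.h_qp + u_t))
            + 0.5 * np.trace(delta @ vh)
            + 0.5 * np.trace(delta @ sx)
        ))
        if abs(tr - n_occ) > TRACE_DRIFT_ABORT:
            raise PropagationError(
                f"electron-number drift {tr - n_occ:.3e} exceeded the hard "
                f"bound at t = {t:.3f} a.u."
            )

    record(0, rho, 0.0)
    for i in range(1, n_samples):
        t = times[i - 1]
        rho, its = etrs_step(rho, t, config.dt, system, field, config,
                             engine, sf, rho0)
        sc_iters[i] = its
        record(i, rho, times[i])

    return Trajectory(
        times=times,
        dipole=dipole,
        field_trace=field_trace,
        diagnostics={
            "trace_s": trace_s,
            "idempotency": idem,
            "hermiticity": herm,
            "energy": energy,
            "sc_iters": sc_iters,
        },
    )
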