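"""Electronic-system bundle: validated operator matrices, state types, file I/O.

An :class:`ElectronicSystem` collects every static quantity the real-time
propagation needs: the overlap matrix ``S`` of the (generally nonorthogonal)
basis, the quasiparticle one-particle Hamiltonian ``h_qp``, the three Cartesian
dipole matrices, the bare Coulomb tensor ``V`` and the statically screened
Coulomb tensor ``W``, and the orbital occupations of one spin channel of a
closed-shell system.  Everything is stored in Hartree atomic units.

Two-electron kernels are :class:`PairKernel` objects and come in two storage
forms:

``dense``
    the explicit 4-index array ``K[a, b, c, d]`` coupling the orbital pair
    ``(a, b)`` with the pair ``(c, d)``.  For the Coulomb tensor this is
    ``(ab|cd)``; for the screened tensor it is ``W_{ab,cd}`` (note the
    pairing: the SEX contraction pairs the *first* index of each bra/ket
    density, see :mod:`rtbse.hamiltonian`).

``ri``
    a resolution-of-identity factorisation ``K[ab, cd] =
    sum_PQ T[a, b, P] M^-1[P, Q] T[c, d, Q]`` with a 3-index factor tensor
    ``T`` (symmetric in its first two indices) and a symmetric
    positive-definite auxiliary metric ``M``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

__all__ = [
    "BundleValidationError",
    "PairKernel",
    "ElectronicSystem",
    "DensityMatrix",
    "EffectiveHamiltonian",
    "FieldSpec",
    "PropagationConfig",
    "Trajectory",
    "validate_system",
    "initial_density",
    "solve_orbitals",
    "save_bundle",
    "load_bundle",
]

BUNDLE_FORMAT_VERSION = 1

SYM_TOL = 1e-12
MO_ORTHO_TOL = 1e-10


class BundleValidationError(ValueError):
    """An electronic-system bundle violates one of its invariants."""


# --------------------------------------------------------------------------
# pair kernels
# --------------------------------------------------------------------------

@dataclass
class PairKernel:
    """Two-electron kernel in dense 4-index or RI-factorised form."""

    form: str  # "dense" or "ri"
    tensor: np.ndarray | None = None          # [n, n, n, n] when dense
    factors: np.ndarray | None = None         # [n, n, n_aux] when ri
    metric: np.ndarray | None = None          # [n_aux, n_aux] SPD when ri

    @classmethod
    def from_dense(cls, tensor: np.ndarray) -> "PairKernel":
        return cls(form="dense", tensor=np.asarray(tensor, dtype=float))

    @classmethod
    def from_ri(cls, factors: np.ndarray, metric: np.ndarray) -> "PairKernel":
        return cls(
            form="ri",
            factors=np.asarray(factors, dtype=float),
            metric=np.asarray(metric, dtype=float),
        )

    @classmethod
    def zero(cls, n: int) -> "PairKernel":
        return cls.from_dense(np.zeros((n, n, n, n)))

    @property
    def n(self) -> int:
        if self.form == "dense":
            return self.tensor.shape[0]
        return self.factors.shape[0]

    @property
    def n_aux(self) -> int | None:
        return self.factors.shape[2] if self.form == "ri" else None

    def dense(self) -> np.ndarray:
        """Explicit 4-index array (reconstructed from the RI factors if needed)."""
        if self.form == "dense":
            return self.tensor
        n, _, naux = self.factors.shape
        t = self.factors.reshape(n * n, naux)
        minv = _spd_inverse(self.metric)
        return (t @ minv @ t.T).reshape(n, n, n, n)

    def pair_matrix(self) -> np.ndarray:
        """Kernel as an [n^2 x n^2] matrix over flattened index pairs."""
        n = self.n
        return self.dense().reshape(n * n, n * n)

    def scaled(self, s: float) -> "PairKernel":
        if self.form == "dense":
            return PairKernel.from_dense(s * self.tensor)
        # scale through the metric: K -> s K  <=>  M -> M / s
        if s == 0.0:
            return PairKernel.zero(self.n)
        return PairKernel.from_ri(self.factors, self.metric / s)


def _spd_inverse(m: np.ndarray) -> np.ndarray:
    c, low = scipy.linalg.cho_factor(m)
    return scipy.linalg.cho_solve((c, low), np.eye(m.shape[0]))


# --------------------------------------------------------------------------
# electronic system
# --------------------------------------------------------------------------

@dataclass
class ElectronicSystem:
    """Static operators and occupations defining the model (atomic units)."""

    n_ao: int
    n_occ: int
    overlap: np.ndarray            # [n, n] real SPD
    h_qp: np.ndarray               # [n, n] real symmetric, Hartree
    dipole: np.ndarray             # [3, n, n] real symmetric, bohr
    coulomb: PairKernel            # (mu nu | sigma lambda)
    screened: PairKernel           # W_{mu lambda, sigma nu}, pairing (12)(34)
    occupations: np.ndarray        # [n_orb] entries in {0, 1}, one spin channel
    mo_coeff: np.ndarray | None = None     # [n, n_orb], C^T S C = 1
    mo_energies: np.ndarray | None = None  # [n_orb], Hartree
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.overlap = np.asarray(self.overlap, dtype=float)
        self.h_qp = np.asarray(self.h_qp, dtype=float)
        self.dipole = np.asarray(self.dipole, dtype=float)
        self.occupations = np.asarray(self.occupations, dtype=float)
        if self.mo_coeff is not None:
            self.mo_coeff = np.asarray(self.mo_coeff, dtype=float)
        if self.mo_energies is not None:
            self.mo_energies = np.asarray(self.mo_energies, dtype=float)

    def dipole_along(self, polarization: np.ndarray) -> np.ndarray:
        """Dipole matrix projected on a polarization direction."""
        eps = np.asarray(polarization, dtype=float)
        return np.einsum("j,jmn->mn", eps, self.dipole)

    def validate(self) -> None:
        validate_system(self)


def _check_sym(name: str, a: np.ndarray, tol: float = SYM_TOL) -> None:
    if np.max(np.abs(a - a.T)) > tol * max(1.0, np.max(np.abs(a))):
        raise BundleValidationError(f"{name} is not symmetric")


def validate_system(sys: ElectronicSystem) -> None:
    """Check every structural invariant; raise naming the first failure."""
    n = sys.n_ao
    if sys.overlap.shape != (n, n):
        raise BundleValidationError("overlap has wrong shape")
    _check_sym("overlap", sys.overlap)
    ev = np.linalg.eigvalsh(0.5 * (sys.overlap + sys.overlap.T))
    if ev.min() <= 0:
        raise BundleValidationError("overlap not positive-definite")
    if sys.h_qp.shape != (n, n):
        raise BundleValidationError("h_qp has wrong shape")
    _check_sym("h_qp", sys.h_qp)
    if sys.dipole.shape != (3, n, n):
        raise BundleValidationError("dipole has wrong shape")
    for j, axis in enumerate("xyz"):
        _check_sym(f"dipole_{axis}", sys.dipole[j])

    for name, kern in (("coulomb", sys.coulomb), ("screened", sys.screened)):
        if kern.n != n:
            raise BundleValidationError(f"{name} has wrong dimension")
        if kern.form == "ri":
            t = kern.factors
            if np.max(np.abs(t - t.transpose(1, 0, 2))) > SYM_TOL * max(
                1.0, np.max(np.abs(t))
            ):
                raise BundleValidationError(
                    f"{name} RI factors not symmetric in orbital pair"
                )
            _check_sym(f"{name} aux metric", kern.metric)
            if np.linalg.eigvalsh(kern.metric).min() <= 0:
                raise BundleValidationError(f"{name} aux metric not positive-definite")
        else:
            v = kern.tensor
            scale = max(1.0, np.max(np.abs(v)))
            # within-pair symmetry (real orbitals)
            if np.max(np.abs(v - v.transpose(1, 0, 2, 3))) > SYM_TOL * scale:
                raise BundleValidationError(f"{name} not symmetric within first pair")
            if np.max(np.abs(v - v.transpose(0, 1, 3, 2))) > SYM_TOL * scale:
                raise BundleValidationError(f"{name} not symmetric within second pair")
            # pair exchange
            if np.max(np.abs(v - v.transpose(2, 3, 0, 1))) > SYM_TOL * scale:
                raise BundleValidationError(f"{name} not symmetric under pair exchange")
        if name == "coulomb" and kern.form == "dense":
            pm = kern.pair_matrix()
            if np.linalg.eigvalsh(0.5 * (pm + pm.T)).min() < -1e-10 * max(
                1.0, np.max(np.abs(pm))
            ):
                raise BundleValidationError(
                    "coulomb not positive semidefinite as a pair kernel"
                )

    occ = sys.occupations
    if not np.all(np.isin(occ, (0.0, 1.0))):
        raise BundleValidationError("occupations must be 0 or 1")
    if int(round(occ.sum())) != sys.n_occ:
        raise BundleValidationError("sum of occupations does not equal n_occ")

    if sys.mo_coeff is not None:
        c = sys.mo_coeff
        g = c.T @ sys.overlap @ c
        if np.max(np.abs(g - np.eye(g.shape[0]))) > MO_ORTHO_TOL:
            raise BundleValidationError("mo_coeff not S-orthonormal")


# --------------------------------------------------------------------------
# state and configuration types
# --------------------------------------------------------------------------

@dataclass
class DensityMatrix:
    """One-particle density matrix rho_{mu nu} in the nonorthogonal basis."""

    rho: np.ndarray  # [n, n] complex Hermitian

    def __post_init__(self):
        self.rho = np.asarray(self.rho, dtype=complex)

    def hermiticity_error(self) -> float:
        return float(np.max(np.abs(self.rho - self.rho.conj().T)))

    def trace_s(self, overlap: np.ndarray) -> float:
        return float(np.real(np.trace(self.rho @ overlap)))

    def idempotency_error(self, overlap: np.ndarray) -> float:
        r = self.rho
        return float(np.max(np.abs(r @ overlap @ r - r)))

    def copy(self) -> "DensityMatrix":
        return DensityMatrix(self.rho.copy())


@dataclass
class EffectiveHamiltonian:
    """The four blocks of the effective one-particle Hamiltonian and their sum."""

    core: np.ndarray           # h_qp
    field: np.ndarray          # U(t) = E(t) * eps . dipole
    hartree_delta: np.ndarray  # V_H[rho - rho0]
    sex_delta: np.ndarray      # Sigma_SEX[rho - rho0]

    @property
    def total(self) -> np.ndarray:
        return self.core + self.field + self.hartree_delta + self.sex_delta


@dataclass
class FieldSpec:
    """Excitation protocol: nothing, an instantaneous kick, or a Gaussian pulse.

    The kick multiplies the equilibrium density by the unitary
    ``exp(-i I S^-1 D_eps)`` and corresponds to the impulsive field
    ``E(t) = I eps delta(t)``.  The pulse is the enveloped carrier
    ``E(t) = E0 cos(w0 t) exp(-(t - t0)^2 / (2 sigma^2))`` applied in length
    gauge.  All values in atomic units.
    """

    kind: str = "none"                       # none | kick | pulse
    polarization: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    kick_strength: float = 0.0               # I, a.u.
    pulse_amplitude: float = 0.0             # E0, a.u. field
    carrier: float = 0.0                     # omega0, Hartree / hbar
    center: float = 0.0                      # t0, a.u. time
    width: float = 1.0                       # sigma, a.u. time

    def __post_init__(self):
        self.polarization = np.asarray(self.polarization, dtype=float)
        if self.kind not in ("none", "kick", "pulse"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        if self.kind != "none":
            nrm = np.linalg.norm(self.polarization)
            if abs(nrm - 1.0) > 1e-12:
                if nrm == 0:
                    raise ValueError("polarization must be a unit vector")
                self.polarization = self.polarization / nrm
        if self.kind == "pulse" and self.width <= 0:
            raise ValueError("pulse width sigma must be positive")

    @classmethod
    def none(cls) -> "FieldSpec":
        return cls(kind="none")

    @classmethod
    def kick(cls, strength: float, polarization=(1.0, 0.0, 0.0)) -> "FieldSpec":
        return cls(kind="kick", kick_strength=strength,
                   polarization=np.asarray(polarization, dtype=float))

    @classmethod
    def pulse(cls, amplitude: float, carrier: float, center: float,
              width: float, polarization=(1.0, 0.0, 0.0)) -> "FieldSpec":
        return cls(kind="pulse", pulse_amplitude=amplitude, carrier=carrier,
                   center=center, width=width,
                   polarization=np.asarray(polarization, dtype=float))


@dataclass
class PropagationConfig:
    """Numerical settings of the enforced-time-reversal-symmetry integrator."""

    dt: float = 0.041341374          # 1 as in a.u. time
    n_steps: int = 20000
    sc_threshold: float = 1e-7       # max-abs density change per SC iteration
    max_sc_iters: int = 50
    exp_method: str = "bch"          # bch | diag
    bch_threshold: float = 1e-14
    diagnostics_every: int = 1

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.sc_threshold <= 0:
            raise ValueError("sc_threshold must be positive")
        if self.exp_method not in ("bch", "diag"):
            raise ValueError(f"unknown exp_method {self.exp_method!r}")


@dataclass
class Trajectory:
    """Propagation record: time grid, dipole series, field trace, diagnostics."""

    times: np.ndarray                # [n_samples], a.u.
    dipole: np.ndarray               # [3, n_samples], a.u. (electronic, spin-summed)
    field_trace: np.ndarray          # [n_samples], applied E(t), a.u.
    diagnostics: dict                # trace_s, idempotency, energy, sc_iters

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def induced_dipole(self) -> np.ndarray:
        """Dipole series relative to the initial (equilibrium) value."""
        return self.dipole - self.dipole[:, :1]

    def to_table(self) -> np.ndarray:
        from .units import au_to_fs

        cols = [au_to_fs(self.times)] + list(self.dipole) + [self.field_trace]
        for key in ("trace_s", "idempotency", "energy"):
            if key in self.diagnostics:
                cols.append(self.diagnostics[key])
        return np.column_stack(cols)

    def save(self, path, header_extra: str = "") -> None:
        header = (
            "rtbse trajectory\n"
            "columns: time_fs mu_x mu_y mu_z field_au trace_s idempotency energy_ha\n"
            + header_extra
        )
        np.savetxt(path, self.to_table(), header=header)


# --------------------------------------------------------------------------
# initial density
# --------------------------------------------------------------------------

DEGENERACY_TOL = 1e-10


def solve_orbitals(sys: ElectronicSystem) -> tuple[np.ndarray, np.ndarray]:
    """Orbital energies and S-orthonormal coefficients.

    Returns the stored quasiparticle orbitals when present; otherwise solves
    the generalized symmetric eigenproblem ``h_qp c = e S c`` with eigenvalues
    ascending.
    """
    if sys.mo_coeff is not None and sys.mo_energies is not None:
        return sys.mo_energies, sys.mo_coeff
    e, c = scipy.linalg.eigh(sys.h_qp, sys.overlap)
    return e, c


def initial_density(sys: ElectronicSystem) -> DensityMatrix:
    """Equilibrium density rho(0) = sum_n f_n c_n c_n^T for one spin channel.

    Refuses to build rho(0) when the occupation edge is degenerate (any
    occupied/empty orbital pair closer than ``DEGENERACY_TOL`` Hartree), since
    the state would be ill-defined.
    """
    e, c = solve_orbitals(sys)
    occ = sys.occupations
    if len(occ) > c.shape[1]:
        raise BundleValidationError("more occupations than orbitals")
    if int(round(occ.sum())) != sys.n_occ:
        raise BundleValidationError("sum of occupations does not equal n_occ")
    occ_idx = np.flatnonzero(occ[: c.shape[1]] == 1.0)
    emp_idx = np.flatnonzero(occ[: c.shape[1]] == 0.0)
    if occ_idx.size and emp_idx.size:
        gap = np.min(np.abs(e[emp_idx][:, None] - e[occ_idx][None, :]))
        if gap < DEGENERACY_TOL:
            raise BundleValidationError(
                "degenerate orbitals at the occupation edge; rho(0) ill-defined"
            )
    c_occ = c[:, occ_idx]
    rho = (c_occ @ c_occ.T).astype(complex)
    return DensityMatrix(rho)


# --------------------------------------------------------------------------
# bundle container I/O
# --------------------------------------------------------------------------

def save_bundle(sys: ElectronicSystem, path) -> None:
    """Write a validated bundle as a single NumPy archive (.npz).

    Keys: overlap, h_qp, dipole_x/y/z, coulomb | coulomb_ri + aux_metric,
    screened | screened_ri + screened_aux_metric, occupations, optionally
    mo_coeff and mo_energies, and a JSON metadata record under "meta".
    """
    validate_system(sys)
    arrays = {
        "overlap": sys.overlap,
        "h_qp": sys.h_qp,
        "dipole_x": sys.dipole[0],
        "dipole_y": sys.dipole[1],
        "dipole_z": sys.dipole[2],
        "occupations": sys.occupations,
    }
    if sys.coulomb.form == "dense":
        arrays["coulomb"] = sys.coulomb.tensor
    else:
        arrays["coulomb_ri"] = sys.coulomb.factors
        arrays["aux_metric"] = sys.coulomb.metric
    if sys.screened.form == "dense":
        arrays["screened"] = sys.screened.tensor
    else:
        arrays["screened_ri"] = sys.screened.factors
        arrays["screened_aux_metric"] = sys.screened.metric
    if sys.mo_coeff is not None:
        arrays["mo_coeff"] = sys.mo_coeff
    if sys.mo_energies is not None:
        arrays["mo_energies"] = sys.mo_energies
    meta = dict(sys.meta)
    meta.update(
        format_version=BUNDLE_FORMAT_VERSION,
        n_ao=int(sys.n_ao),
        n_occ=int(sys.n_occ),
        coulomb_form=sys.coulomb.form,
        screened_form=sys.screened.form,
    )
    arrays["meta"] = np.array(json.dumps(meta))
    np.savez(path, **arrays)


def load_bundle(path) -> ElectronicSystem:
    """Read and validate a bundle archive written by :func:`save_bundle`."""
    with np.load(path, allow_pickle=False) as data:
        keys = set(data.files)
        if "meta" not in keys:
            raise BundleValidationError("bundle missing 'meta' record")
        meta = json.loads(str(data["meta"]))
        required = {"overlap", "h_qp", "dipole_x", "dipole_y", "dipole_z",
                    "occupations"}
        missing = required - keys
        if missing:
            raise BundleValidationError(f"bundle missing keys: {sorted(missing)}")

        if meta.get("coulomb_form") == "ri":
            if not {"coulomb_ri", "aux_metric"} <= keys:
                raise BundleValidationError("bundle missing RI coulomb arrays")
            coulomb = PairKernel.from_ri(data["coulomb_ri"], data["aux_metric"])
        else:
            if "coulomb" not in keys:
                raise BundleValidationError("bundle missing key 'coulomb'")
            coulomb = PairKernel.from_dense(data["coulomb"])
        if meta.get("screened_form") == "ri":
            if not {"screened_ri", "screened_aux_metric"} <= keys:
                raise BundleValidationError("bundle missing RI screened arrays")
            screened = PairKernel.from_ri(
                data["screened_ri"], data["screened_aux_metric"]
            )
        else:
            if "screened" not in keys:
                raise BundleValidationError("bundle missing key 'screened'")
            screened = PairKernel.from_dense(data["screened"])

        sys = ElectronicSystem(
            n_ao=int(meta["n_ao"]),
            n_occ=int(meta["n_occ"]),
            overlap=data["overlap"],
            h_qp=data["h_qp"],
            dipole=np.stack([data["dipole_x"], data["dipole_y"], data["dipole_z"]]),
            coulomb=coulomb,
            screened=screened,
            occupations=data["occupations"],
            mo_coeff=data["mo_coeff"] if "mo_coeff" in keys else None,
            mo_energies=data["mo_energies"] if "mo_energies" in keys else None,
            meta=meta,
        )
    validate_system(sys)
    return sys
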