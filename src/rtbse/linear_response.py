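"""Linear-response BSE (Casida-type) solver in the bundle's orbital space.

Serves as the frequency-domain cross-check for the real-time propagation:
both contain the same physics to first order in the field, so weak-kick
real-time peak positions must coincide with the excitation energies Omega_n
computed here.

Singlet response blocks over occupied-virtual pairs (i a), (j b):

    A_{ia,jb} = (e_a - e_i) delta_ij delta_ab + 2 (ia|jb) - W_{ij,ab}
    B_{ia,jb} = 2 (ia|bj) - W_{ib,aj}

with the factor 2 on the bare-exchange terms from the closed-shell spin
convention and the statically screened electron-hole attraction W.  The full
problem is reduced to the symmetric half-size eigenproblem

    (A-B)^(1/2) (A+B) (A-B)^(1/2)  Z = Omega^2 Z,

and transition dipoles follow from the response-normalized amplitudes
X + Y = Omega^(-1/2) (A-B)^(1/2) Z as <n|r_j|0> = sqrt(2) (X+Y)^T d_j.
The Tamm-Dancoff approximation (diagonalize A alone) is kept as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .system import ElectronicSystem, solve_orbitals
from .spectra import PeakFit
from .units import HARTREE_EV

__all__ = [
    "LRResult",
    "MOBlocks",
    "mo_transform",
    "solve_lr",
    "lr_polarizability",
    "compare_peaks",
    "PeakComparison",
]


@dataclass
class LRResult:
    """Excitation energies (Hartree) and transition dipoles (bohr)."""

    energies: np.ndarray            # [n_exc], ascending
    transition_dipoles: np.ndarray  # [n_exc, 3], <Psi_n| r_j |Psi_0>
    flavor: str = "full"            # full | tda
    broadening: float = 0.0         # eta, Hartree (set by lr_polarizability)

    def oscillator_weights(self) -> np.ndarray:
        """Per-state dipole strength sum_j |d_nj|^2."""
        return np.sum(self.transition_dipoles**2, axis=1)

    def peak_list(self, min_rel_intensity: float = 0.0) -> list[PeakFit]:
        """Excitations as a peak list (position eV, intensity ~ height of the
        absorption peak at fixed broadening, i.e. the dipole strength)."""
        w = self.oscillator_weights()
        if w.size == 0:
            return []
        wmax = w.max() if w.max() > 0 else 1.0
        peaks = [
            PeakFit(position=float(e * HARTREE_EV), width=0.0,
                    amplitude=float(wi), relative_intensity=float(wi / wmax))
            for e, wi in zip(self.energies, w)
        ]
        return [p for p in peaks if p.relative_intensity >= min_rel_intensity]


@dataclass
class MOBlocks:
    """Occupied-virtual integral blocks entering the response matrices."""

    eps_occ: np.ndarray      # [no]
    eps_virt: np.ndarray     # [nv]
    v_ovov: np.ndarray       # (ia|jb), [no, nv, no, nv]
    w_oovv: np.ndarray       # W_{ij,ab}, [no, no, nv, nv]
    w_ovvo: np.ndarray       # W_{ib,aj} indexed [i, b, a, j]
    dip_ov: np.ndarray       # [3, no, nv], <i| r_j |a>


def _transform4(t4: np.ndarray, c1, c2, c3, c4) -> np.ndarray:
    out = np.einsum("abcd,ap->pbcd", t4, c1, optimize=True)
    out = np.einsum("pbcd,bq->pqcd", out, c2, optimize=True)
    out = np.einsum("pqcd,cr->pqrd", out, c3, optimize=True)
    return np.einsum("pqrd,ds->pqrs", out, c4, optimize=True)


def mo_transform(system: ElectronicSystem) -> MOBlocks:
    """Transform V, W and the dipoles to the occupied-virtual orbital basis."""
    e, c = solve_orbitals(system)
    occ = system.occupations[: c.shape[1]] == 1.0
    c_o, c_v = c[:, occ], c[:, ~occ]
    if c_o.shape[1] == 0 or c_v.shape[1] == 0:
        raise ValueError("need at least one occupied and one virtual orbital")
    e_o, e_v = e[occ], e[~occ]

    v = system.coulomb
    w = system.screened
    if v.form == "ri":
        t = v.factors
        minv = np.linalg.inv(v.metric)
        t_ov = np.einsum("mnp,mi,na->iap", t, c_o, c_v, optimize=True)
        no, nv, naux = t_ov.shape
        tm = t_ov.reshape(no * nv, naux)
        v_ovov = (tm @ minv @ tm.T).reshape(no, nv, no, nv)
    else:
        v_ovov = _transform4(v.tensor, c_o, c_v, c_o, c_v)
    if w.form == "ri":
        u = w.factors
        minv_w = np.linalg.inv(w.metric)
        u_oo = np.einsum("mnp,mi,nj->ijp", u, c_o, c_o, optimize=True)
        u_vv = np.einsum("mnp,ma,nb->abp", u, c_v, c_v, optimize=True)
        u_ov = np.einsum("mnp,mi,na->iap", u, c_o, c_v, optimize=True)
        no = u_oo.shape[0]
        nv = u_vv.shape[0]
        w_oovv = np.einsum("ijp,pq,abq->ijab", u_oo, minv_w, u_vv, optimize=True)
        # W_{ib,aj}: first pair (i b), second pair (a j) -> (ov) x (ov) blocks
        w_ovvo = np.einsum("ibp,pq,jaq->ibaj", u_ov, minv_w, u_ov, optimize=True)
    else:
        wt = w.tensor
        w_oovv = _transform4(wt, c_o, c_o, c_v, c_v)
        w_ovvo = _transform4(wt, c_o, c_v, c_v, c_o)

    dip_ov = np.einsum("jmn,mi,na->jia", system.dipole, c_o, c_v, optimize=True)
    return MOBlocks(eps_occ=e_o, eps_virt=e_v, v_ovov=v_ovov,
                    w_oovv=w_oovv, w_ovvo=w_ovvo, dip_ov=dip_ov)


def response_matrices(system: ElectronicSystem) -> tuple[np.ndarray, np.ndarray, MOBlocks]:
    """Dense singlet A and B over flattened (ia) pairs."""
    blocks = mo_transform(system)
    no, nv = blocks.eps_occ.size, blocks.eps_virt.size
    nov = no * nv
    delta = (blocks.eps_virt[None, :] - blocks.eps_occ[:, None]).ravel()
    v = blocks.v_ovov.reshape(nov, nov)
    # W_{ij,ab} -> rows (ia), cols (jb)
    w_a = blocks.w_oovv.transpose(0, 2, 1, 3).reshape(nov, nov)
    # W_{ib,aj} indexed [i,b,a,j] -> rows (ia), cols (jb)
    w_b = blocks.w_ovvo.transpose(0, 2, 3, 1).reshape(nov, nov)
    a = np.diag(delta) + 2.0 * v - w_a
    b = 2.0 * v - w_b
    return a, b, blocks


def solve_lr(system: ElectronicSystem, flavor: str = "full") -> LRResult:
    """Excitation energies and transition dipoles of the linear-response BSE.

    ``flavor="full"`` solves the coupled resonant/antiresonant problem via
    the positive-definite (A-B)^(1/2)(A+B)(A-B)^(1/2) reduction;
    ``flavor="tda"`` diagonalizes A alone.
    """
    if flavor not in ("full", "tda"):
        raise ValueError(f"unknown LR flavor {flavor!r}")
    a, b, blocks = response_matrices(system)
    d_ov = blocks.dip_ov.reshape(3, -1)  # [3, nov]

    if flavor == "tda":
        omega, x = np.linalg.eigh(a)
        order = np.argsort(omega)
        omega, x = omega[order], x[:, order]
        dips = np.sqrt(2.0) * (d_ov @ x).T
        return LRResult(energies=omega, transition_dipoles=dips, flavor="tda")

    amb = a - b
    ev_amb, vec_amb = np.linalg.eigh(amb)
    if ev_amb.min() <= 0:
        raise ValueError(
            "response instability: A - B is not positive-definite "
            f"(lowest eigenvalue {ev_amb.min():.3e})"
        )
    amb_half = (vec_amb * np.sqrt(ev_amb)) @ vec_amb.T
    m = amb_half @ (a + b) @ amb_half
    om2, z = np.linalg.eigh(0.5 * (m + m.T))
    if om2.min() <= 0:
        raise ValueError(
            "response instability: (A-B)^(1/2)(A+B)(A-B)^(1/2) has a "
            f"nonpositive eigenvalue {om2.min():.3e}"
        )
    omega = np.sqrt(om2)
    order = np.argsort(omega)
    omega, z = omega[order], z[:, order]
    # response-normalized X + Y
    xpy = amb_half @ z / np.sqrt(omega)[None, :]
    dips = np.sqrt(2.0) * (d_ov @ xpy).T
    return LRResult(energies=omega, transition_dipoles=dips, flavor="full")


def lr_polarizability(
    lr: LRResult,
    omega_ev: np.ndarray,
    eta_ev: float,
) -> np.ndarray:
    """Isotropic polarizability from the sum-over-states expression.

    alpha_iso(w) = (1/3) sum_{n,j} 2 Omega_n |d_nj|^2 / (Omega_n^2 - (w + i eta)^2)
    """
    if eta_ev <= 0:
        raise ValueError("broadening eta must be positive")
    w = np.asarray(omega_ev, dtype=float) / HARTREE_EV
    eta = eta_ev / HARTREE_EV
    z2 = (w + 1j * eta) ** 2
    strengths = lr.oscillator_weights()
    out = np.zeros(w.shape, dtype=complex)
    for om, s in zip(lr.energies, strengths):
        out += 2.0 * om * s / (om**2 - z2)
    lr.broadening = eta
    return out / 3.0


@dataclass
class PeakComparison:
    """Matched real-time vs linear-response peaks and their deviations."""

    pairs: list                  # (rt_peak, lr_peak, abs deviation eV)
    unmatched_rt: list
    unmatched_lr: list
    mad: float                   # mean absolute deviation, eV, all matches
    mad_bright: float            # restricted to rel. intensity > 50%

    @property
    def n_matched(self) -> int:
        return len(self.pairs)


def compare_peaks(
    rt_peaks: list[PeakFit],
    lr_peaks: list[PeakFit],
    matching_tolerance: float = 0.3,
    bright_threshold: float = 0.5,
) -> PeakComparison:
    """Greedy nearest-position matching of two peak lists (positions in eV).

    Pairs are formed closest-first within ``matching_tolerance``; reports the
    per-pair |Delta|, the overall mean absolute deviation, and the deviation
    restricted to peaks whose relative intensity exceeds 50% in either list.
    """
    if not rt_peaks or not lr_peaks:
        raise ValueError("both peak lists must be nonempty")
    cand = [
        (abs(r.position - l.position), i, j)
        for i, r in enumerate(rt_peaks)
        for j, l in enumerate(lr_peaks)
        if abs(r.position - l.position) <= matching_tolerance
    ]
    cand.sort()
    used_r, used_l = set(), set()
    pairs = []
    for d, i, j in cand:
        if i in used_r or j in used_l:
            continue
        used_r.add(i)
        used_l.add(j)
        pairs.append((rt_peaks[i], lr_peaks[j], d))
    devs = [d for _, _, d in pairs]
    bright = [
        d for r, l, d in pairs
        if r.relative_intensity > bright_threshold
        and l.relative_intensity > bright_threshold
    ]
    return PeakComparison(
        pairs=pairs,
        unmatched_rt=[p for i, p in enumerate(rt_peaks) if i not in used_r],
        unmatched_lr=[p for j, p in enumerate(lr_peaks) if j not in used_l],
        mad=float(np.mean(devs)) if devs else np.nan,
        mad_bright=float(np.mean(bright)) if bright else np.nan,
    )
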