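"""Synthetic electronic-system bundles.

Every downstream stage of the toolkit (Hamiltonian assembly, propagation,
spectra, linear response) is exercised on bundles built here, so no external
quantum-chemistry data is ever required.  Three families are provided:

* a two-level model with an analytically known excitation, for closed-form
  oracles;
* a few-level model without inversion symmetry whose lowest bright excitation
  is *tuned by construction* (bisection against the linear-response solver)
  to a requested energy - the stand-in for a noncentrosymmetric molecule in
  second-harmonic-generation experiments;
* seeded random bundles with a nonorthogonal overlap, RI-factorized Coulomb
  and screened tensors that satisfy all validity invariants by construction.

The screened interaction W of a random bundle is an arbitrary
SPD-metric tensor; :func:`make_rpa_screened` optionally replaces it with the
static random-phase-approximation screening computed in the bundle's own
auxiliary space, which obeys the physical inequality W <= V.
"""

from __future__ import annotations

import numpy as np

from .system import ElectronicSystem, PairKernel, validate_system
from .units import HARTREE_EV

__all__ = [
    "make_two_level",
    "make_noncentrosymmetric_model",
    "make_random_bundle",
    "make_rpa_screened",
]


# --------------------------------------------------------------------------
# two-level model
# --------------------------------------------------------------------------

def make_two_level(
    gap: float,
    dipole_strength: float = 1.0,
    interaction: str | float = "none",
    coupling_scale: float = 0.3,
) -> ElectronicSystem:
    """Two-level, one-electron-pair model in an orthonormal basis.

    Parameters
    ----------
    gap:
        Orbital energy difference in eV.  With ``interaction="none"`` this is
        exactly the excitation energy.
    dipole_strength:
        Off-diagonal transition dipole in bohr (x direction).
    interaction:
        ``"none"`` for vanishing V and W, ``"bare"`` for W = V, or a float
        s in [0, 1] for W = s V (a crude screening strength).
    coupling_scale:
        Overall magnitude (Hartree^1/2) of the RI factor defining V.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    gap_ha = gap / HARTREE_EV
    h = np.diag([0.0, gap_ha])
    dip = np.zeros((3, 2, 2))
    dip[0] = [[0.0, dipole_strength], [dipole_strength, 0.0]]

    if interaction == "none":
        coulomb = PairKernel.zero(2)
        screened = PairKernel.zero(2)
    else:
        g = coupling_scale * np.array([[0.8, 0.1], [0.1, 0.6]])
        factors = g[:, :, None]
        metric = np.eye(1)
        coulomb = PairKernel.from_ri(factors, metric)
        if interaction == "bare":
            s = 1.0
        else:
            s = float(interaction)
            if not 0.0 <= s <= 1.0:
                raise ValueError("screening scale must lie in [0, 1]")
        screened = coulomb.scaled(s) if s > 0 else PairKernel.zero(2)

    sys = ElectronicSystem(
        n_ao=2,
        n_occ=1,
        overlap=np.eye(2),
        h_qp=h,
        dipole=dip,
        coulomb=coulomb,
        screened=screened,
        occupations=np.array([1.0, 0.0]),
        mo_coeff=np.eye(2),
        mo_energies=np.array([0.0, gap_ha]),
        meta={"model": "two_level", "gap_ev": gap},
    )
    validate_system(sys)
    return sys


# --------------------------------------------------------------------------
# noncentrosymmetric few-level model
# --------------------------------------------------------------------------

_LEVEL_RATIOS = np.array([0.0, 1.0, 1.55, 2.25, 3.0, 3.8, 4.6, 5.4])


def _build_noncentro(
    gap_scale: float, n_levels: int, asymmetry: float, interaction_scale: float
) -> ElectronicSystem:
    n = n_levels
    ratios = _LEVEL_RATIOS[:n] if n <= _LEVEL_RATIOS.size else np.concatenate(
        [_LEVEL_RATIOS, _LEVEL_RATIOS[-1] + 0.8 * np.arange(1, n - _LEVEL_RATIOS.size + 1)]
    )[:n]
    h = np.diag(gap_scale * ratios)

    dip = np.zeros((3, n, n))
    # ladder couplings (parity-odd under the alternating-sign inversion)
    for k in range(n - 1):
        dip[0, k, k + 1] = dip[0, k + 1, k] = 0.8 / (1.0 + 0.3 * k)
    # permanent-dipole differences break inversion symmetry
    diag_pattern = np.array([0.0, 0.8, 0.45, 0.95, 0.6, 1.05, 0.7, 1.1])[:n] if n <= 8 \
        else np.resize([0.0, 0.8, 0.45, 0.95], n)
    dip[0] += asymmetry * np.diag(diag_pattern)

    # weak deterministic interaction in RI form; each auxiliary channel
    # couples orbital pairs of a single parity so the interaction respects
    # the ladder's inversion symmetry (only the dipole diagonal breaks it)
    idx = np.arange(n)
    even_mask = ((idx[:, None] - idx[None, :]) % 2 == 0).astype(float)
    t = np.zeros((n, n, 2))
    t[:, :, 0] = interaction_scale * (np.eye(n) + 0.25 * even_mask)
    ladder = np.zeros((n, n))
    for k in range(n - 1):
        ladder[k, k + 1] = ladder[k + 1, k] = 1.0
    t[:, :, 1] = 0.6 * interaction_scale * ladder
    coulomb = PairKernel.from_ri(t, np.eye(2))
    screened = coulomb.scaled(0.7)

    occ = np.zeros(n)
    occ[0] = 1.0
    sys = ElectronicSystem(
        n_ao=n,
        n_occ=1,
        overlap=np.eye(n),
        h_qp=h,
        dipole=dip,
        coulomb=coulomb,
        screened=screened,
        occupations=occ,
        meta={"model": "noncentro", "gap_scale": gap_scale,
              "asymmetry": asymmetry},
    )
    return sys


def make_noncentrosymmetric_model(
    target_excitation: float,
    n_levels: int = 4,
    asymmetry: float = 0.5,
    interaction_scale: float = 0.12,
    tune_tolerance_ev: float = 1e-3,
    bright_threshold: float = 0.05,
) -> ElectronicSystem:
    """Few-level model without inversion symmetry, tuned to a target excitation.

    The dipole matrix has unequal diagonal elements (permanent dipoles differ
    between states), which removes inversion symmetry and enables even-order
    responses such as second-harmonic generation.  A bisection on the level
    spacing, with the linear-response solver in the loop, places the lowest
    *bright* excitation at ``target_excitation`` (eV) within
    ``tune_tolerance_ev``.
    """
    from .linear_response import solve_lr

    if asymmetry == 0:
        raise ValueError("asymmetry must be nonzero for a noncentrosymmetric model")
    if n_levels < 3:
        raise ValueError("need at least 3 levels")
    if target_excitation <= 0:
        raise ValueError("target excitation must be positive")
    target_ha = target_excitation / HARTREE_EV
    tol_ha = tune_tolerance_ev / HARTREE_EV

    def lowest_bright(gap_scale: float) -> float:
        sys = _build_noncentro(gap_scale, n_levels, asymmetry, interaction_scale)
        lr = solve_lr(sys, flavor="full")
        w = lr.oscillator_weights()
        bright = w >= bright_threshold * w.max()
        return float(lr.energies[bright][0])

    lo, hi = 0.2 * target_ha, 3.0 * target_ha
    f_lo = lowest_bright(lo) - target_ha
    f_hi = lowest_bright(hi) - target_ha
    if f_lo * f_hi > 0:
        raise RuntimeError(
            "tuning failed to bracket the target excitation; adjust the "
            "interaction scale or target"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = lowest_bright(mid) - target_ha
        if abs(f_mid) < tol_ha:
            break
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    else:
        raise RuntimeError("tuning bisection did not converge")

    sys = _build_noncentro(mid, n_levels, asymmetry, interaction_scale)
    sys.meta["target_excitation_ev"] = target_excitation
    validate_system(sys)
    return sys


# --------------------------------------------------------------------------
# seeded random bundles
# --------------------------------------------------------------------------

def make_random_bundle(
    n_ao: int,
    n_occ: int,
    n_aux: int,
    seed: int,
    max_condition: float = 50.0,
    coupling_scale: float = 0.12,
) -> ElectronicSystem:
    """Reproducible random bundle with a nonorthogonal basis and RI tensors.

    Orbital energies are drawn so that occupied-virtual gaps fall in the
    few-eV window of a typical small organic molecule; the overlap eigenvalue
    spread is capped at ``max_condition``; Coulomb and screened kernels are
    assembled from random symmetric 3-index factors with SPD auxiliary
    metrics, which guarantees the pair-kernel symmetries and positive
    semidefiniteness by construction.
    """
    if n_occ >= n_ao:
        raise ValueError("need n_occ < n_ao")
    rng = np.random.default_rng(seed)
    n = n_ao

    q, _ = np.linalg.qr(rng.normal(size=(n, n)))
    lam = np.exp(np.linspace(0.0, np.log(max_condition), n))
    lam = lam / np.sqrt(lam[0] * lam[-1])   # spread the condition around 1
    s = (q * lam) @ q.T
    ev, vec = np.linalg.eigh(s)
    s_inv_half = (vec / np.sqrt(ev)) @ vec.T

    e_occ = np.sort(rng.uniform(-0.45, -0.25, size=n_occ))
    e_virt = np.sort(rng.uniform(-0.05, 0.20, size=n - n_occ))
    energies = np.concatenate([e_occ, e_virt])
    q2, _ = np.linalg.qr(rng.normal(size=(n, n)))
    c = s_inv_half @ q2
    h = s @ c @ np.diag(energies) @ c.T @ s
    h = 0.5 * (h + h.T)

    dip = rng.normal(scale=0.5, size=(3, n, n))
    dip = 0.5 * (dip + dip.transpose(0, 2, 1))

    def random_kernel(scale: float) -> PairKernel:
        t = rng.normal(scale=scale, size=(n, n, n_aux))
        t = 0.5 * (t + t.transpose(1, 0, 2))
        g = rng.normal(size=(n_aux, n_aux))
        metric = g @ g.T / n_aux + np.eye(n_aux)
        return PairKernel.from_ri(t, metric)

    coulomb = random_kernel(coupling_scale)
    screened = random_kernel(0.8 * coupling_scale)

    occ = np.zeros(n)
    occ[:n_occ] = 1.0
    sys = ElectronicSystem(
        n_ao=n,
        n_occ=n_occ,
        overlap=s,
        h_qp=h,
        dipole=dip,
        coulomb=coulomb,
        screened=screened,
        occupations=occ,
        mo_coeff=c,
        mo_energies=energies,
        meta={"model": "random", "seed": int(seed), "n_aux": int(n_aux)},
    )
    validate_system(sys)
    return sys


# --------------------------------------------------------------------------
# static RPA screening
# --------------------------------------------------------------------------

def make_rpa_screened(system: ElectronicSystem) -> ElectronicSystem:
    """Replace W by the static random-phase-approximation screened interaction.

    Working entirely in the auxiliary space of the RI Coulomb tensor: the
    3-index integrals are transformed to occupied-virtual pairs, the static
    density response enters as

        X_PQ = -4 sum_ia B_iaP B_iaQ / (eps_a - eps_i)

    (spin factor 2 times resonant+antiresonant factor 2), and solving the
    Dyson equation for W in this space amounts to replacing the auxiliary
    metric M by M - X.  Since X is negative semidefinite, M - X stays SPD and
    W <= V as pair-space kernels.
    """
    if system.coulomb.form != "ri":
        raise ValueError("RPA screening requires an RI-form Coulomb tensor")
    from .system import solve_orbitals

    e, c = solve_orbitals(system)
    occ = system.occupations[: c.shape[1]] == 1.0
    c_o, c_v = c[:, occ], c[:, ~occ]
    e_o, e_v = e[occ], e[~occ]
    if c_o.shape[1] == 0 or c_v.shape[1] == 0:
        raise ValueError("need occupied and virtual orbitals")
    gaps = e_v[None, :] - e_o[:, None]
    if np.min(gaps) < 1e-10:
        raise ValueError("zero HOMO-LUMO gap: static screening is singular")

    t = system.coulomb.factors
    b_ov = np.einsum("mnp,mi,na->iap", t, c_o, c_v, optimize=True)
    weights = 4.0 / gaps                    # spin 2 x (resonant+antiresonant) 2
    x = -np.einsum("iap,ia,iaq->pq", b_ov, weights, b_ov, optimize=True)
    metric_w = system.coulomb.metric - x

    out = ElectronicSystem(
        n_ao=system.n_ao,
        n_occ=system.n_occ,
        overlap=system.overlap,
        h_qp=system.h_qp,
        dipole=system.dipole,
        coulomb=system.coulomb,
        screened=PairKernel.from_ri(t.copy(), metric_w),
        occupations=system.occupations,
        mo_coeff=system.mo_coeff,
        mo_energies=system.mo_energies,
        meta={**system.meta, "screened": "rpa_static"},
    )
    validate_system(out)
    return out
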