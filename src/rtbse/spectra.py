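"""Frequency-domain processing of dipole trajectories.

The pipeline is: window the induced dipole mu(t) - mu(0) (exponential damping
for kick spectra, a Gaussian window for pulse-driven runs), take the one-sided
discrete Fourier transform

    mu(omega) ~ dt * sum_k mu(t_k) exp(+i omega t_k),

refine the coarse transform with a rational (Pade) approximant evaluated on a
fine energy grid, divide by the field spectrum to obtain the polarizability
tensor alpha_jk(omega) = mu_j(omega) / E_k(omega) and its isotropic third of
the trace, fit Lorentzians to the peaks, and fit log-log scaling exponents of
nonlinear features against the field amplitude.

Pade refinement: the fitted variable is zeta = exp(i omega tau) with
tau = pi / omega_max_fit, which maps the (symmetrized) fit range
[-omega_max, +omega_max] onto the full unit circle where the rational
least-squares problem is well conditioned.  The approximant uses N/2
parameters for N fitted samples - half in the numerator, half in the
denominator (constant term fixed to one) - solved by linear least squares
with column scaling; if the system is numerically singular the routine falls
back to interpolation of the raw samples and flags it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.signal

from .units import AU_TIME_PER_FS, HARTREE_EV
from .system import FieldSpec, Trajectory

__all__ = [
    "WindowSpec",
    "SpectrumConfig",
    "Spectrum",
    "PeakFit",
    "ScalingFit",
    "apply_window",
    "fourier_dipole",
    "pade_refine",
    "field_spectrum",
    "polarizability",
    "alpha_iso_from_kicks",
    "fit_peaks",
    "scaling_analysis",
]


# --------------------------------------------------------------------------
# configuration and result types
# --------------------------------------------------------------------------

@dataclass
class WindowSpec:
    """Time-domain window: exponential damping or a Gaussian gate (fs units)."""

    kind: str = "exponential"   # exponential | gaussian | none
    gamma_fs: float = 0.2       # damping rate, 1/fs
    center_fs: float = 0.0      # Gaussian center
    spread_fs: float = 4.0      # Gaussian standard deviation

    def __post_init__(self):
        if self.kind not in ("exponential", "gaussian", "none"):
            raise ValueError(f"unknown window kind {self.kind!r}")
        if self.kind == "gaussian" and self.spread_fs <= 0:
            raise ValueError("gaussian window spread must be positive")

    def values(self, times_au: np.ndarray) -> np.ndarray:
        t_fs = times_au / AU_TIME_PER_FS
        if self.kind == "exponential":
            return np.exp(-self.gamma_fs * t_fs)
        if self.kind == "gaussian":
            return np.exp(-((t_fs - self.center_fs) ** 2) / (2 * self.spread_fs**2))
        return np.ones_like(t_fs)


@dataclass
class SpectrumConfig:
    """Grid, window and refinement settings for spectrum extraction (eV/fs)."""

    window: WindowSpec = field(default_factory=WindowSpec)
    pade_enabled: bool = True
    pade_fit_max_energy: float = 200.0   # eV; samples up to here enter the fit
    grid_min: float = 0.0                # eV
    grid_max: float = 20.0               # eV
    grid_step: float = 0.02              # eV
    n_pade_params: int | None = None     # default: N/2 for N fitted samples

    def __post_init__(self):
        if self.grid_step <= 0:
            raise ValueError("grid step must be positive")
        if self.pade_fit_max_energy < self.grid_max:
            raise ValueError("Pade fit range must contain the output grid")

    def grid_ev(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step)) + 1
        return self.grid_min + self.grid_step * np.arange(n)


@dataclass
class Spectrum:
    """Frequency-domain observables on an energy grid (eV)."""

    omega_ev: np.ndarray
    mu_omega: np.ndarray | None = None    # [M, 3] complex
    alpha: np.ndarray | None = None       # [M, 3, 3] complex
    alpha_iso: np.ndarray | None = None   # [M] complex
    metadata: dict = field(default_factory=dict)

    def finalize_iso(self) -> None:
        """Set alpha_iso to exactly the mean of the diagonal alpha entries."""
        if self.alpha is not None:
            self.alpha_iso = np.einsum("mjj->m", self.alpha) / 3.0

    def save(self, path, header_extra: str = "") -> None:
        cols = [self.omega_ev]
        names = ["energy_ev"]
        if self.mu_omega is not None:
            for j, ax in enumerate("xyz"):
                cols += [self.mu_omega[:, j].real, self.mu_omega[:, j].imag]
                names += [f"re_mu_{ax}", f"im_mu_{ax}"]
        if self.alpha_iso is not None:
            cols += [self.alpha_iso.real, self.alpha_iso.imag]
            names += ["re_alpha_iso", "im_alpha_iso"]
        header = "rtbse spectrum\ncolumns: " + " ".join(names) + "\n" + header_extra
        np.savetxt(path, np.column_stack(cols), header=header)


@dataclass
class PeakFit:
    """A Lorentzian fitted to a local maximum of a real-valued spectrum."""

    position: float            # eV
    width: float               # eV, half width at half maximum
    amplitude: float           # spectrum units
    relative_intensity: float  # fraction of the tallest fitted peak


@dataclass
class ScalingFit:
    """Log-log power-law exponent of a feature magnitude vs field amplitude."""

    exponent: float
    n_used: int
    excluded: list = field(default_factory=list)


# --------------------------------------------------------------------------
# windowing and Fourier transform
# --------------------------------------------------------------------------

def apply_window(trajectory: Trajectory, config: SpectrumConfig) -> np.ndarray:
    """Window the induced dipole series; returns a [3, n_samples] array."""
    w = config.window.values(trajectory.times)
    return trajectory.induced_dipole() * w[None, :]


def fourier_dipole(series: np.ndarray, dt: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided transform ``dt * sum_k f_k exp(+i omega t_k)`` on the FFT grid.

    ``series`` is real with time on the last axis; returns angular frequencies
    (a.u.) and complex samples with the same leading shape.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=dt)
    # +i omega t convention: conjugate of the standard rfft of a real signal
    samples = dt * np.conj(np.fft.rfft(series, axis=-1))
    return omega, samples


# --------------------------------------------------------------------------
# Pade refinement
# --------------------------------------------------------------------------

def pade_refine(
    omega_au: np.ndarray,
    samples: np.ndarray,
    config: SpectrumConfig,
    omega_out_au: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Rational-approximant refinement of coarse spectrum samples.

    Fits numerator and denominator polynomials in zeta = exp(i omega tau) to
    the complex ``samples`` (one spectrum; 1-D), using the samples with
    ``omega`` inside the fit range together with their reflection
    ``f(-omega) = f(omega)*`` implied by a real time signal.  Returns
    ``(omega_out, values, info)`` where ``info['fallback']`` marks a singular
    fit that was replaced by plain interpolation.
    """
    omega_au = np.asarray(omega_au, dtype=float)
    samples = np.asarray(samples, dtype=complex)
    wmax = config.pade_fit_max_energy / HARTREE_EV
    sel = omega_au <= wmax
    w_fit = omega_au[sel]
    f_fit = samples[sel]
    n_fit = w_fit.size
    if omega_out_au is None:
        omega_out_au = config.grid_ev() / HARTREE_EV
    if n_fit < 4:
        raise ValueError("need at least 4 samples in the Pade fit range")

    n_par = config.n_pade_params if config.n_pade_params is not None else n_fit // 2
    n_par = max(n_par, 2)
    p = (n_par + 1) // 2          # numerator coefficients a_0..a_{p-1}
    q = n_par - p                 # denominator coefficients b_1..b_q

    # reflect to negative frequencies (reality of the time signal)
    w_all = np.concatenate([-w_fit[:0:-1], w_fit])
    f_all = np.concatenate([np.conj(f_fit[:0:-1]), f_fit])

    tau = np.pi / wmax
    zeta = np.exp(1j * tau * w_all)

    # linearized rational fit: sum_j a_j zeta^j - f * sum_{j>=1} b_j zeta^j = f
    cols = [zeta**j for j in range(p)] + [-f_all * zeta**j for j in range(1, q + 1)]
    a_mat = np.column_stack(cols)
    scale = np.linalg.norm(a_mat, axis=0)
    scale[scale == 0] = 1.0
    info = {"fallback": False, "n_fit": n_fit, "n_params": p + q}
    try:
        sol, _, rank, _ = np.linalg.lstsq(a_mat / scale, f_all, rcond=None)
        sol = sol / scale
        singular = not np.all(np.isfinite(sol))
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        warnings.warn("Pade fit numerically singular; falling back to "
                      "raw-grid interpolation", RuntimeWarning)
        info["fallback"] = True
        vals = np.interp(omega_out_au, w_fit, f_fit.real) + 1j * np.interp(
            omega_out_au, w_fit, f_fit.imag
        )
        return omega_out_au, vals, info

    a_coef = sol[:p]
    b_coef = np.concatenate([[1.0], sol[p:]])
    zo = np.exp(1j * tau * omega_out_au)
    num = np.polyval(a_coef[::-1], zo)
    den = np.polyval(b_coef[::-1], zo)
    small = np.abs(den) < 1e-300
    den[small] = 1e-300
    return omega_out_au, num / den, info


def refine_or_interpolate(omega_au, samples, config: SpectrumConfig):
    """Pade-refine onto the output grid, or interpolate if refinement is off."""
    grid_au = config.grid_ev() / HARTREE_EV
    if config.pade_enabled:
        return pade_refine(omega_au, samples, config, grid_au)
    vals = np.interp(grid_au, omega_au, samples.real) + 1j * np.interp(
        grid_au, omega_au, samples.imag
    )
    return grid_au, vals, {"fallback": False, "refined": False}


# --------------------------------------------------------------------------
# polarizability
# --------------------------------------------------------------------------

FIELD_FLOOR = 1e-12


def field_spectrum(omega_au: np.ndarray, fieldspec: FieldSpec) -> np.ndarray:
    """Analytic Fourier transform of the applied field amplitude E(t).

    A delta kick has the flat spectrum I; the Gaussian-enveloped carrier has
    the closed-form two-branch Gaussian transform (the envelope is assumed to
    be negligible at t < 0, which holds for t0 a few sigma after the start).
    """
    omega_au = np.asarray(omega_au, dtype=float)
    if fieldspec.kind == "kick":
        return np.full(omega_au.shape, fieldspec.kick_strength, dtype=complex)
    if fieldspec.kind == "pulse":
        e0, w0 = fieldspec.pulse_amplitude, fieldspec.carrier
        t0, sig = fieldspec.center, fieldspec.width
        pref = 0.5 * e0 * np.sqrt(2.0 * np.pi) * sig
        out = np.zeros(omega_au.shape, dtype=complex)
        for s in (+1.0, -1.0):
            w = omega_au + s * w0
            out += pref * np.exp(1j * w * t0 - 0.5 * (sig * w) ** 2)
        return out
    raise ValueError("field kind 'none' has no spectrum")


def polarizability(
    mu_omega: np.ndarray,
    e_omega: np.ndarray,
) -> np.ndarray:
    """alpha_j(omega) = mu_j(omega) / E(omega), masked where the field vanishes."""
    mu_omega = np.asarray(mu_omega, dtype=complex)
    e_omega = np.asarray(e_omega, dtype=complex)
    mask = np.abs(e_omega) < FIELD_FLOOR
    safe = np.where(mask, 1.0, e_omega)
    out = mu_omega / (safe[:, None] if mu_omega.ndim == 2 else safe)
    if mu_omega.ndim == 2:
        out[mask, :] = np.nan
    else:
        out[mask] = np.nan
    return out


def alpha_iso_from_kicks(
    mu_spectra: dict[int, np.ndarray],
    kick_strength: float,
) -> tuple[np.ndarray | None, np.ndarray]:
    """Assemble alpha and its isotropic part from per-direction kick runs.

    ``mu_spectra`` maps the kicked Cartesian direction k to the [M, 3] array
    mu_j(omega).  With all three directions present the full tensor is
    returned; alpha_iso is the mean of the available diagonal entries (the
    caller declares symmetry by supplying fewer directions).
    """
    some = next(iter(mu_spectra.values()))
    m = some.shape[0]
    diag = []
    alpha = None
    if len(mu_spectra) == 3:
        alpha = np.empty((m, 3, 3), dtype=complex)
        for k, mu in mu_spectra.items():
            alpha[:, :, k] = mu / kick_strength
        iso = np.einsum("mjj->m", alpha) / 3.0
        return alpha, iso
    for k, mu in mu_spectra.items():
        diag.append(mu[:, k] / kick_strength)
    return alpha, np.mean(diag, axis=0)


# --------------------------------------------------------------------------
# peak fitting
# --------------------------------------------------------------------------

def _lorentzian(x, amp, x0, hwhm):
    return amp * hwhm**2 / ((x - x0) ** 2 + hwhm**2)


def fit_peaks(
    omega_ev: np.ndarray,
    y: np.ndarray,
    min_rel_intensity: float = 0.01,
    fit_halfwidth_ev: float = 0.5,
) -> list[PeakFit]:
    """Locate local maxima above threshold and fit each with a Lorentzian.

    The fit window extends +/- ``fit_halfwidth_ev`` around each maximum but is
    truncated at the neighboring local minima and at the contiguous region
    above 40% of the peak height, so overlapping peaks do not contaminate each
    other.  Returns peaks sorted by position with intensities relative to the
    tallest.
    """
    omega_ev = np.asarray(omega_ev, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size == 0 or not np.any(np.isfinite(y)):
        return []
    ymax = np.nanmax(y)
    if ymax <= 0:
        return []
    idx, _ = scipy.signal.find_peaks(y, height=min_rel_intensity * ymax)
    if idx.size == 0:
        return []
    minima, _ = scipy.signal.find_peaks(-y)
    step = omega_ev[1] - omega_ev[0] if omega_ev.size > 1 else 1.0
    half_n = max(2, int(round(fit_halfwidth_ev / step)))

    results = []
    for i in idx:
        lo = max(0, i - half_n)
        hi = min(y.size, i + half_n + 1)
        left_min = minima[minima < i]
        right_min = minima[minima > i]
        if left_min.size:
            lo = max(lo, left_min[-1])
        if right_min.size:
            hi = min(hi, right_min[0] + 1)
        # restrict to the contiguous core above 40% of the peak height
        level = 0.4 * y[i]
        j = i
        while j > lo and y[j - 1] >= level:
            j -= 1
        k = i
        while k < hi - 1 and y[k + 1] >= level:
            k += 1
        lo, hi = j, k + 1
        if hi - lo < 4:
            lo = max(0, i - 2)
            hi = min(y.size, i + 3)
        xw, yw = omega_ev[lo:hi], y[lo:hi]
        p0 = (y[i], omega_ev[i], max(2 * step, 0.05))
        try:
            popt, _ = scipy.optimize.curve_fit(
                _lorentzian, xw, yw, p0=p0,
                bounds=([0, xw[0], step * 1e-3], [np.inf, xw[-1], np.inf]),
                maxfev=5000,
            )
            amp, pos, hwhm = popt
        except (RuntimeError, ValueError):
            amp, pos, hwhm = y[i], omega_ev[i], 2 * step
        results.append(PeakFit(position=float(pos), width=float(hwhm),
                               amplitude=float(amp), relative_intensity=1.0))
    amax = max(r.amplitude for r in results)
    for r in results:
        r.relative_intensity = r.amplitude / amax
    results = [r for r in results if r.relative_intensity >= min_rel_intensity]
    return sorted(results, key=lambda r: r.position)


# --------------------------------------------------------------------------
# nonlinear-order scaling
# --------------------------------------------------------------------------

def scaling_analysis(
    field_amplitudes: np.ndarray,
    feature_magnitudes: dict[str, np.ndarray],
) -> dict[str, ScalingFit]:
    """Log-log least-squares exponent of each feature magnitude vs E0.

    A linear optical feature yields exponent 1; second-order features
    (second harmonic, optical rectification) yield exponent 2.  Nonpositive
    magnitudes are excluded from the fit and reported.
    """
    e0 = np.asarray(field_amplitudes, dtype=float)
    if e0.size < 2:
        raise ValueError("need at least two field amplitudes")
    out = {}
    for name, mags in feature_magnitudes.items():
        mags = np.asarray(mags, dtype=float)
        good = mags > 0
        excluded = list(np.flatnonzero(~good))
        if good.sum() < 2:
            out[name] = ScalingFit(exponent=np.nan, n_used=int(good.sum()),
                                   excluded=excluded)
            continue
        slope = np.polyfit(np.log(e0[good]), np.log(mags[good]), 1)[0]
        out[name] = ScalingFit(exponent=float(slope), n_used=int(good.sum()),
                               excluded=excluded)
    return out
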