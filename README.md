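# rtbse

Real-time Bethe–Salpeter (RT-BSE) propagation of the one-particle density
matrix for linear and nonlinear molecular optical response.

## What it does, and for whom

Optical spectra of molecules with excitonic (electron–hole attraction)
effects are usually computed with the linear-response Bethe–Salpeter
equation, which only covers first-order response. This package instead
propagates the one-particle density matrix **ρ**(t) in real time under an
explicit electric field, with the screened-exchange self-energy carrying the
electron–hole physics. Linear absorption comes from the Fourier transform of
the induced dipole after a weak delta kick; second-order effects — second-
harmonic generation (SHG) and optical rectification — emerge naturally from
the same propagation under a finite pulse. It is aimed at method developers
and students of many-body electron dynamics: all inputs are matrices and
tensors in an abstract Gaussian-type basis, produced by the built-in
synthetic generators or exported from any electronic-structure code
(producing such exports is out of scope here).

## The model

All operators are matrices in a nonorthogonal basis with overlap **S**
(atomic units throughout). The equation of motion is the von Neumann
equation

    dρ/dt = -i (S⁻¹ H(t) ρ - ρ H(t) S⁻¹),

with the effective one-particle Hamiltonian

    H(t) = h_qp + U(t) + V_H[ρ(t) - ρ(0)] + Σ_SEX[ρ(t) - ρ(0)],

where `h_qp` carries quasiparticle energies (from a preceding GW-type
calculation — an *input* here), `U(t) = E(t) ε·D` is the length-gauge field
coupling through the dipole matrices **D**, and the mean-field terms are

    V_H[ρ]_{μν}    =  2 Σ_{λσ} (μν|σλ) ρ_{λσ}          (Hartree, bare V)
    Σ_SEX[ρ]_{μν}  = -  Σ_{λσ} W_{μλ,σν} ρ_{λσ}        (screened exchange, static W)

for one spin channel of a closed-shell system. Both kernels may be stored
explicitly (4-index) or RI-factorized (3-index factors + SPD auxiliary
metric). The integrator is the enforced time-reversal-symmetry (ETRS)
scheme — a time-symmetric split exponential step, implicit in H(t+Δt) and
solved by self-consistent iteration — which conserves Hermiticity, electron
number Tr(ρS) and idempotency ρSρ = ρ essentially to machine precision.

Spectra: the induced dipole μ(t) = -2 Tr(ρ(t) D) is windowed (exponential
damping γ for kick spectra, a Gaussian gate for pulse runs), Fourier
transformed, refined with a rational (Padé) approximant on a fine energy
grid, and divided by the field spectrum to give the polarizability
α_jk(ω) = μ_j(ω)/E_k(ω) and its isotropic part α_iso = tr(α)/3. A
linear-response BSE solver (Casida-type, full or Tamm–Dancoff) built on the
same tensors provides the independent cross-check: in the weak-field limit
the real-time peak positions must coincide with its excitation energies Ω_n.

## Worked example

`examples/02_rt_vs_lr_benchmark.py` generates a reproducible interacting
6-orbital bundle, runs three weak delta kicks for 20 fs at 1 as steps, and
matches the Padé-refined spectrum against the linear-response solver:

```
matched peaks (RT vs LR, eV):
   13.4338   13.4339   |dev|   0.16 meV   rel. intensity 0.23
   12.2937   12.2943   |dev|   0.59 meV   rel. intensity 1.00
   16.0457   16.0448   |dev|   0.91 meV   rel. intensity 0.65
   19.2576   19.2589   |dev|   1.33 meV   rel. intensity 0.03
   10.2044   10.2059   |dev|   1.50 meV   rel. intensity 1.00
    7.5846    7.5828   |dev|   1.73 meV   rel. intensity 0.18
mean absolute deviation: 1.04 meV (bright peaks only: 1.00 meV)
```

Each row is one excitation found independently by both routes; the
millielectronvolt-level deviations mean the propagator, the self-energy
contractions and the response kernel are mutually consistent.

`examples/03_shg_and_rectification.py` drives the noncentrosymmetric model
(lowest bright excitation tuned to 6.0 eV) with Gaussian pulses of three
amplitudes and prints

```
feature           position (eV)   log-log exponent vs E0
linear                 5.975      0.9998
second_harmonic       12.029      1.9980
rectification          0.079      1.9998
```

— the linear peak at the drive frequency scaling as E0, and the two
second-order features (at 2ω and near ω = 0) scaling as E0², exactly as
second-order response theory demands; a centrosymmetric counterpart shows
no second harmonic at all (see `tests/test_nonlinear.py`).

The other examples cover the two-level closed-form check and bundle I/O
with static RPA screening. A thin CLI wraps the same pipelines:
`rtbse generate | validate | propagate | spectrum | lr | compare | shg-scan
| run` (see `rtbse --help`).

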