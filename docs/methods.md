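# Methods

This note records the model, the numerical scheme, the defaults and the
design decisions of `rtbse`, in enough detail to reproduce or modify any of
them. Everything is in Hartree atomic units unless stated otherwise
(1 Ha = 27.211386 eV, 1 fs = 41.341374 a.u. of time).

## Model and assumptions

The propagated object is the one-particle density matrix ρ_{μν}(t) of one
spin channel of a closed-shell system, expressed in a nonorthogonal basis
with overlap S. The equation of motion is the von Neumann equation with the
effective Hamiltonian

    H(t) = h_qp + U(t) + V_H[Δρ] + Σ_SEX[Δρ],   Δρ = ρ(t) - ρ(0),

and contains **no phenomenological damping**: all line broadening is applied
at post-processing time as a window function. The screened-exchange
self-energy uses the *static* screened interaction W(ω = 0); W is read once
from the input bundle and never updated during the dynamics (the engine
precomputes read-only contraction operators from it). A Coulomb-hole term
does not appear: with a static W fixed at the quasiparticle level it is a
constant shift that cancels in the Δρ form of the Hamiltonian.

Spin convention: occupations f_n ∈ {0, 1} refer to one channel. The Hartree
contraction carries a factor 2 (the total density of both channels screens)
and the dipole expectation μ = -2 Tr(ρD) is spin-summed; screened exchange
couples same-spin pairs only and carries factor 1. The linear-response
kernel uses the matching singlet convention, A = Δε + 2(ia|jb) - W_{ij,ab},
B = 2(ia|jb) - W_{ib,aj}, with transition dipoles √2 (X+Y)ᵀ d_ov. The
factor assignment is not free: the real-time and linear-response routes
agree to ~1 meV in peak positions only with this pairing, and a unit test
pins the SEX sign and index pairing to the Hartree–Fock-exchange limit
(W = V reproduces minus the exchange matrix of an explicit loop oracle).

Equilibrium: ρ(0) = Σ_n f_n c_n c_nᵀ from stored orbitals, or from solving
h_qp c = ε S c when orbitals are absent. A degenerate occupied/virtual edge
(closer than 1e-10 Ha) is refused rather than broken arbitrarily, since
ρ(0) would be ill-defined.

## Integrator

The ETRS step is

    ρ(t+Δt) = exp(-i S⁻¹H(t+Δt) Δt/2) ρ(t+Δt/2) exp(+i H(t+Δt) S⁻¹ Δt/2),

with ρ(t+Δt/2) obtained the same way using H(t). H(t+Δt) depends on the
unknown ρ(t+Δt); the loop builds a first candidate from the half-step
density and then iterates Hamiltonian rebuild → propagation until the
max-abs change of the density matrix falls below the threshold ϵ
(density-independent Hamiltonians therefore converge at iteration 1 with
residual 0). Non-convergence raises with the last residual; there is no
silent sub-stepping.

The similarity exponentials are computed either by the nested-commutator
(BCH) series, truncated when the current term's max-abs falls below a
threshold (order cap 40, with an error advising a smaller step on
non-convergence), or exactly by diagonalizing S^(-1/2) H S^(-1/2). Both
conserve Hermiticity structurally; conservation of Tr(ρS) and of ρSρ = ρ is
exact up to the series truncation. S⁻¹ and S^(±1/2) are built once per run
by symmetric eigendecomposition; a condition number above 1e10 triggers a
warning. A hard abort fires if the electron number drifts by more than
1e-6 during a run.

Defaults (also the settings of the acceptance suite): Δt = 1 as,
20 000 steps (20 fs), ϵ = 1e-7, BCH threshold 1e-14. Measured over
20 000 interacting steps: Hermiticity < 1e-12, trace drift < 1e-10,
idempotency < 1e-8, and post-pulse drift of the conserved functional
E[ρ] = Tr(ρ(h+U)) + ½Tr(Δρ V_H[Δρ]) + ½Tr(Δρ Σ_SEX[Δρ]) below 1e-8 Ha.

Delta kick: ρ' = exp(-i I S⁻¹D_ε) ρ(0) exp(+i I D_ε S⁻¹), an S-unitary
boost equivalent to the impulsive field E(t) = I ε δ(t). The default kick
strength for linear spectra is I = 1e-3 a.u.; doubling or halving it moves
Padé-refined peak positions by far less than a grid step (asserted in the
tests via the linearity of the response amplitude to 0.1%).

## Spectra

Windowing: exponential damping e^(-γt) with γ = 0.2 fs⁻¹ by default, which
attenuates the 20 fs sample by e⁻⁴ and gives Lorentzian lines of HWHM
γħ ≈ 0.132 eV; pulse-driven runs use an unnormalized Gaussian gate (peak
value 1 — spectra are in arbitrary consistent units, so the normalization
drops out of every reported quantity).

Transform: one-sided discrete approximation of ∫₀^∞ e^{iωt} μ(t) dt on the
FFT grid, normalization × Δt.

Padé refinement: a rational approximant is fitted to the coarse complex
samples up to 200 eV and evaluated on the output grid (default 0–20 eV in
20 meV steps). The fitted variable is ζ = exp(iωτ) with τ = π/ω_max: the
sample set, symmetrized to negative frequencies by μ(-ω) = μ(ω)*, then
covers the full unit circle, where the linearized least-squares system
(numerator and denominator polynomials, N/2 parameters for N samples, half
each, denominator constant fixed to 1, columns scaled to unit norm) is well
conditioned even with ~480 parameters. A numerically singular fit falls
back to raw-grid interpolation and flags it in the metadata. On the
two-mode fixture the refinement localizes peaks to within one output grid
step; in the real-time-vs-linear-response suite it delivers ~1 meV
agreement against excitation energies, i.e. two orders below the coarse
FFT spacing (0.207 eV for 20 fs).

Polarizability: α_jk(ω) = μ_j(ω)/E_k(ω) with the kick spectrum E(ω) = I
(flat) or the closed-form Gaussian-pulse transform — the analytic form, not
the sampled trace, to avoid windowing bias in the denominator. Grid points
where |E(ω)| < 1e-12 are masked. α_iso is exactly the mean of the diagonal.
Absorption peaks are read from Im α_iso.

Peak fitting: local maxima above 1% of the global maximum, each fitted by a
Lorentzian over a window of ±0.5 eV truncated at neighboring minima *and*
at the contiguous region above 40% of the peak height — the latter keeps
overlapping peaks from pulling each other's fitted positions (the magnitude
of a sum of complex Lorentzians is not a Lorentzian; the core region is the
reliable part).

Nonlinear features: the second harmonic is the magnitude maximum of the
windowed |μ(ω)| near 2ω₀, the rectification signal is |μ(ω)| at the first
nonzero frequency bin (the ω = 0 bin contains the static offset), and
scaling exponents are log–log least-squares slopes against the field
amplitude E0, with nonpositive magnitudes excluded and reported.

## Synthetic systems

The generators define the conditions every test and acceptance run uses;
none of their parameters is adjusted per experiment.

* **Two-level model** — gap in eV, one off-diagonal dipole, optional
  interaction built from a single-channel RI factor (`coupling_scale`
  0.3 Ha^1/2); `interaction` is "none", "bare" (W = V) or a screening
  scale s with W = sV. Closed forms for everything.
* **Noncentrosymmetric model** — a few-level ladder (level ratios
  0 : 1 : 1.55 : 2.25 …) with nearest-neighbor transition dipoles and
  *unequal permanent dipoles* (the diagonal, scaled by `asymmetry`), which
  is what breaks inversion symmetry; the interaction's RI channels couple
  orbital pairs of a single parity each, so only the dipole diagonal breaks
  the symmetry and the `asymmetry = 0` counterpart is exactly
  centrosymmetric (its SHG vanishes to numerical noise — the selection-rule
  test). A bisection on the level spacing with the LR solver in the loop
  places the lowest bright excitation at the requested energy within 1 meV.
* **Random bundles** — seeded: overlap with condition number capped at 50,
  orbital energies drawn so occupied→virtual gaps span ~5–18 eV (the window
  of a small organic chromophore), random symmetric dipoles, and RI kernels
  from random symmetric 3-index factors with SPD metrics (`coupling_scale`
  0.12 → excitation shifts of a few tenths of an eV). Symmetries and
  pair-space positive semidefiniteness hold by construction. A random
  synthetic W is *not* guaranteed weaker than V, so occasional seeds
  produce a response instability (A - B not positive definite); the solver
  refuses those loudly, and `make_rpa_screened` provides the physical
  alternative: the static RPA W, computed entirely in the auxiliary space
  by replacing the metric M with M - X (X the negative-semidefinite static
  response projection), which obeys W ⪯ V exactly.

What the generators do **not** emulate: real Gaussian-orbital integrals,
molecular point-group structure, the density of states of real molecules,
or frequency dependence of W. Passing tests therefore demonstrate the
internal consistency and conservation properties of the method and its
spectral machinery — not agreement with any real molecule's spectrum, which
would require externally exported bundles.

## Pulse experiments

The reference nonlinear run drives the 6.0 eV-tuned noncentrosymmetric
model with E(t) = E0 cos(ω₀t) exp(-(t-t₀)²/(2σ²)), t₀ = 12.6 fs,
σ = 4.2 fs, ħω₀ = 6.0 eV, for 52.6 fs (52 600 steps at 1 as), windowing
with a Gaussian centered at 32.6 fs, spread 4.0 fs. Amplitudes: resonant
driving accumulates over the ~8 fs envelope, so the perturbative window is
narrow — a Rabi-angle estimate d·E0·√(2π)σ/2 shows E0 ≈ 1e-3 a.u. already
saturates the transition (measured exponents collapse there). The scan
uses E0 ∈ {5e-5, 1e-4, 2e-4} a.u. (a 16-fold intensity span), where the
measured exponents are 1.000/2.000/2.000 for linear/SHG/rectification.

## Problem sizes

Everything is dense linear algebra on few-orbital models: the
equivalence suite uses five random bundles of 4–8 orbitals plus the two
fixture models at the full 20 fs / 20 000-step settings (~20 s per bundle
on one core), and the nonlinear scan three 52 600-step runs of the 4-level
model (~15 s each). Dense LR solves are exact at these sizes; iterative
eigensolvers and N²-scaling contraction schemes are out of scope.

## Known limitations

* Static W only; no frequency-dependent screening, no Coulomb-hole term.
* Spin-restricted closed-shell response only; no triplet channel.
* No nuclear motion, no periodic boundary conditions, no damping in the
  equation of motion (environment-induced dephasing must be mimicked by the
  window function).
* The rational refinement is a least-squares fit, not an analytic
  continuation: isolated spurious pole–zero pairs are possible in
  principle; the fallback and the peak-fit stage make the peak lists robust
  against them, and none were observed in the test suite.
* Absolute cross-sections are not produced; spectra are in arbitrary
  consistent units.
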