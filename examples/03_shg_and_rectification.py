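"""Second-harmonic generation and optical rectification in a model without
inversion symmetry.

The model's lowest bright excitation is tuned to 6.0 eV.  A Gaussian pulse
(t0 = 12.6 fs, sigma = 4.2 fs, carrier 6.0 eV) drives it for 52.6 fs at
three field amplitudes; the dipole is Gaussian-windowed after the pulse and
Fourier transformed.  Second-order features (the 2*omega peak and the static
rectification shift) must grow with the square of the field amplitude, the
linear peak with its first power.
"""

from rtbse import make_noncentrosymmetric_model
from rtbse.pipelines import shg_scan

system = make_noncentrosymmetric_model(target_excitation=6.0)

result = shg_scan(system, amplitudes=[5e-5, 1e-4, 2e-4], carrier_ev=6.0)

print("feature           position (eV)   log-log exponent vs E0")
for name in ("linear", "second_harmonic", "rectification"):
    fit = result.exponents[name]
    print(f"{name:16s}  {result.positions[name][-1]:10.3f}      "
          f"{fit.exponent:.4f}")
print("expected: linear peak at 6 eV with exponent 1, second harmonic at "
      "12 eV and rectification at ~0 eV with exponent 2")
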