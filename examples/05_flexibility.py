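"""Flexibility of the entrained clock and its phase-amplitude anatomy.

Builds the linearised parameter-to-orbit response matrix in 12:12 LD,
takes its SVD, then perturbs the parameters 1% along the leading right
singular vector and decomposes the resulting orbit change into per-channel
phase shifts and amplitude changes. Takes a couple of minutes.
"""

import numpy as np

from frqwc import (
    apply_principal_perturbation,
    entrained_orbit,
    phase_amplitude_decompose,
    response_matrix,
    singular_spectrum,
    wild_type,
)

wt = wild_type()
rm = response_matrix(wt)
sp = singular_spectrum(rm)

print("leading singular values:", np.round(sp.sigma[:5], 1))
print(f"flexibility sum = {sp.flexibility_sum:.1f}, "
      f"sigma1/sigma2 = {sp.dominance:.1f} (one direction dominates)")

v1 = sp.principal_direction()
top = sorted(zip(sp.parameter_names, v1), key=lambda kv: -abs(kv[1]))[:5]
print("largest v1 components:", ", ".join(f"{k}={w:+.2f}" for k, w in top))

pert = apply_principal_perturbation(wt, v1, magnitude=0.01)
orbit = entrained_orbit(pert, rm.protocol)
dec = phase_amplitude_decompose(rm.baseline, orbit)
print("\nper-channel phase shift s (h) and relative amplitude change rho:")
for name in dec.s:
    print(f"  {name:4s}  s = {dec.s[name]:+.3f}   rho = {dec.rho[name]:+.3f}")
print(f"conidiation-phase change: {dec.delta_phi_frq:+.3f} h (tracks s_FRQ)")
print("\nFRQ protein phase moves far more than either transcript: the clock's"
      "\nmost accessible degree of freedom is conidiation phase itself.")
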