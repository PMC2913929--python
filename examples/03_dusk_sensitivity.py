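"""Dusk sensitivity: systematic versus driven entrainment.

d(phi)/d(t_dusk) = 0 means dawn-locked, 1 dusk-locked, 1/2 midnight-tracking.
The wild type tracks midnight in LD cycles but is dusk-driven in symmetric
T-cycles; removing the positive wc-1 loop makes long days dusk-driven too.
"""

from frqwc import LightProtocol, dusk_sensitivity, wild_type

wt = wild_type()
mut = wt.scaled(a7=0.01)  # positive loop at 1% strength

for label, params in (("wild type", wt), ("1% coupling", mut)):
    s8 = dusk_sensitivity(params, LightProtocol.LD(8.0, 24.0)).value
    s16 = dusk_sensitivity(params, LightProtocol.LD(16.0, 24.0)).value
    print(f"{label:12s}  s(P=8) = {s8:.3f}   s(P=16) = {s16:.3f}")

s21 = dusk_sensitivity(wt, LightProtocol.tcycle(21.0)).value
print(f"\nwild type, symmetric T-cycle T=21: s = {s21:.3f} (driven: phase rides on dusk)")
print("Short days stay near 0.5 when the loop is decoupled; long days move to 1:"
      "\nthe positive loop is what keeps long-day entrainment systematic.")
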