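"""Circadian feature scoring and desk-scale parameter refinement.

Scores the wild type against the packaged qualitative target table, then
displaces one degradation constant by 30% and lets the local refiner walk
it back using only the circadian features as the objective.
"""

import numpy as np

from frqwc import cost_score, default_cost_config, extract_features, refine_parameters, wild_type

wt = wild_type()
config = default_cost_config()

fs = extract_features(wt)
print("wild-type features:")
for name, value in fs.values.items():
    print(f"  {name:24s} {value:+8.3f}")
print(f"cost score: {cost_score(fs, config):.2f} "
      f"(acceptance threshold {config.accept_threshold})")

start = wt.scaled(d2=1.3)
res = refine_parameters(start, config, budget=60, seed=0, subset=["d2"])
print(f"\nrefinement of d2 displaced +30%: cost {res.start_score:.2f} -> {res.final_score:.2f} "
      f"in {res.n_evaluations} evaluations")
print(f"d2: start {start.d2:.4f} -> refined {res.params.d2:.4f} (wild type {wt.d2:.4f}); "
      f"residual displacement {abs(np.log(res.params.d2 / wt.d2)) / abs(np.log(1.3)):.0%}")
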