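"""Synthetic inputs: parameter ensembles and noisy sparse time courses.

Generates the input classes the analyses consume: a log-normal parameter
ensemble standing in for evolutionary variation, and a noisy 2 h-sampled
time course standing in for an experimental series.
"""

import numpy as np

from frqwc import (
    EnsembleSpec,
    LightProtocol,
    NoisyTimecourseSpec,
    free_running_orbit,
    noisy_timecourse,
    parameter_ensemble,
    protocol_suite,
    simulate,
    wild_type,
)

wt = wild_type()

members = parameter_ensemble(EnsembleSpec(base=wt, sigma_log=0.05, size=200, seed=3))
periods = []
for m in members[:20]:
    orbit = free_running_orbit(m, transient=400.0, window=160.0)
    if orbit.rhythmic:
        periods.append(orbit.period)
print(f"ensemble: {len(members)} members at 5% log-normal spread; "
      f"{len(periods)}/20 simulated members rhythmic, "
      f"period {np.mean(periods):.2f} +/- {np.std(periods):.2f} h")

orbit = free_running_orbit(wt)
traj = simulate(wt, LightProtocol.DD(), (0.0, 96.0), initial=orbit.states[:, 0])
table = noisy_timecourse(traj, NoisyTimecourseSpec(interval=2.0, cv=0.1, seed=1,
                                                   channels=("M_F", "F_T")))
print(f"noisy series: {len(table)} observations "
      f"({table.channel.nunique()} channels, 2 h sampling, 10% CV)")
print(table.head(4).to_string(index=False))

suite = protocol_suite()
print(f"\nprotocol suite: {', '.join(suite)}")
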