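"""Synthetic inputs: protocol suites, parameter ensembles, noisy time courses.

Everything here is a pure function of its spec (including the seed): rerunning
with the same arguments reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .light import LightProtocol
from .model import Trajectory
from .params import KINETIC_NAMES, ClockParameters

__all__ = [
    "EnsembleSpec",
    "NoisyTimecourseSpec",
    "parameter_ensemble",
    "noisy_timecourse",
    "protocol_suite",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Log-normal parameter ensemble emulating evolutionary variation.

    Each member perturbs the kinetic constants as k -> k exp(eps) with
    eps ~ N(0, sigma_log^2) drawn independently per parameter; multiplicative
    noise keeps every rate positive and matches the proportional-perturbation
    convention of the sensitivity analyses. Hill coefficients are floored
    at 1.
    """

    base: ClockParameters
    sigma_log: float = 0.05
    size: int = 100
    seed: int = 0
    subset: tuple | None = None

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be >= 0")
        if self.size < 1:
            raise ValueError("ensemble size must be >= 1")


def parameter_ensemble(spec: EnsembleSpec) -> list[ClockParameters]:
    """Draw the ensemble described by ``spec`` (seed-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    names = list(spec.subset) if spec.subset is not None else list(KINETIC_NAMES)
    members = []
    for _ in range(spec.size):
        eps = rng.normal(0.0, spec.sigma_log, size=len(names))
        members.append(spec.base.perturbed_log(dict(zip(names, eps))))
    return members


@dataclass(frozen=True)
class NoisyTimecourseSpec:
    """Sparse, noisy sampling of a simulated trajectory.

    Emulates experimental series: observations every ``interval`` hours on
    the channels listed, with multiplicative log-normal noise of the given
    coefficient of variation (mean-preserving).
    """

    interval: float = 2.0
    cv: float = 0.1
    seed: int = 0
    channels: tuple = ("M_F", "F_T", "M_W", "P_W")

    def __post_init__(self) -> None:
        if self.interval <= 0:
            raise ValueError("sampling interval must be > 0")
        if self.cv < 0:
            raise ValueError("coefficient of variation must be >= 0")


def noisy_timecourse(traj: Trajectory, spec: NoisyTimecourseSpec) -> pd.DataFrame:
    """Long-format table ``t, channel, value`` of noisy subsamples.

    Sample times are the trajectory grid points nearest to multiples of the
    sampling interval, so samples always lie on the simulated grid.
    """
    t0, t1 = traj.t[0], traj.t[-1]
    if t1 - t0 < spec.interval:
        raise ValueError("trajectory shorter than one sampling interval")
    targets = np.arange(t0, t1 + 1e-9, spec.interval)
    idx = np.unique(np.searchsorted(traj.t, targets).clip(0, len(traj.t) - 1))
    rng = np.random.default_rng(spec.seed)
    sigma = np.sqrt(np.log1p(spec.cv**2))
    rows = []
    for name in spec.channels:
        x = traj.f_total if name == "F_T" else traj.component(name)
        vals = x[idx]
        if sigma > 0:
            noise = np.exp(rng.normal(-sigma**2 / 2, sigma, size=vals.size))
            vals = vals * noise
        for t, v in zip(traj.t[idx], vals):
            rows.append({"t": float(t), "channel": name, "value": float(v)})
    return pd.DataFrame(rows, columns=["t", "channel", "value"])


def protocol_suite() -> dict[str, LightProtocol]:
    """The named protocol set behind the standard experiments.

    DD and LL, 24 h LD cycles at photoperiods 6-18 h in 2 h steps, and
    symmetric photic T-cycles for T = 18-24 h.
    """
    suite: dict[str, LightProtocol] = {
        "DD": LightProtocol.DD(),
        "LL": LightProtocol.LL(),
    }
    for P in range(6, 19, 2):
        suite[f"LD_{P:02d}"] = LightProtocol.LD(float(P), 24.0)
    for T in range(18, 25):
        suite[f"T{T}"] = LightProtocol.tcycle(float(T))
    return suite
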