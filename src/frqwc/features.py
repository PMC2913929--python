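"""Circadian feature extraction and qualitative cost scoring.

Parameter sets are scored against reproducible circadian observables -
free-running period, relative peak/trough phases, entrainment and phase of
conidiation in 12:12 light-dark cycles - rather than against raw time
series. The packaged target table encodes the wild-type feature values with
scales reflecting the variability of the underlying experimental measures.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import minimize

from .light import LightProtocol
from .orbits import ENTRAINED, FREE_RUNNING, entrained_orbit, free_running_orbit, phase_markers
from .params import KINETIC_NAMES, ClockParameters

__all__ = [
    "FeatureSet",
    "CostConfig",
    "extract_features",
    "cost_score",
    "refine_parameters",
    "RefinementResult",
    "default_cost_config",
]

#: Feature names computed in constant darkness.
DD_FEATURES = (
    "dd_period",
    "dd_mf_peak",         # M_F peak time relative to F_T peak (signed, h)
    "dd_mf_trough",
    "dd_ft_trough",
    "dd_pw_antiphase",    # circular distance F_T peak <-> P_W peak, in [0, T/2]
    "dd_mw_rel_amp",      # wc-1 mRNA peak-trough amplitude / mean
)
#: Feature names computed in 12:12 LD.
LD_FEATURES = (
    "ld_phi_minus_midnight",
    "ld_mf_peak_minus_dawn",
    "ld_mf_trough_minus_dusk",
)


@dataclass
class FeatureSet:
    """Computed circadian features; absent features are listed in ``missing``."""

    values: dict
    missing: frozenset
    dd_rhythmic: bool
    ld_entrained: bool

    def __getitem__(self, key: str) -> float:
        return self.values[key]


def _signed(dt: float, period: float) -> float:
    """Reduce a time difference to (-T/2, T/2]."""
    return -((-dt + period / 2) % period - period / 2)


def extract_features(
    params: ClockParameters,
    include_ld: bool = True,
    transient: float = 600.0,
    window: float = 200.0,
    **entrain_kwargs,
) -> FeatureSet:
    """Circadian features from the free-running and 12:12-entrained orbits.

    Arrhythmic parameter sets have every DD feature flagged missing;
    likewise LD features when the clock fails to entrain.
    """
    values: dict = {}
    missing: set = set()

    dd = free_running_orbit(params, transient=transient, window=window)
    dd_rhythmic = dd.status == FREE_RUNNING
    if dd_rhythmic:
        T = dd.period
        mk = phase_markers(dd)
        ft_pk = mk.peaks["F_T"]
        values["dd_period"] = T
        values["dd_mf_peak"] = _signed(mk.peaks["M_F"] - ft_pk, T)
        values["dd_mf_trough"] = _signed(mk.troughs["M_F"] - ft_pk, T)
        values["dd_ft_trough"] = _signed(mk.troughs["F_T"] - ft_pk, T)
        values["dd_pw_antiphase"] = abs(_signed(mk.peaks["P_W"] - ft_pk, T))
        mw = dd.component("M_W")
        values["dd_mw_rel_amp"] = float((mw.max() - mw.min()) / mw.mean())
    else:
        missing.update(DD_FEATURES)

    ld_entrained = False
    if include_ld:
        orbit = entrained_orbit(params, LightProtocol.LD(12.0, 24.0), **entrain_kwargs)
        ld_entrained = orbit.status == ENTRAINED
        if ld_entrained:
            mk = phase_markers(orbit)
            values["ld_phi_minus_midnight"] = _signed(mk.phi_frq - 18.0, 24.0)
            values["ld_mf_peak_minus_dawn"] = _signed(mk.peaks["M_F"], 24.0)
            values["ld_mf_trough_minus_dusk"] = _signed(mk.troughs["M_F"] - 12.0, 24.0)
        else:
            missing.update(LD_FEATURES)
    else:
        missing.update(LD_FEATURES)

    return FeatureSet(
        values=values, missing=frozenset(missing),
        dd_rhythmic=dd_rhythmic, ld_entrained=ld_entrained,
    )


@dataclass
class CostConfig:
    """Targets, weights and scales for the qualitative cost function.

    ``targets`` maps feature name -> {target, weight, scale}. ``penalty``
    is added once per missing feature and dominates any achievable weighted
    mismatch; ``accept_threshold`` is the score below which a parameter set
    counts as a qualitative match.
    """

    targets: dict
    penalty: float = 100.0
    accept_threshold: float = 10.0

    def __post_init__(self) -> None:
        for name, spec in self.targets.items():
            if spec.get("weight", 1.0) < 0:
                raise ValueError(f"negative weight for feature {name}")
            if spec.get("scale", 1.0) <= 0:
                raise ValueError(f"non-positive scale for feature {name}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CostConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            targets=raw["targets"],
            penalty=raw.get("penalty", 100.0),
            accept_threshold=raw.get("accept_threshold", 10.0),
        )

    def uses_ld(self) -> bool:
        return any(
            name in LD_FEATURES and spec.get("weight", 1.0) > 0
            for name, spec in self.targets.items()
        )


def default_cost_config() -> CostConfig:
    """The packaged wild-type target table."""
    ref = importlib.resources.files("frqwc") / "data" / "targets.yaml"
    with importlib.resources.as_file(ref) as path:
        return CostConfig.from_yaml(path)


def cost_score(features: FeatureSet, config: CostConfig) -> float:
    """Weighted sum of squared scaled mismatches plus missing-feature penalty.

    Zero if and only if every targeted feature hits its target exactly and
    none are missing.
    """
    total = 0.0
    for name, spec in config.targets.items():
        w = spec.get("weight", 1.0)
        if w == 0:
            continue
        if name in features.missing or name not in features.values:
            total += config.penalty
            continue
        scale = spec.get("scale", 1.0)
        total += w * ((features.values[name] - spec["target"]) / scale) ** 2
    return total


@dataclass
class RefinementResult:
    params: ClockParameters
    start_score: float
    final_score: float
    n_evaluations: int
    history: list = field(default_factory=list)


def refine_parameters(
    start: ClockParameters,
    config: CostConfig,
    budget: int = 200,
    seed: int = 0,
    subset: Sequence[str] | None = None,
    cost_fn: Callable[[ClockParameters], float] | None = None,
    **extract_kwargs,
) -> RefinementResult:
    """Desk-scale local refinement of a parameter set.

    A derivative-free simplex search in log-parameter space over ``subset``
    (default: all 33 kinetic parameters), capped at ``budget`` cost
    evaluations. The returned set never scores worse than the start. The
    search itself is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic generators.

    ``cost_fn`` overrides the default pipeline (feature extraction followed
    by :func:`cost_score`) - useful for synthetic objectives.
    """
    names = list(subset) if subset is not None else list(KINETIC_NAMES)
    for name in names:
        if name not in KINETIC_NAMES:
            raise KeyError(f"unknown kinetic parameter {name!r}")

    include_ld = config.uses_ld() if cost_fn is None else False

    def build(x: np.ndarray) -> ClockParameters:
        return replace(start, **{n: float(np.exp(v)) for n, v in zip(names, x)})

    history: list = []

    def objective(x: np.ndarray) -> float:
        pset = build(x)
        try:
            if cost_fn is not None:
                score = cost_fn(pset)
            else:
                score = cost_score(
                    extract_features(pset, include_ld=include_ld, **extract_kwargs), config
                )
        except Exception:
            score = config.penalty * len(config.targets)
        history.append(score)
        return score

    x0 = np.log([getattr(start, n) for n in names])
    start_score = objective(x0)
    if budget <= 1:
        return RefinementResult(start, start_score, start_score, len(history), history)

    res = minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxfev": budget, "xatol": 1e-4, "fatol": 1e-6, "adaptive": True},
    )
    if res.fun < start_score:
        best = build(res.x)
        final = float(res.fun)
    else:
        best, final = start, start_score
    return RefinementResult(best, start_score, final, len(history), history)
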