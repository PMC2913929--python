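"""Kinetic parameters of the FRQ/WC-1 oscillator.

The model has exactly 33 free kinetic constants (maximal rates, Michaelis
and repression constants, delay-chain rates, light-state interconversion
rates and Hill coefficients), plus three fixed light-input settings and two
structural chain lengths that are not counted as kinetic parameters.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml

#: Names of the 33 free kinetic parameters, in canonical order.
KINETIC_NAMES: tuple[str, ...] = (
    "a1", "a2", "a3", "a4", "a5", "a6", "a7",
    "b1", "b2", "b3", "b4", "b5", "b6", "b7", "b8", "b9", "b10",
    "d1", "d2", "d3", "d4", "d5",
    "f1", "f2", "gamma1", "gamma2",
    "r1", "r2",
    "n", "m", "k", "g", "h",
)

#: Hill coefficients (dimensionless); floored at 1 when perturbed.
HILL_NAMES: tuple[str, ...] = ("n", "m", "k", "g", "h")


class InvalidParameterError(ValueError):
    """Raised when a kinetic parameter violates its positivity contract."""


@dataclass(frozen=True)
class LightInput:
    """The three fixed settings of the light pathway.

    intensity
        Scale of the light signal L(t) when lights are on (dimensionless,
        default 1); multiplies the WC-1 -> WC-1* photoconversion rate.
    ramp
        Duration in hours of the linear lights-on/lights-off transition;
        0 gives a hard square-wave step.
    dawn_offset
        Absolute time of lights-on within the external cycle (h).
    """

    intensity: float = 1.0
    ramp: float = 0.0
    dawn_offset: float = 0.0


@dataclass(frozen=True)
class ClockParameters:
    """The 33 kinetic constants plus structural/light settings.

    Default values are the fitted wild-type set (to 4 decimal places).
    Units: a1..a6, d1..d5, f1, f2, gamma1, gamma2, r1, r2 in 1/h;
    a7 in 1/(nM h); b1..b10 in nM (b1, b3 act as repression thresholds);
    n, m, k, g, h dimensionless.
    """

    a1: float = 8.3450      # max rate, WC-1*-driven frq transcription
    a2: float = 3.7925      # max rate, WC-1-driven frq transcription
    a3: float = 0.3154      # FRQ translation rate
    a4: float = 0.6787      # basal wc-1 transcription
    a5: float = 10.0718     # max rate, WC-1*-driven wc-1 transcription
    a6: float = 6.6644      # basal WC-1 translation
    a7: float = 2.4695      # FRQ-upregulated WC-1 translation (positive loop)
    b1: float = 4.1472      # repression threshold, light pathway
    b2: float = 0.1560      # half-saturation, WC-1*-driven frq transcription
    b3: float = 0.7149      # repression threshold, dark pathway
    b4: float = 2.9415      # half-saturation, WC-1-driven frq transcription
    b5: float = 4.1075      # Michaelis constant, frq mRNA degradation
    b6: float = 0.4715      # Michaelis constant, active-FRQ degradation
    b7: float = 3.5676      # half-saturation, WC-1*-driven wc-1 transcription
    b8: float = 0.5805      # Michaelis constant, wc-1 mRNA degradation
    b9: float = 7.0233      # Michaelis constant, active-WC-1 degradation
    b10: float = 0.8218     # Michaelis constant, WC-1* degradation
    d1: float = 7.4608      # max rate, frq mRNA degradation
    d2: float = 0.4405      # max rate, active-FRQ degradation
    d3: float = 2.1710      # max rate, wc-1 mRNA degradation
    d4: float = 3.0883      # max rate, active-WC-1 degradation
    d5: float = 23.3120     # max rate, WC-1* degradation
    f1: float = 0.1962      # FRQ delay-chain progression rate
    f2: float = 0.1317      # WC-1 delay-chain progression rate
    gamma1: float = 0.0422  # FRQ delay-chain loss rate
    gamma2: float = 0.0244  # WC-1 delay-chain loss rate
    r1: float = 5.1759      # WC-1 -> WC-1* photoconversion rate
    r2: float = 5.0326      # WC-1* -> WC-1 reversion rate
    n: float = 1.0168       # Hill coeff., WC-1* activation of frq
    m: float = 2.8134       # Hill coeff., WC-1 activation of frq
    k: float = 1.4135       # Hill coeff., WC-1* activation of wc-1
    g: float = 1.2730       # Hill coeff., repression of light pathway
    h: float = 3.6978       # Hill coeff., repression of dark pathway

    light: LightInput = field(default_factory=LightInput)
    chain_len_frq: int = 2
    chain_len_wc: int = 2

    def __post_init__(self) -> None:
        for name in KINETIC_NAMES:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise InvalidParameterError(
                    f"kinetic parameter {name} must be finite and > 0, got {value!r}"
                )
        if self.chain_len_frq < 1 or self.chain_len_wc < 1:
            raise InvalidParameterError("chain lengths must be positive integers")

    # -- array views ---------------------------------------------------

    def kinetic_array(self) -> np.ndarray:
        """The 33 kinetic parameters as a vector in canonical order."""
        return np.array([getattr(self, name) for name in KINETIC_NAMES])

    def with_kinetics(self, values: Iterable[float]) -> "ClockParameters":
        """A copy with the kinetic vector replaced (canonical order)."""
        values = np.asarray(list(values), dtype=float)
        if values.shape != (len(KINETIC_NAMES),):
            raise ValueError(f"expected {len(KINETIC_NAMES)} values, got {values.shape}")
        return replace(self, **dict(zip(KINETIC_NAMES, values.tolist())))

    def scaled(self, **factors: float) -> "ClockParameters":
        """A copy with named kinetic parameters multiplied by factors.

        ``params.scaled(a7=0.01)`` is the loop-decoupling mutant at 1%
        positive-feedback strength.
        """
        updates = {}
        for name, factor in factors.items():
            if name not in KINETIC_NAMES:
                raise KeyError(f"unknown kinetic parameter {name!r}")
            updates[name] = getattr(self, name) * factor
        return replace(self, **updates)

    def perturbed_log(self, delta: Mapping[str, float] | np.ndarray) -> "ClockParameters":
        """Apply proportional (log-space) perturbations k -> k * exp(delta).

        ``delta`` is either a mapping from parameter name to log-perturbation
        or a length-33 vector in canonical order. Hill coefficients are
        floored at 1 after perturbation.
        """
        if isinstance(delta, Mapping):
            vec = np.zeros(len(KINETIC_NAMES))
            for name, d in delta.items():
                vec[KINETIC_NAMES.index(name)] = d
        else:
            vec = np.asarray(delta, dtype=float)
        new = self.kinetic_array() * np.exp(vec)
        for i, name in enumerate(KINETIC_NAMES):
            if name in HILL_NAMES:
                new[i] = max(new[i], 1.0)
        return self.with_kinetics(new)

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = {name: float(getattr(self, name)) for name in KINETIC_NAMES}
        d["light_params"] = {
            "intensity": self.light.intensity,
            "ramp": self.light.ramp,
            "dawn_offset": self.light.dawn_offset,
        }
        d["chain_len_frq"] = self.chain_len_frq
        d["chain_len_wc"] = self.chain_len_wc
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ClockParameters":
        d = dict(d)
        light = d.pop("light_params", {})
        return cls(light=LightInput(**light), **d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ClockParameters":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def wild_type() -> ClockParameters:
    """The packaged wild-type parameter set."""
    ref = importlib.resources.files("frqwc") / "data" / "table1_wt.yaml"
    with importlib.resources.as_file(ref) as path:
        return ClockParameters.from_yaml(path)


def n_kinetic_parameters() -> int:
    """Number of free kinetic parameters in the model (33)."""
    return len(KINETIC_NAMES)
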