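"""Dusk sensitivity, phase robustness and the FRQ-degradation saturation index.

Dusk sensitivity s = d(phi)/d(t_dusk), computed with dawn held at 0, measures
how an entrained phase marker responds to the timing of lights-off: s = 0 is
a dawn-locked (driven) phase, s = 1 dusk-locked, and s = 1/2 a phase that
tracks the middle of the night, i.e. weighs dawn and dusk equally. The
photoperiod-averaged evaluation of this local score is a scalar robustness
index in the spirit of Kitano's framework: R = 1 for a clock that entrains
systematically over the whole photoperiod range, R = 0 for one that is
light-driven throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .light import LightProtocol
from .orbits import ENTRAINED, PeriodicOrbit, conidiation_phase, entrained_orbit, phase_markers
from .params import ClockParameters

__all__ = [
    "DuskSensitivity",
    "RobustnessScore",
    "SaturationProfile",
    "dusk_sensitivity",
    "evaluation_function",
    "robustness_index",
    "relative_robustness",
    "saturation_profile",
    "measure_phi_frq",
    "measure_dawn",
    "measure_dusk",
    "measure_midnight",
    "measure_marker",
]


# ---------------------------------------------------------------------------
# phase measures

def measure_phi_frq(orbit: PeriodicOrbit, alpha: float = 0.15) -> float:
    """Conidiation phase (h after dawn)."""
    return conidiation_phase(orbit, alpha)


def measure_marker(component: str, kind: str = "peak") -> Callable[[PeriodicOrbit], float]:
    """Phase measure returning the peak or trough time of one component."""

    def measure(orbit: PeriodicOrbit) -> float:
        mk = phase_markers(orbit)
        return mk.peaks[component] if kind == "peak" else mk.troughs[component]

    measure.__name__ = f"{component}_{kind}"
    return measure


def _protocol_only(fn):
    fn.protocol_only = True
    return fn


@_protocol_only
def measure_dawn(protocol: LightProtocol) -> float:
    """Analytic reference measure: dawn itself (sensitivity exactly 0)."""
    return protocol.dawn_time


@_protocol_only
def measure_dusk(protocol: LightProtocol) -> float:
    """Analytic reference measure: dusk itself (sensitivity exactly 1)."""
    return protocol.dusk_time


@_protocol_only
def measure_midnight(protocol: LightProtocol) -> float:
    """Analytic reference measure: middle of the night (sensitivity 1/2)."""
    return (protocol.dusk_time + protocol.cycle_length) / 2.0


# ---------------------------------------------------------------------------
# dusk sensitivity


@dataclass
class DuskSensitivity:
    """Central-difference sensitivity of a phase measure to dusk time."""

    value: float
    measure: str
    delta: float
    protocol: LightProtocol
    entrained_minus: bool
    entrained_plus: bool

    @property
    def missing(self) -> bool:
        return not (self.entrained_minus and self.entrained_plus)

    def __float__(self) -> float:
        return self.value


def _perturbed_protocols(protocol: LightProtocol, delta: float) -> tuple[LightProtocol, LightProtocol]:
    """Protocols with dusk shifted by -delta and +delta, dawn fixed at 0.

    In an LD cycle of fixed length, moving dusk is moving the photoperiod.
    In a symmetric T-cycle, dusk sits at T/2, so a dusk shift of delta is a
    cycle-length change of 2*delta.
    """
    if protocol.mode == "LD":
        T = protocol.cycle_length
        return (
            LightProtocol.LD(protocol.photoperiod - delta, T),
            LightProtocol.LD(protocol.photoperiod + delta, T),
        )
    if protocol.mode == "TCYCLE":
        T = protocol.cycle_length
        return (
            LightProtocol.tcycle(T - 2 * delta),
            LightProtocol.tcycle(T + 2 * delta),
        )
    raise ValueError("dusk sensitivity needs a forced protocol")


def dusk_sensitivity(
    params: ClockParameters,
    protocol: LightProtocol,
    phase_measure: Callable | None = None,
    delta: float = 0.5,
    require_baseline: bool = True,
    **entrain_kwargs,
) -> DuskSensitivity:
    """s = [phi(t_dusk + delta) - phi(t_dusk - delta)] / (2 delta).

    ``phase_measure`` maps a :class:`PeriodicOrbit` to a phase in hours after
    dawn (default: conidiation phase). Measures marked ``protocol_only``
    (see :func:`measure_dusk` and friends) are evaluated directly on the
    protocol without simulation; they serve as exact references.

    Phase differences are unwrapped modulo the cycle length to the nearest
    representative, and the result is flagged missing (value NaN) when a
    perturbed protocol fails to entrain.
    """
    if phase_measure is None:
        phase_measure = measure_phi_frq
    name = getattr(phase_measure, "__name__", "phase")
    proto_minus, proto_plus = _perturbed_protocols(protocol, delta)

    if getattr(phase_measure, "protocol_only", False):
        lo = phase_measure(proto_minus)
        hi = phase_measure(proto_plus)
        return DuskSensitivity((hi - lo) / (2 * delta), name, delta, protocol, True, True)

    if require_baseline:
        base = entrained_orbit(params, protocol, **entrain_kwargs)
        if base.status != ENTRAINED:
            raise RuntimeError(f"baseline protocol does not entrain ({base.status})")

    phases = []
    flags = []
    for proto in (proto_minus, proto_plus):
        orbit = entrained_orbit(params, proto, **entrain_kwargs)
        flags.append(orbit.status == ENTRAINED)
        phases.append(phase_measure(orbit) if orbit.status == ENTRAINED else math.nan)
    if not all(flags):
        return DuskSensitivity(math.nan, name, delta, protocol, *flags)
    T = protocol.cycle_length
    diff = (phases[1] - phases[0] + T / 2) % T - T / 2
    return DuskSensitivity(diff / (2 * delta), name, delta, protocol, *flags)


# ---------------------------------------------------------------------------
# evaluation function and robustness index


def evaluation_function(s: float) -> float:
    """Local performance score E(s): tent map peaking at systematic entrainment.

    E(1/2) = 1 (systematic, most robust), E(0) = E(1) = 0 (driven);
    values outside [0, 1] clamp to 0.
    """
    if not np.isfinite(s):
        return 0.0
    return float(np.clip(1.0 - abs(2.0 * s - 1.0), 0.0, 1.0))


@dataclass
class RobustnessScore:
    """Photoperiod profile of the evaluation function and its average R."""

    photoperiods: np.ndarray
    sensitivities: np.ndarray
    evaluations: np.ndarray
    robustness: float
    cycle_length: float = 24.0
    meta: dict = field(default_factory=dict)


def robustness_index(
    params: ClockParameters,
    p_min: float = 6.0,
    p_max: float = 18.0,
    step: float = 2.0,
    cycle_length: float = 24.0,
    delta: float = 0.5,
    evaluation: Callable[[float], float] = evaluation_function,
    sensitivity_fn: Callable[[float], float] | None = None,
    **sens_kwargs,
) -> RobustnessScore:
    """Phase robustness R = (1/(P2-P1)) * integral of E(P) dP (trapezoid).

    Photoperiods at which the clock fails to entrain score E = 0 (loss of
    systematic entrainment is the least robust outcome). ``sensitivity_fn``
    substitutes an externally supplied s(P) - used for analytic checks of
    the quadrature itself.
    """
    grid = np.arange(p_min, p_max + 1e-9, step)
    if grid.size < 2:
        raise ValueError("need at least two photoperiod grid points")
    sens = np.empty(grid.size)
    for i, P in enumerate(grid):
        if sensitivity_fn is not None:
            sens[i] = sensitivity_fn(P)
        else:
            try:
                res = dusk_sensitivity(
                    params, LightProtocol.LD(P, cycle_length), delta=delta,
                    require_baseline=False, **sens_kwargs,
                )
                sens[i] = res.value
            except RuntimeError:
                sens[i] = math.nan
    evals = np.array([evaluation(s) for s in sens])
    if sensitivity_fn is None and np.all(~np.isfinite(sens)):
        raise RuntimeError("no photoperiod on the grid entrains; R undefined")
    R = float(np.trapezoid(evals, grid) / (grid[-1] - grid[0]))
    return RobustnessScore(grid, sens, evals, R, cycle_length)


def relative_robustness(
    params_modified: ClockParameters,
    params_wt: ClockParameters,
    **kwargs,
) -> float:
    """R(modified) / R(wild type) over the same photoperiod range."""
    r_mod = robustness_index(params_modified, **kwargs).robustness
    r_wt = robustness_index(params_wt, **kwargs).robustness
    return r_mod / r_wt


# ---------------------------------------------------------------------------
# saturation index


@dataclass
class SaturationProfile:
    """SI(t) = P_F/(b6 + P_F) over one cycle and its night-time average."""

    t: np.ndarray
    si: np.ndarray
    d_si: float
    photoperiod: float


def saturation_profile(orbit: PeriodicOrbit, params: ClockParameters | None = None) -> SaturationProfile:
    """Saturation of FRQ degradation along an entrained orbit.

    SI close to 1 means the degradation of active FRQ runs at its maximal
    (zero-order) rate, so total FRQ falls linearly through the night. D_SI
    averages SI over the dark interval [dusk, next dawn].
    """
    if params is None:
        params = orbit.params
    if not orbit.protocol.forced:
        raise ValueError("saturation index needs a light-dark cycle (no night in DD/LL)")
    pf = orbit.component("P_F")
    si = pf / (params.b6 + pf)
    dusk = orbit.protocol.photoperiod
    night = orbit.t >= dusk
    return SaturationProfile(
        t=orbit.t, si=si, d_si=float(si[night].mean()), photoperiod=dusk
    )
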