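"""Periodic orbits: free-running rhythms, entrainment and phase markers.

Phases are reported in hours after dawn of the same external cycle
(dawn = 0). Conidiation onset is read off the falling limb of the total-FRQ
profile: the unique time at which F_T has dropped to
F_min + theta (F_max - F_min) with theta = 1/2 - alpha, the threshold
calibrated so that onset coincides with midnight in 12:12 light-dark cycles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .light import LightProtocol
from .model import Trajectory, simulate, initial_state, state_names
from .params import ClockParameters

__all__ = [
    "PeriodicOrbit",
    "PhaseMarkers",
    "PhaseError",
    "free_running_orbit",
    "entrained_orbit",
    "phase_markers",
    "conidiation_phase",
    "scan_photoperiods",
    "scan_tcycles",
]

FREE_RUNNING = "free_running"
ENTRAINED = "entrained"
ARRHYTHMIC = "arrhythmic"
NOT_ENTRAINED = "not_entrained"

#: Peak-to-trough F_T amplitude below which a rhythm counts as absent (nM).
AMPLITUDE_FLOOR = 1e-4

#: Components whose phase markers are reported (F_T handled separately).
MARKER_COMPONENTS = ("M_F", "P_F", "M_W", "P_W", "P_L")


class PhaseError(RuntimeError):
    """Raised when a phase marker is undefined or non-unique."""


@dataclass
class PeriodicOrbit:
    """One sampled cycle of an attractor.

    ``t`` is a uniform grid from 0 to ``period`` inclusive (>= 200 interior
    points); for forced orbits t = 0 is dawn. ``states`` follows the state
    layout of :mod:`frqwc.model`; ``status`` is one of free_running,
    entrained, arrhythmic, not_entrained.
    """

    period: float
    t: np.ndarray
    states: np.ndarray
    status: str
    protocol: LightProtocol
    params: ClockParameters
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.names = state_names(self.params)

    def component(self, name: str) -> np.ndarray:
        if name == "F_T":
            return self.f_total
        return self.states[self.names.index(name)]

    @property
    def f_total(self) -> np.ndarray:
        p = self.params.chain_len_frq
        return self.states[1 : 2 + p].sum(axis=0)

    @property
    def rhythmic(self) -> bool:
        return self.status in (FREE_RUNNING, ENTRAINED)

    def amplitude(self, name: str = "F_T") -> float:
        x = self.component(name)
        return float(x.max() - x.min())


# ---------------------------------------------------------------------------
# free-running rhythms


def _mean_crossings(t: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Times of upward crossings of the series mean, refined by local
    cubic interpolation around each bracketing interval."""
    mu = x.mean()
    s = x - mu
    idx = np.where((s[:-1] < 0) & (s[1:] >= 0))[0]
    out = []
    for i in idx:
        if 1 <= i < len(t) - 2:
            # cubic through the 4 surrounding samples, root by bisection
            ts = t[i - 1 : i + 3]
            xs = s[i - 1 : i + 3]
            coef = np.polynomial.polynomial.polyfit(ts - ts[0], xs, 3)
            lo, hi = t[i] - ts[0], t[i + 1] - ts[0]
            for _ in range(60):
                mid = 0.5 * (lo + hi)
                if np.polynomial.polynomial.polyval(mid, coef) < 0:
                    lo = mid
                else:
                    hi = mid
            out.append(ts[0] + 0.5 * (lo + hi))
        else:
            out.append(t[i] + (t[i + 1] - t[i]) * s[i] / (s[i] - s[i + 1]))
    return np.array(out)


def free_running_orbit(
    params: ClockParameters,
    protocol: LightProtocol | None = None,
    transient: float = 600.0,
    window: float = 200.0,
    initial: np.ndarray | None = None,
    samples: int = 480,
    amplitude_floor: float = AMPLITUDE_FLOOR,
) -> PeriodicOrbit:
    """Locate the free-running limit cycle in constant conditions.

    Integrates through ``transient`` hours, then estimates the period from
    successive upward mean-crossings of F_T over a ``window``-hour stretch
    (averaged over at least 5 cycles). The orbit is classified arrhythmic
    when the F_T amplitude falls below ``amplitude_floor`` or the crossing
    intervals vary by more than 1%.
    """
    if protocol is None:
        protocol = LightProtocol.DD()
    if protocol.forced:
        raise ValueError("free_running_orbit needs a constant-condition protocol")
    y0 = initial_state(params) if initial is None else initial
    pre = simulate(params, protocol, (0.0, transient), initial=y0, dense=False)
    traj = simulate(params, protocol, (0.0, window), initial=pre.final_state)
    ft = traj.f_total
    amp = float(ft.max() - ft.min())
    diagnostics: dict = {"amplitude": amp}
    if amp < amplitude_floor:
        return PeriodicOrbit(
            period=math.nan, t=traj.t, states=traj.states, status=ARRHYTHMIC,
            protocol=protocol, params=params, diagnostics=diagnostics,
        )
    crossings = _mean_crossings(traj.t, ft)
    if len(crossings) < 6:
        diagnostics["reason"] = "fewer than 5 full cycles in window"
        return PeriodicOrbit(
            period=math.nan, t=traj.t, states=traj.states, status=ARRHYTHMIC,
            protocol=protocol, params=params, diagnostics=diagnostics,
        )
    intervals = np.diff(crossings)
    period = float(intervals.mean())
    spread = float(np.abs(intervals - period).max() / period)
    # slowly damped oscillations can keep regular crossings for a long time;
    # a steadily shrinking envelope across the window betrays them
    fifth = len(ft) // 5
    amp_first = float(ft[:fifth].max() - ft[:fifth].min())
    amp_last = float(ft[-fifth:].max() - ft[-fifth:].min())
    decay_ratio = amp_last / amp_first if amp_first > 0 else 1.0
    diagnostics.update(
        n_cycles=len(intervals), interval_spread=spread, decay_ratio=decay_ratio
    )
    if spread > 0.01 or decay_ratio < 0.7:
        return PeriodicOrbit(
            period=math.nan, t=traj.t, states=traj.states, status=ARRHYTHMIC,
            protocol=protocol, params=params, diagnostics=diagnostics,
        )
    # sample one cycle starting at the last crossing (deterministic anchor)
    start_state = simulate(
        params, protocol, (0.0, crossings[-1]), initial=pre.final_state, dense=False
    ).final_state
    cyc = simulate(
        params, protocol, (0.0, period), initial=start_state,
        output_step=period / samples,
    )
    return PeriodicOrbit(
        period=period, t=cyc.t, states=cyc.states, status=FREE_RUNNING,
        protocol=protocol, params=params, diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# entrainment


def _peaks_per_cycle(ft: np.ndarray, prominence_frac: float = 0.01) -> int:
    """Count F_T peaks in one periodic cycle (prominence-filtered)."""
    from scipy.signal import find_peaks

    amp = ft.max() - ft.min()
    if amp <= 0:
        return 0
    x = np.concatenate([ft[:-1], ft[:-1], ft[:-1]])  # 3 tiles, open grid
    pk, _ = find_peaks(x, prominence=prominence_frac * amp)
    n = len(ft) - 1
    return int(np.sum((pk >= n) & (pk < 2 * n)))


def entrained_orbit(
    params: ClockParameters,
    protocol: LightProtocol,
    transient_cycles: int = 40,
    check_cycles: int = 5,
    lock_tol: float = 1e-4,
    max_cycles: int = 80,
    initial: np.ndarray | None = None,
    output_step: float = 0.05,
) -> PeriodicOrbit:
    """Integrate under periodic forcing and test for stable 1:1 entrainment.

    The clock is run cycle by cycle; it is entrained when, after the
    transient, the state sampled at dawn agrees cycle-to-cycle to within
    ``lock_tol`` (relative) for ``check_cycles`` consecutive cycles and F_T
    has exactly one peak per cycle. Anything else - period doubling,
    quasiperiodicity, drift - is classified not_entrained.
    """
    if not protocol.forced:
        raise ValueError("entrained_orbit needs an LD or TCYCLE protocol")
    T = protocol.cycle_length
    y = initial_state(params) if initial is None else np.asarray(initial, dtype=float)
    dawn_states = [y.copy()]
    locked_at = None
    cycle = 0
    while cycle < max_cycles:
        y = simulate(params, protocol, (0.0, T), initial=y, dense=False).final_state
        dawn_states.append(y.copy())
        cycle += 1
        if cycle >= max(transient_cycles, check_cycles + 1):
            recent = dawn_states[-(check_cycles + 1):]
            rels = [
                np.max(np.abs(a - b) / (np.abs(b) + 1e-12))
                for a, b in zip(recent[:-1], recent[1:])
            ]
            if max(rels) < lock_tol:
                locked_at = cycle
                break
    diagnostics = {
        "cycles_run": cycle,
        "final_mismatch": float(
            np.max(np.abs(dawn_states[-1] - dawn_states[-2]) / (np.abs(dawn_states[-1]) + 1e-12))
        ),
    }
    n = max(200, int(round(T / output_step)))
    cyc = simulate(params, protocol, (0.0, T), initial=y, output_step=T / n)
    ft = cyc.f_total
    npk = _peaks_per_cycle(ft)
    diagnostics["peaks_per_cycle"] = npk
    status = ENTRAINED if (locked_at is not None and npk == 1) else NOT_ENTRAINED
    return PeriodicOrbit(
        period=T, t=cyc.t, states=cyc.states, status=status,
        protocol=protocol, params=params, diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# phase markers


def _refine_extremum(t: np.ndarray, x: np.ndarray, i: int, kind: str) -> tuple[float, float]:
    """Quadratic fit over 5 grid points around a periodic extremum."""
    n = len(t) - 1  # last sample duplicates the first
    step = t[1] - t[0]
    offs = np.arange(-2, 3)
    idx = (i + offs) % n
    ts = t[i] + offs * step
    xs = x[idx]
    c = np.polyfit(ts, xs, 2)
    if abs(c[0]) < 1e-300:
        return float(t[i]), float(x[i])
    tv = -c[1] / (2 * c[0])
    if not (ts[0] <= tv <= ts[-1]):  # degenerate fit; keep grid point
        return float(t[i]), float(x[i])
    xv = np.polyval(c, tv)
    return float(tv), float(xv)


@dataclass
class PhaseMarkers:
    """Peak/trough times per component plus the conidiation phase.

    Times are hours after dawn (forced orbits) or after the orbit's
    reference point (free-running), reduced modulo the period.
    """

    period: float
    peaks: dict
    troughs: dict
    phi_frq: float
    alpha: float
    ft_max: float
    ft_min: float

    def as_row(self) -> dict:
        row = {"phi_FRQ": self.phi_frq}
        for name in ("M_F", "F_T"):
            row[f"{name}_peak"] = self.peaks[name]
            row[f"{name}_trough"] = self.troughs[name]
        return row


def phase_markers(orbit: PeriodicOrbit, alpha: float = 0.15) -> PhaseMarkers:
    """Locate per-component peaks/troughs and the conidiation phase phi_FRQ.

    phi_FRQ is the unique time on the falling limb of F_T (between its peak
    and the following trough) where F_T crosses
    F_min + (1/2 - alpha)(F_max - F_min).
    """
    if not orbit.rhythmic:
        raise PhaseError(f"cannot extract phases from a {orbit.status} orbit")
    T = orbit.period
    peaks: dict = {}
    troughs: dict = {}
    for name in MARKER_COMPONENTS + ("F_T",):
        x = orbit.component(name)
        tp, _ = _refine_extremum(orbit.t, x, int(np.argmax(x[:-1])), "max")
        tt, _ = _refine_extremum(orbit.t, x, int(np.argmin(x[:-1])), "min")
        peaks[name] = tp % T
        troughs[name] = tt % T

    ft = orbit.component("F_T")
    ft_max, ft_min = float(ft.max()), float(ft.min())
    level = ft_min + (0.5 - alpha) * (ft_max - ft_min)
    # falling limb: from the F_T peak to the following trough (cyclic)
    n = len(ft) - 1
    i_pk = int(np.argmax(ft[:-1]))
    rolled = np.concatenate([ft[i_pk:-1], ft[:i_pk], ft[i_pk : i_pk + 1]])
    t_roll = orbit.t[i_pk] + np.arange(len(rolled)) * (orbit.t[1] - orbit.t[0])
    i_tr = int(np.argmin(rolled))
    seg, tseg = rolled[: i_tr + 1], t_roll[: i_tr + 1]
    cross = np.where((seg[:-1] >= level) & (seg[1:] < level))[0]
    if len(cross) == 0:
        raise PhaseError("F_T never crosses the conidiation threshold on its falling limb")
    if len(cross) > 1:
        raise PhaseError(f"conidiation phase not unique ({len(cross)} crossings)")
    j = cross[0]
    phi = tseg[j] + (seg[j] - level) / (seg[j] - seg[j + 1]) * (tseg[j + 1] - tseg[j])
    return PhaseMarkers(
        period=T, peaks=peaks, troughs=troughs, phi_frq=float(phi % T),
        alpha=alpha, ft_max=ft_max, ft_min=ft_min,
    )


def conidiation_phase(orbit: PeriodicOrbit, alpha: float = 0.15) -> float:
    """Shortcut for ``phase_markers(orbit, alpha).phi_frq``."""
    return phase_markers(orbit, alpha).phi_frq


# ---------------------------------------------------------------------------
# scans

SCAN_COLUMNS = [
    "P_or_T", "status", "frq_peak", "frq_trough", "FRQ_peak", "FRQ_trough",
    "phi_FRQ", "phi_FRQ_minus_dusk",
]


def _scan_row(value: float, orbit: PeriodicOrbit, dusk: float, alpha: float) -> dict:
    row = dict.fromkeys(SCAN_COLUMNS, math.nan)
    row["P_or_T"] = value
    row["status"] = orbit.status
    if orbit.status == ENTRAINED:
        mk = phase_markers(orbit, alpha)
        row.update(
            frq_peak=mk.peaks["M_F"], frq_trough=mk.troughs["M_F"],
            FRQ_peak=mk.peaks["F_T"], FRQ_trough=mk.troughs["F_T"],
            phi_FRQ=mk.phi_frq, phi_FRQ_minus_dusk=(mk.phi_frq - dusk) % orbit.period,
        )
    return row


def scan_photoperiods(
    params: ClockParameters,
    photoperiods,
    cycle_length: float = 24.0,
    alpha: float = 0.15,
    **entrain_kwargs,
) -> pd.DataFrame:
    """Phase markers across photoperiods in fixed-length LD cycles."""
    rows = []
    for P in photoperiods:
        orbit = entrained_orbit(params, LightProtocol.LD(P, cycle_length), **entrain_kwargs)
        rows.append(_scan_row(P, orbit, dusk=P, alpha=alpha))
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)


def scan_tcycles(
    params: ClockParameters,
    cycle_lengths,
    alpha: float = 0.15,
    **entrain_kwargs,
) -> pd.DataFrame:
    """Phase markers across symmetric photic T-cycles (P = T/2)."""
    rows = []
    for T in cycle_lengths:
        orbit = entrained_orbit(params, LightProtocol.tcycle(T), **entrain_kwargs)
        rows.append(_scan_row(T, orbit, dusk=T / 2, alpha=alpha))
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)
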