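"""Loss of free-running rhythmicity as the positive loop is decoupled.

The positive-loop coupling a7 (FRQ-upregulated WC-1 translation) is scanned
as a fraction c of its wild-type value. The mechanism of rhythm loss is
classified from the amplitude and period of the free-running oscillation
along the scan: a supercritical Hopf bifurcation shows a continuous
amplitude collapse with A^2 linear in c near the critical coupling and a
bounded period; a SNIC (saddle-node on invariant circle) shows a diverging
period at near-constant amplitude; a subcritical Hopf or fold of cycles
shows an amplitude jump with hysteresis between sweep directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .light import LightProtocol
from .model import initial_state, simulate
from .orbits import FREE_RUNNING, free_running_orbit
from .params import ClockParameters

__all__ = [
    "CouplingScan",
    "scan_coupling",
    "classify_loss_of_rhythmicity",
    "SUPERCRITICAL_HOPF",
    "SNIC",
    "SUBCRITICAL_OR_FOLD",
    "UNDETERMINED",
]

SUPERCRITICAL_HOPF = "supercritical_hopf"
SNIC = "snic"
SUBCRITICAL_OR_FOLD = "subcritical_or_fold"
UNDETERMINED = "undetermined"


@dataclass
class CouplingScan:
    """Free-running amplitude/period along a coupling-strength grid.

    ``amplitude`` is the peak-trough F_T amplitude (nM), zero for
    arrhythmic entries; ``status`` holds the orbit classification per point.
    """

    c: np.ndarray
    amplitude: np.ndarray
    period: np.ndarray
    mean_level: np.ndarray
    status: list
    params: ClockParameters | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "c": self.c,
                "amplitude": self.amplitude,
                "period": self.period,
                "mean": self.mean_level,
                "status": self.status,
            }
        )


def scan_coupling(
    params: ClockParameters,
    c_grid,
    transient: float = 600.0,
    window: float = 200.0,
) -> CouplingScan:
    """Free-running orbits for a7 scaled by each fraction in ``c_grid``.

    The scan proceeds through the grid in the given order with numerical
    continuation: each point starts from the final state of the previous
    one, which keeps the solution on the same attractor branch and makes
    bidirectional sweeps meaningful.
    """
    c_grid = np.asarray(list(c_grid), dtype=float)
    if np.any(c_grid <= 0) or np.any(c_grid > 1):
        raise ValueError("coupling fractions must lie in (0, 1]")
    amps = np.empty_like(c_grid)
    periods = np.full_like(c_grid, math.nan)
    means = np.empty_like(c_grid)
    status = []
    y0 = initial_state(params)
    for i, c in enumerate(c_grid):
        pset = params.scaled(a7=c)
        orbit = free_running_orbit(pset, transient=transient, window=window, initial=y0)
        ft = orbit.f_total
        means[i] = float(ft.mean())
        if orbit.status == FREE_RUNNING:
            amps[i] = orbit.amplitude("F_T")
            periods[i] = orbit.period
            y0 = orbit.states[:, -1]
        else:
            amps[i] = 0.0
            # continue from wherever the damped solution ended up
            y0 = simulate(pset, LightProtocol.DD(), (0.0, transient),
                          initial=y0, dense=False).final_state
        status.append(orbit.status)
    return CouplingScan(
        c=c_grid, amplitude=amps, period=periods, mean_level=means,
        status=status, params=params,
    )


def _critical_fraction(scan: CouplingScan) -> tuple[float, np.ndarray]:
    """Estimate c* and return indices of rhythmic points sorted by closeness."""
    rhythmic = scan.amplitude > 0
    c_rh = scan.c[rhythmic]
    c_ar = scan.c[~rhythmic]
    c_star = (c_rh.min() + c_ar.max()) / 2 if c_ar.size else c_rh.min()
    order = np.argsort(np.abs(scan.c - c_star))
    near = [i for i in order if rhythmic[i]]
    return float(c_star), np.array(near)


def classify_loss_of_rhythmicity(
    scan: CouplingScan,
    reverse_scan: CouplingScan | None = None,
    jump_fraction: float = 0.2,
    r2_min: float = 0.9,
    fit_points: int = 5,
) -> dict:
    """Classify how the free-running rhythm is destroyed along the scan.

    Returns a report dict with the classification, the estimated critical
    fraction c*, the R^2 of the A^2-versus-c linear fit near c*, and the
    period ratio diagnostics. Requires the scan to contain both rhythmic
    and arrhythmic entries.
    """
    rhythmic = scan.amplitude > 0
    if rhythmic.all() or (~rhythmic).all():
        raise ValueError("scan must contain both rhythmic and arrhythmic points")

    c_star, near = _critical_fraction(scan)
    a_max = scan.amplitude.max()

    # amplitude jump between adjacent rhythmic grid points; the residual
    # drop at the rhythmic/arrhythmic boundary is judged separately (it
    # shrinks with the grid only for a continuous collapse)
    order = np.argsort(scan.c)
    a_sorted = scan.amplitude[order]
    rhythmic_sorted = a_sorted > 0
    pair_ok = rhythmic_sorted[:-1] & rhythmic_sorted[1:]
    jumps = np.abs(np.diff(a_sorted))[pair_ok]
    max_jump = float(jumps.max() / a_max) if jumps.size else 0.0
    boundary_frac = float(scan.amplitude[near[0]] / a_max)

    # A^2 vs c on the rhythmic points nearest c*
    sel = near[:fit_points]
    x = scan.c[sel]
    y = scan.amplitude[sel] ** 2
    r2 = math.nan
    slope = math.nan
    if len(sel) >= 3:
        coef = np.polyfit(x, y, 1)
        pred = np.polyval(coef, x)
        ss_res = float(np.sum((y - pred) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else math.nan
        slope = float(coef[0])

    # period behaviour approaching c*
    ref_period = scan.period[rhythmic][np.argmax(scan.c[rhythmic])]
    periods = scan.period[rhythmic]
    period_ratio = float(np.nanmax(periods) / ref_period)

    hysteresis = False
    if reverse_scan is not None:
        both = {}
        for s in (scan, reverse_scan):
            for c, a in zip(s.c, s.amplitude):
                both.setdefault(round(float(c), 12), []).append(a)
        for c, vals in both.items():
            if len(vals) == 2 and min(vals) > 0:
                if abs(vals[0] - vals[1]) > 0.01 * max(vals):
                    hysteresis = True

    continuous = max_jump <= jump_fraction and boundary_frac < 0.5
    if period_ratio > 3.0:
        label = SNIC
    elif continuous and (not math.isnan(r2)) and r2 > r2_min and period_ratio < 2.0:
        label = SUPERCRITICAL_HOPF
    elif not continuous and hysteresis:
        label = SUBCRITICAL_OR_FOLD
    else:
        label = UNDETERMINED

    return {
        "classification": label,
        "c_star": c_star,
        "r_squared": r2,
        "a2_slope": slope,
        "max_amplitude_jump_fraction": max_jump,
        "boundary_amplitude_fraction": boundary_frac,
        "period_ratio": period_ratio,
        "hysteresis": hysteresis,
    }
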