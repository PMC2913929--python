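"""Core oscillator equations and trajectory integration.

The circuit couples a negative loop, in which active FRQ protein shuts down
transcription of its own gene, to a positive loop in which FRQ boosts
production of its transcriptional activator WC-1. Light acts through
photoconversion of active WC-1 into the light-activated form WC-1*, a potent
activator of both frq and wc-1 transcription.

The lag between translation of a protein and the appearance of its active
form is gamma-distributed. A gamma delay with integer shape is equivalent to
a linear chain of first-order intermediates (the "linear chain trick"), which
converts the integrodifferential system into ordinary differential equations:
a chain of length p with progression rate f and loss rate gamma realises the
kernel

    G(tau) = f^p tau^(p-1) exp(-(f+gamma) tau) / (p-1)!

whose total mass (the fraction of translated protein that ever matures) is
(f/(f+gamma))^p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .light import LightProtocol
from .params import ClockParameters, InvalidParameterError

__all__ = [
    "delay_kernel",
    "build_ode_system",
    "simulate",
    "total_frq",
    "Trajectory",
    "IntegrationError",
    "state_names",
    "initial_state",
]

#: Default solver settings; halving them moves F_T by well under 0.1%.
RTOL = 1e-8
ATOL = 1e-10
DEFAULT_OUTPUT_STEP = 0.05  # h


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last valid time t={last_time:.3f} h)")
        self.last_time = last_time


def delay_kernel(tau, f: float, gamma: float, p: int):
    """Gamma delay-kernel density G(tau) in 1/h.

    Parameters
    ----------
    tau : float or array
        Elapsed time since translation (h), >= 0.
    f, gamma : float
        Chain progression and loss rates (1/h); f > 0, gamma >= 0.
    p : int
        Chain length (gamma shape parameter), >= 1.
    """
    if f <= 0 or not np.isfinite(f):
        raise InvalidParameterError(f"progression rate f must be > 0, got {f}")
    if gamma < 0:
        raise InvalidParameterError(f"loss rate gamma must be >= 0, got {gamma}")
    if int(p) != p or p < 1:
        raise InvalidParameterError(f"chain length p must be a positive integer, got {p}")
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be non-negative")
    p = int(p)
    return f**p * tau ** (p - 1) * np.exp(-(f + gamma) * tau) / math.factorial(p - 1)


def state_names(params: ClockParameters) -> list[str]:
    """Component names in state-vector order."""
    p, q = params.chain_len_frq, params.chain_len_wc
    return (
        ["M_F"]
        + [f"F_{i+1}" for i in range(p)]
        + ["P_F", "M_W"]
        + [f"W_{j+1}" for j in range(q)]
        + ["P_W", "P_L"]
    )


def initial_state(params: ClockParameters, level: float = 0.1) -> np.ndarray:
    """Uniform initial condition (all components at `level` nM)."""
    return np.full(5 + params.chain_len_frq + params.chain_len_wc, float(level))


def build_ode_system(params: ClockParameters) -> Callable[[np.ndarray, float, float], np.ndarray]:
    """Right-hand side f(state, t, light_level) of the clock ODEs.

    State layout: [M_F, F_1..F_p, P_F, M_W, W_1..W_q, P_W, P_L].
    ``light_level`` is the instantaneous L(t) (already intensity-scaled).

    Transcription of frq combines a light pathway (Hill activation by WC-1*)
    and a dark pathway (Hill activation by WC-1), each gated by its own
    FRQ repression term 1/(1 + (P_F/b)^e); degradation of mRNAs and active
    proteins follows Michaelis-Menten kinetics.
    """
    pr = params
    p, q = pr.chain_len_frq, pr.chain_len_wc
    i_PF = 1 + p
    i_MW = 2 + p
    i_PW = 3 + p + q
    i_PL = 4 + p + q
    nvar = 5 + p + q
    fg1 = pr.f1 + pr.gamma1
    fg2 = pr.f2 + pr.gamma2
    b2n = pr.b2**pr.n
    b4m = pr.b4**pr.m
    b7k = pr.b7**pr.k

    def rhs(y: np.ndarray, t: float, light: float) -> np.ndarray:
        # Clamp tiny solver undershoots so fractional powers stay real.
        y = np.maximum(y, 0.0)
        MF = y[0]
        PF = y[i_PF]
        MW = y[i_MW]
        PW = y[i_PW]
        PL = y[i_PL]

        PLn = PL**pr.n
        act_light = pr.a1 * PLn / (b2n + PLn) / (1.0 + (PF / pr.b1) ** pr.g)
        PWm = PW**pr.m
        act_dark = pr.a2 * PWm / (b4m + PWm) / (1.0 + (PF / pr.b3) ** pr.h)

        dy = np.empty(nvar)
        dy[0] = act_light + act_dark - pr.d1 * MF / (pr.b5 + MF)

        dy[1] = pr.a3 * MF - fg1 * y[1]
        for i in range(2, 1 + p):
            dy[i] = pr.f1 * y[i - 1] - fg1 * y[i]
        dy[i_PF] = pr.f1 * y[p] - pr.d2 * PF / (pr.b6 + PF)

        PLk = PL**pr.k
        dy[i_MW] = pr.a4 + pr.a5 * PLk / (b7k + PLk) - pr.d3 * MW / (pr.b8 + MW)

        dy[i_MW + 1] = (pr.a6 + pr.a7 * PF) * MW - fg2 * y[i_MW + 1]
        for j in range(i_MW + 2, i_MW + 1 + q):
            dy[j] = pr.f2 * y[j - 1] - fg2 * y[j]

        dy[i_PW] = (
            pr.f2 * y[i_MW + q]
            - pr.d4 * PW / (pr.b9 + PW)
            - pr.r1 * light * PW
            + pr.r2 * PL
        )
        dy[i_PL] = pr.r1 * light * PW - pr.r2 * PL - pr.d5 * PL / (pr.b10 + PL)
        return dy

    return rhs


@dataclass
class Trajectory:
    """A sampled solution of the clock equations.

    ``states`` has one row per component (see :func:`state_names`) and one
    column per time point. ``f_total`` is the derived total-FRQ channel
    F_T = P_F + sum(F_i), the quantity read out as "FRQ protein".
    """

    t: np.ndarray
    states: np.ndarray
    params: ClockParameters
    protocol: LightProtocol

    def __post_init__(self) -> None:
        self.names = state_names(self.params)

    def component(self, name: str) -> np.ndarray:
        return self.states[self.names.index(name)]

    @property
    def f_total(self) -> np.ndarray:
        p = self.params.chain_len_frq
        return self.states[1 : 2 + p].sum(axis=0)

    @property
    def final_state(self) -> np.ndarray:
        return self.states[:, -1]

    def to_frame(self, include_chain: bool = False) -> pd.DataFrame:
        cols = {"t": self.t}
        keep = self.names if include_chain else ["M_F", "P_F", "M_W", "P_W", "P_L"]
        for name in keep:
            cols[name] = self.component(name)
        cols["F_T"] = self.f_total
        return pd.DataFrame(cols)

    def to_csv(self, path: str | Path, include_chain: bool = False) -> None:
        self.to_frame(include_chain).to_csv(path, index=False)


def total_frq(traj: Trajectory) -> np.ndarray:
    """Total FRQ protein F_T(t) = P_F(t) + sum of chain intermediates."""
    return traj.f_total


def _segments_with_ramp(protocol: LightProtocol, intensity: float, ramp: float,
                        t0: float, t1: float) -> list[tuple[float, float, float]]:
    segs = [(a, b, lvl * intensity) for a, b, lvl in protocol.segments(t0, t1)]
    if ramp <= 0:
        return segs
    # Approximate the linear transition by short constant sub-steps.
    out: list[tuple[float, float, float]] = []
    nsub = 8
    for idx, (a, b, lvl) in enumerate(segs):
        prev = segs[idx - 1][2] if idx > 0 else lvl
        width = min(ramp, b - a)
        if idx > 0 and prev != lvl and width > 0:
            for s in range(nsub):
                lo = a + width * s / nsub
                hi = a + width * (s + 1) / nsub
                frac = (s + 0.5) / nsub
                out.append((lo, hi, prev + (lvl - prev) * frac))
            out.append((a + width, b, lvl))
        else:
            out.append((a, b, lvl))
    return [(a, b, l) for a, b, l in out if b > a]


def simulate(
    params: ClockParameters,
    protocol: LightProtocol,
    t_span: tuple[float, float],
    initial: Sequence[float] | None = None,
    output_step: float = DEFAULT_OUTPUT_STEP,
    dense: bool = True,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> Trajectory:
    """Integrate the clock under a light protocol.

    The square-wave light signal is handled by integrating each maximal
    interval of constant light separately with a stiff-capable variable-step
    solver, so discontinuities never fall inside a solver step. With
    ``dense=False`` only the solver's own steps are kept (used for
    transients, where the fine output grid is not needed).
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if t1 <= t0:
        raise ValueError("t_span must have positive length")
    y = (
        initial_state(params)
        if initial is None
        else np.asarray(initial, dtype=float).copy()
    )
    if y.shape != initial_state(params).shape:
        raise ValueError("initial state has wrong dimension")
    rhs = build_ode_system(params)

    def f(t, y, light):
        return rhs(y, t, light)

    segs = _segments_with_ramp(protocol, params.light.intensity, params.light.ramp, t0, t1)
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    for a, b, level in segs:
        kwargs = {}
        if dense:
            grid = np.arange(a, b, output_step)
            if grid.size == 0 or grid[-1] < b:
                grid = np.append(grid, b)
            kwargs["t_eval"] = grid
        sol = solve_ivp(
            f, (a, b), y, args=(level,), method="LSODA", rtol=rtol, atol=atol, **kwargs
        )
        if not sol.success:
            raise IntegrationError(sol.message, sol.t[-1] if sol.t.size else a)
        y = sol.y[:, -1].copy()
        ts.append(sol.t)
        ys.append(sol.y)
    t = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)
    # drop duplicated segment-boundary points
    keep = np.concatenate([[True], np.diff(t) > 0])
    t, Y = t[keep], Y[:, keep]
    low = Y.min()
    if low < -1e-9:
        raise IntegrationError(f"state went negative ({low:.2e} nM)", t[-1])
    np.clip(Y, 0.0, None, out=Y)
    return Trajectory(t=t, states=Y, params=params, protocol=protocol)
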