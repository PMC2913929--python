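"""Global flexibility of the entrained clock.

The linearisation of the map from (log-)parameter perturbations to changes
of the entrained limit cycle is sampled as a finite matrix: rows stack the
five observed channels at N time points per cycle (each channel scaled by
its wild-type mean level, so entries are relative concentration changes),
columns are central differences with respect to ln k_j for each of the 33
kinetic parameters. Its singular values
measure how strongly bounded parameter variation - a proxy for evolutionary
change - can reshape the clock's outputs; the sum of singular values is the
scalar flexibility index, and the leading right singular vector v1 is the
most effective direction of combined parameter change.

A perturbed cycle is interpreted through a phase-amplitude decomposition:
delta x_i(t) ~ -s_i * dx_i/dt + rho_i (x_i(t) - mean x_i), i.e. each
component's change is explained as a phase shift s_i (h, positive = delay)
plus a relative amplitude change rho_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .light import LightProtocol
from .orbits import ENTRAINED, PeriodicOrbit, conidiation_phase, entrained_orbit
from .params import KINETIC_NAMES, ClockParameters

__all__ = [
    "ResponseMatrix",
    "FlexibilitySpectrum",
    "PhaseAmplitudeDecomposition",
    "response_matrix",
    "singular_spectrum",
    "relative_flexibility",
    "apply_principal_perturbation",
    "phase_amplitude_decompose",
    "CHANNELS",
]

#: Observed channels of the limit cycle (FRQ protein read out as F_T).
CHANNELS = ("M_F", "F_T", "M_W", "P_W", "P_L")


class EntrainmentLostError(RuntimeError):
    """A perturbed parameter set failed to entrain; the matrix is invalid."""


def _sample_channels(orbit: PeriodicOrbit, n: int) -> np.ndarray:
    """Channel values on a uniform n-point grid over one cycle (open grid)."""
    tgrid = np.linspace(0.0, orbit.period, n, endpoint=False)
    out = np.empty((len(CHANNELS), n))
    for i, name in enumerate(CHANNELS):
        out[i] = np.interp(tgrid, orbit.t, orbit.component(name))
    return out


@dataclass
class ResponseMatrix:
    """Linearised parameter-to-orbit map, sampled as a (5N x 33) matrix."""

    matrix: np.ndarray
    sample_times: np.ndarray
    scales: np.ndarray              # per-channel normalisation scales A_i (mean levels)
    rel_step: float
    baseline: PeriodicOrbit
    baseline_samples: np.ndarray    # raw channel samples (5 x N)
    params: ClockParameters
    protocol: LightProtocol
    parameter_names: tuple = KINETIC_NAMES


def response_matrix(
    params: ClockParameters,
    protocol: LightProtocol | None = None,
    rel_step: float = 0.01,
    samples_per_cycle: int = 120,
    warm_transient: int = 15,
    **entrain_kwargs,
) -> ResponseMatrix:
    """Central-difference response of the entrained orbit to each parameter.

    Each parameter is perturbed proportionally by exp(+/- rel_step); the
    perturbed systems are re-entrained (warm-started from the baseline dawn
    state) and the orbit change per unit log-parameter forms one column.
    Orbits are aligned by absolute clock time (dawn = 0), which is valid
    because the entrained period is pinned to the cycle length.
    """
    if protocol is None:
        protocol = LightProtocol.LD(12.0, 24.0)
    base = entrained_orbit(params, protocol, **entrain_kwargs)
    if base.status != ENTRAINED:
        raise EntrainmentLostError(f"baseline does not entrain ({base.status})")
    n = samples_per_cycle
    base_samples = _sample_channels(base, n)
    scales = base_samples.mean(axis=1)
    if np.any(scales <= 0):
        raise EntrainmentLostError("a baseline channel has zero mean level")
    y_warm = base.states[:, 0]

    cols = np.empty((len(CHANNELS) * n, len(KINETIC_NAMES)))
    warm_kwargs = dict(entrain_kwargs)
    warm_kwargs.setdefault("transient_cycles", warm_transient)
    for j, name in enumerate(KINETIC_NAMES):
        sides = []
        for sign in (-1.0, +1.0):
            pert = params.perturbed_log({name: sign * rel_step})
            orbit = entrained_orbit(pert, protocol, initial=y_warm, **warm_kwargs)
            if orbit.status != ENTRAINED:
                raise EntrainmentLostError(
                    f"perturbation of {name} ({sign:+.0f}{rel_step:.2%}) lost entrainment"
                )
            sides.append(_sample_channels(orbit, n) / scales[:, None])
        cols[:, j] = ((sides[1] - sides[0]) / (2 * rel_step)).ravel()
    tgrid = np.linspace(0.0, base.period, n, endpoint=False)
    return ResponseMatrix(
        matrix=cols, sample_times=tgrid, scales=scales, rel_step=rel_step,
        baseline=base, baseline_samples=base_samples, params=params, protocol=protocol,
    )


@dataclass
class FlexibilitySpectrum:
    """Singular spectrum of a response matrix."""

    sigma: np.ndarray               # descending singular values
    u: np.ndarray                   # left singular vectors (columns)
    v: np.ndarray                   # right singular vectors (columns)
    parameter_names: tuple
    normalisation: dict = field(default_factory=dict)

    @property
    def flexibility_sum(self) -> float:
        return float(self.sigma.sum())

    @property
    def dominance(self) -> float:
        """sigma_1 / sigma_2."""
        return float(self.sigma[0] / self.sigma[1])

    def principal_direction(self) -> np.ndarray:
        """v1, sign-fixed so a positive step delays the clock (see
        :func:`apply_principal_perturbation`)."""
        sign = self.normalisation.get("v1_sign", 1.0)
        return sign * self.v[:, 0]


def singular_spectrum(rm: ResponseMatrix) -> FlexibilitySpectrum:
    """Full SVD of the response matrix.

    The sign of the leading pair (u1, v1) is fixed by requiring that u1's
    projection onto the (normalised) negative time-derivative of the
    baseline orbit is positive, so that stepping parameters along +v1
    produces a phase delay of the cycle.
    """
    U, s, Vt = np.linalg.svd(rm.matrix, full_matrices=False)
    err = np.linalg.norm(rm.matrix - (U * s) @ Vt)
    scale = np.linalg.norm(rm.matrix)
    if scale > 0 and err > 1e-8 * scale:
        raise RuntimeError("SVD reconstruction failed")
    # derivative of the normalised baseline channels, stacked like the rows
    dt = rm.sample_times[1] - rm.sample_times[0]
    xb = rm.baseline_samples / rm.scales[:, None]
    xdot = (np.roll(xb, -1, axis=1) - np.roll(xb, 1, axis=1)) / (2 * dt)
    proj = float(U[:, 0] @ (-xdot.ravel()))
    sign = 1.0 if proj >= 0 else -1.0
    return FlexibilitySpectrum(
        sigma=s, u=U, v=Vt.T, parameter_names=rm.parameter_names,
        normalisation={
            "scales": rm.scales.tolist(),
            "channels": list(CHANNELS),
            "rel_step": rm.rel_step,
            "samples_per_cycle": len(rm.sample_times),
            "coordinates": "log-parameters; channels scaled by WT mean level",
            "v1_sign": sign,
        },
    )


def relative_flexibility(
    spectrum_modified: FlexibilitySpectrum, spectrum_wt: FlexibilitySpectrum
) -> float:
    """Ratio of singular-value sums: flexibility relative to the wild type."""
    return spectrum_modified.flexibility_sum / spectrum_wt.flexibility_sum


def apply_principal_perturbation(
    params: ClockParameters, v1: np.ndarray, magnitude: float = 0.02
) -> ClockParameters:
    """Proportional parameter step along a unit direction in log space:
    k_j -> k_j * exp(magnitude * v1_j)."""
    v1 = np.asarray(v1, dtype=float)
    norm = np.linalg.norm(v1)
    if abs(norm - 1.0) > 1e-6:
        raise ValueError(f"v1 must be a unit vector, |v1| = {norm:.6f}")
    return params.perturbed_log(magnitude * v1)


@dataclass
class PhaseAmplitudeDecomposition:
    """Per-component phase shifts and relative amplitude changes."""

    s: dict                         # h; positive = delay
    rho: dict                       # dimensionless
    delta_phi_frq: float            # h; independent re-measurement via phi_FRQ
    residual_fraction: dict         # |residual| / |delta x| per component
    period: float


def phase_amplitude_decompose(
    base: PeriodicOrbit,
    perturbed: PeriodicOrbit,
    alpha: float = 0.15,
) -> PhaseAmplitudeDecomposition:
    """Least-squares fit delta x_i(t) ~ -s_i xdot_i(t) + rho_i (x_i - mean x_i).

    Both orbits must be entrained to the same cycle length; they are sampled
    on a common dawn-anchored grid. The conidiation-phase change is measured
    independently by re-running the threshold-crossing phase marker on the
    perturbed orbit.
    """
    if abs(base.period - perturbed.period) > 1e-6 * base.period:
        raise ValueError("orbits have different periods; decomposition undefined")
    n = 240
    xb = _sample_channels(base, n)
    xp = _sample_channels(perturbed, n)
    dt = base.period / n
    s: dict = {}
    rho: dict = {}
    resid: dict = {}
    for i, name in enumerate(CHANNELS):
        x = xb[i]
        dx = xp[i] - x
        xdot = (np.roll(x, -1) - np.roll(x, 1)) / (2 * dt)
        A = np.column_stack([-xdot, x - x.mean()])
        coef, *_ = np.linalg.lstsq(A, dx, rcond=None)
        s[name] = float(coef[0])
        rho[name] = float(coef[1])
        dnorm = np.linalg.norm(dx)
        resid[name] = float(np.linalg.norm(dx - A @ coef) / dnorm) if dnorm > 0 else 0.0
    T = base.period
    dphi = conidiation_phase(perturbed, alpha) - conidiation_phase(base, alpha)
    dphi = (dphi + T / 2) % T - T / 2
    return PhaseAmplitudeDecomposition(
        s=s, rho=rho, delta_phi_frq=float(dphi), residual_fraction=resid, period=T
    )
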