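import numpy as np
import pytest

from frqwc import LightProtocol, entrained_orbit, free_running_orbit, wild_type


@pytest.fixture(scope="session")
def wt():
    return wild_type()


@pytest.fixture(scope="session")
def dd_orbit(wt):
    """Converged free-running orbit in constant darkness."""
    return free_running_orbit(wt)


@pytest.fixture(scope="session")
def ld12_orbit(wt):
    """Wild type entrained to a 12:12 light-dark cycle."""
    return entrained_orbit(wt, LightProtocol.LD(12.0, 24.0))


def shifted_orbit(orbit, shift):
    """Copy of a periodic orbit advanced in time by `shift` hours."""
    from copy import copy

    new = copy(orbit)
    T = orbit.period
    src = (orbit.t - shift) % T
    order = np.argsort(orbit.t % T)
    tt = orbit.t[order]
    states = np.empty_like(orbit.states)
    for i in range(orbit.states.shape[0]):
        states[i] = np.interp(src, tt, orbit.states[i][order], period=T)
    new.states = states
    return new


def sinusoidal_orbit(wt, period=24.0, n=240):
    """Smooth synthetic orbit: every component a cosine with its own phase
    and amplitude (well inside the linear regime of the phase-amplitude
    decomposition)."""
    from frqwc.model import initial_state
    from frqwc.orbits import ENTRAINED, PeriodicOrbit
    from frqwc.light import LightProtocol

    nvar = initial_state(wt).size
    t = np.linspace(0.0, period, n + 1)
    rng = np.random.default_rng(1234)
    phases = rng.uniform(0, period, size=nvar)
    amps = rng.uniform(0.3, 1.2, size=nvar)
    states = 1.5 + amps[:, None] * np.cos(2 * np.pi * (t[None, :] - phases[:, None]) / period)
    return PeriodicOrbit(period=period, t=t, states=states, status=ENTRAINED,
                         protocol=LightProtocol.LD(12.0, 24.0), params=wt)


def scaled_orbit(orbit, rho):
    """Copy with every component scaled by (1 + rho) about its own mean."""
    from copy import copy

    new = copy(orbit)
    means = orbit.states.mean(axis=1, keepdims=True)
    new.states = means + (1.0 + rho) * (orbit.states - means)
    return new
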