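import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import quad

from frqwc import LightProtocol, delay_kernel, simulate, total_frq, wild_type
from frqwc.model import Trajectory, build_ode_system, initial_state
from frqwc.params import ClockParameters, InvalidParameterError

TINY = 1e-12


class TestDelayKernel:
    def test_pure_exponential_when_single_stage_no_loss(self):
        tau = np.linspace(0, 20, 50)
        np.testing.assert_allclose(delay_kernel(tau, 1.0, 0.0, 1), np.exp(-tau))

    def test_total_mass_is_conversion_fraction(self):
        # quadrature oracle against the closed-form (f/(f+gamma))^p,
        # at the fitted FRQ-delay rates
        f, gamma = 0.1962, 0.0422
        for p in (1, 2, 3):
            mass, _ = quad(lambda t: delay_kernel(t, f, gamma, p), 0, np.inf)
            assert mass == pytest.approx((f / (f + gamma)) ** p, rel=1e-9)

    @pytest.mark.parametrize("bad", [dict(f=0.0), dict(f=-1.0), dict(p=0), dict(p=1.5)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(f=1.0, gamma=0.1, p=2)
        kwargs.update(bad)
        with pytest.raises(InvalidParameterError):
            delay_kernel(1.0, kwargs["f"], kwargs["gamma"], kwargs["p"])


def test_chain_matches_convolution_quadrature():
    """The delay chain's output for (near-)constant mRNA input equals the
    convolution of the gamma kernel with that input, to 1e-6 relative."""
    wt = wild_type()
    # freeze M_F ~ 1 nM: no production or degradation of mRNA to speak of
    params = replace(
        wt, a1=TINY, a2=TINY, a4=TINY, a5=TINY, a6=TINY, a7=TINY, d1=TINY, d3=TINY
    )
    p = params.chain_len_frq
    y0 = initial_state(params, 0.0)
    y0[0] = 1.0  # M_F
    traj = simulate(params, LightProtocol.DD(), (0.0, 60.0), initial=y0)
    chain_output = params.f1 * traj.component(f"F_{p}")
    for t in (5.0, 15.0, 30.0, 60.0):
        expected, _ = quad(
            lambda s: delay_kernel(t - s, params.f1, params.gamma1, p) * params.a3 * 1.0,
            0.0, t,
        )
        got = np.interp(t, traj.t, chain_output)
        assert got == pytest.approx(expected, rel=1e-6)


class TestOdeSystem:
    def test_zero_state_with_vanishing_basal_rates_gives_zero_derivative(self):
        params = replace(ClockParameters(), a4=TINY)
        rhs = build_ode_system(params)
        dy = rhs(initial_state(params, 0.0), 0.0, 0.0)
        np.testing.assert_allclose(dy, 0.0, atol=1e-10)

    def test_decoupled_chain_input_reduces_to_basal_translation(self, wt):
        # with a7 -> 0 the WC-1 chain is fed by a6 * M_W alone
        mut = wt.scaled(a7=1e-10)
        rhs = build_ode_system(mut)
        y = initial_state(mut, 0.5)
        dy = rhs(y, 0.0, 0.0)
        i_w1 = 3 + mut.chain_len_frq
        fg2 = mut.f2 + mut.gamma2
        assert dy[i_w1] == pytest.approx(mut.a6 * 0.5 - fg2 * 0.5, rel=1e-8)

    def test_dark_equations_have_no_light_source(self, wt):
        # with L = 0 the only inflow to WC-1* is r2-reversible loss; from
        # a zero-WC-1* state its derivative cannot be positive
        rhs = build_ode_system(wt)
        y = initial_state(wt, 1.0)
        y[-1] = 0.0  # P_L
        dy = rhs(y, 0.0, 0.0)
        assert dy[-1] <= 0.0


class TestSimulate:
    def test_zero_length_span_rejected(self, wt):
        with pytest.raises(ValueError):
            simulate(wt, LightProtocol.DD(), (0.0, 0.0))

    def test_decay_to_zero_without_production(self):
        params = replace(
            ClockParameters(),
            a1=TINY, a2=TINY, a3=TINY, a4=TINY, a5=TINY, a6=TINY, a7=TINY,
        )
        traj = simulate(params, LightProtocol.DD(), (0.0, 200.0))
        assert np.all(np.diff(traj.f_total) <= 1e-12)
        assert traj.f_total[-1] < 1e-3

    def test_states_non_negative_in_dd_and_ld(self, wt):
        for proto in (LightProtocol.DD(), LightProtocol.LD(12.0, 24.0)):
            traj = simulate(wt, proto, (0.0, 100.0))
            assert traj.states.min() >= 0.0

    def test_sustained_oscillation_with_constant_wc1_mrna_in_dd(self, wt):
        traj = simulate(
            wt, LightProtocol.DD(), (0.0, 100.0),
            initial=simulate(wt, LightProtocol.DD(), (0.0, 600.0), dense=False).final_state,
        )
        ft = traj.f_total
        assert ft.max() - ft.min() > 1.0  # healthy rhythm, nM scale
        mw = traj.component("M_W")
        assert (mw.max() - mw.min()) / mw.mean() < 0.01  # wc-1 mRNA flat in the dark
        assert traj.component("P_L").max() < 1e-6  # no light-activated WC-1*

    def test_tolerance_refinement_converges(self, wt):
        start = simulate(wt, LightProtocol.DD(), (0.0, 600.0), dense=False).final_state
        a = simulate(wt, LightProtocol.DD(), (0.0, 50.0), initial=start)
        b = simulate(wt, LightProtocol.DD(), (0.0, 50.0), initial=start,
                     rtol=5e-9, atol=5e-11)
        scale = a.f_total.max()
        assert np.max(np.abs(a.f_total - np.interp(a.t, b.t, b.f_total))) < 1e-3 * scale


class TestTotalFrq:
    def test_equals_pf_when_chain_empty(self, wt):
        y = initial_state(wt, 0.0)
        y[1 + wt.chain_len_frq] = 2.5  # P_F only
        traj = Trajectory(
            t=np.array([0.0]), states=y[:, None], params=wt, protocol=LightProtocol.DD()
        )
        assert total_frq(traj)[0] == pytest.approx(2.5)

    def test_dominates_active_frq_pointwise(self, wt):
        traj = simulate(wt, LightProtocol.DD(), (0.0, 60.0))
        assert np.all(total_frq(traj) >= traj.component("P_F") - 1e-12)


def test_net_frq_synthesis_identity(wt, dd_orbit):
    """Along any trajectory, dF_T/dt = a3 M_F - d2 P_F/(b6+P_F) - gamma1 * sum F_i:
    the chain construction makes the net-synthesis expression exact up to the
    intermediate-loss correction."""
    t, ft = dd_orbit.t, dd_orbit.f_total
    dft = np.gradient(ft, t)
    mf = dd_orbit.component("M_F")
    pf = dd_orbit.component("P_F")
    chain = sum(dd_orbit.component(f"F_{i+1}") for i in range(wt.chain_len_frq))
    rhs = wt.a3 * mf - wt.d2 * pf / (wt.b6 + pf) - wt.gamma1 * chain
    # interior points only; np.gradient is second order
    assert np.max(np.abs(dft - rhs)[5:-5]) < 2e-3
    # and the loss correction is genuinely small relative to synthesis
    assert np.max(wt.gamma1 * chain) < 0.5 * np.max(wt.a3 * mf)
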