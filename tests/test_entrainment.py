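import numpy as np
import pytest

from frqwc import (
    LightProtocol,
    entrained_orbit,
    free_running_orbit,
    phase_markers,
    scan_photoperiods,
    scan_tcycles,
    simulate,
    wild_type,
)
from frqwc.orbits import (
    ARRHYTHMIC,
    ENTRAINED,
    NOT_ENTRAINED,
    PeriodicOrbit,
    PhaseError,
    conidiation_phase,
)


def _synthetic_orbit(wt, ft_fn, period=24.0, n=480, status=ENTRAINED,
                     protocol=None):
    """Orbit whose total FRQ equals ft_fn(t); all other components flat."""
    from frqwc.model import initial_state, state_names

    t = np.linspace(0.0, period, n + 1)
    nvar = initial_state(wt).size
    states = np.full((nvar, t.size), 0.5)
    states[state_names(wt).index("P_F")] = ft_fn(t)
    for i in range(wt.chain_len_frq):
        states[1 + i] = 0.0
    return PeriodicOrbit(
        period=period, t=t, states=states, status=status,
        protocol=protocol or LightProtocol.LD(12.0, 24.0), params=wt,
    )


class TestFreeRunning:
    def test_period_matches_autocorrelation_oracle(self, wt, dd_orbit):
        # independent estimate: autocorrelation peak of a long F_T series
        traj = simulate(wt, LightProtocol.DD(), (0.0, 160.0),
                        initial=dd_orbit.states[:, 0])
        x = traj.f_total - traj.f_total.mean()
        ac = np.correlate(x, x, mode="full")[x.size - 1:]
        dt = traj.t[1] - traj.t[0]
        lo = int(10 / dt)
        k = lo + np.argmax(ac[lo: int(35 / dt)])
        # parabolic refinement of the autocorrelation peak
        num = ac[k - 1] - ac[k + 1]
        den = 2 * (ac[k - 1] - 2 * ac[k] + ac[k + 1])
        period_ac = (k + num / den) * dt
        assert abs(period_ac - dd_orbit.period) < 0.1

    def test_arrhythmic_when_positive_loop_removed(self, wt):
        orbit = free_running_orbit(wt.scaled(a7=0.02))
        assert orbit.status == ARRHYTHMIC

    def test_initial_condition_independence(self, wt, dd_orbit):
        rng = np.random.default_rng(11)
        other = free_running_orbit(wt, initial=rng.uniform(0.05, 2.0, dd_orbit.states.shape[0]))
        assert abs(other.period - dd_orbit.period) < 0.01

    def test_rejects_forced_protocol(self, wt):
        with pytest.raises(ValueError):
            free_running_orbit(wt, protocol=LightProtocol.LD(12.0, 24.0))


class TestEntrainment:
    def test_wt_locks_to_1212_with_cycle_period(self, ld12_orbit):
        assert ld12_orbit.status == ENTRAINED
        assert ld12_orbit.period == 24.0
        # cyclic continuity of the sampled cycle
        rel = np.abs(ld12_orbit.states[:, -1] - ld12_orbit.states[:, 0]) / (
            np.abs(ld12_orbit.states[:, 0]) + 1e-12
        )
        assert rel.max() < 1e-4

    def test_short_photoperiod_fails_to_entrain(self, wt):
        orbit = entrained_orbit(wt, LightProtocol.LD(4.0, 24.0))
        assert orbit.status == NOT_ENTRAINED

    def test_rejects_unforced_protocol(self, wt):
        with pytest.raises(ValueError):
            entrained_orbit(wt, LightProtocol.DD())


class TestPhaseMarkers:
    def test_cosine_crossing_quarter_period_after_peak(self, wt):
        # pure cosine with alpha = 0: threshold at the mean, reached a
        # quarter period past the peak
        T = 24.0
        orbit = _synthetic_orbit(wt, lambda t: 2 + np.cos(2 * np.pi * (t - 3) / T), T)
        phi = conidiation_phase(orbit, alpha=0.0)
        assert phi == pytest.approx(3 + T / 4, abs=0.02)

    @pytest.mark.parametrize("alpha", [0.0, 0.1, 0.15])
    def test_triangular_wave_closed_form(self, wt, alpha):
        # rise over [0, 6], fall over [6, 24]; crossing of the falling ramp
        # at level theta solves 1 - (t - 6)/18 = theta
        T = 24.0

        def tri(t):
            t = np.asarray(t) % T
            return np.where(t < 6, t / 6, 1 - (t - 6) / 18) + 1.0

        orbit = _synthetic_orbit(wt, tri, T)
        theta = 0.5 - alpha
        expected = 6 + 18 * (1 - theta)
        assert conidiation_phase(orbit, alpha) == pytest.approx(expected, abs=0.05)

    def test_conidiation_phase_at_midnight_in_1212(self, ld12_orbit):
        phi = conidiation_phase(ld12_orbit, alpha=0.15)
        assert phi == pytest.approx(18.0, abs=0.5)

    def test_phi_lies_on_falling_segment(self, ld12_orbit):
        mk = phase_markers(ld12_orbit)
        T = ld12_orbit.period
        assert (mk.phi_frq - mk.peaks["F_T"]) % T < (mk.troughs["F_T"] - mk.peaks["F_T"]) % T

    def test_arrhythmic_orbit_rejected(self, wt):
        orbit = _synthetic_orbit(wt, lambda t: np.ones_like(t), status=ARRHYTHMIC)
        with pytest.raises(PhaseError):
            phase_markers(orbit)

    def test_grid_refinement_invariance(self, wt):
        coarse = entrained_orbit(wt, LightProtocol.LD(12.0, 24.0), output_step=0.1)
        fine = entrained_orbit(wt, LightProtocol.LD(12.0, 24.0), output_step=0.05)
        assert abs(conidiation_phase(coarse) - conidiation_phase(fine)) < 0.05


class TestScans:
    def test_empty_photoperiod_list(self, wt):
        table = scan_photoperiods(wt, [])
        assert len(table) == 0
        assert "phi_FRQ" in table.columns

    def test_single_tcycle_row(self, wt):
        table = scan_tcycles(wt, [21.0])
        assert len(table) == 1
        assert table.iloc[0]["status"] == ENTRAINED

    def test_frq_mrna_peak_locked_to_dawn(self, wt):
        # light induces frq at dawn: the mRNA peak stays put as the
        # photoperiod moves dusk by 8 hours
        table = scan_photoperiods(wt, [8.0, 12.0, 16.0])
        peaks = table["frq_peak"].to_numpy()
        assert np.all(peaks < 2.0)
        assert peaks.max() - peaks.min() < 1.0

    def test_conidiation_tracks_dusk_in_tcycles(self, wt):
        # symmetric T-cycles: onset a roughly constant interval after dusk
        table = scan_tcycles(wt, np.arange(18.0, 24.1, 1.0))
        assert (table["status"] == ENTRAINED).all()
        rel = table["phi_FRQ_minus_dusk"].to_numpy()
        assert np.abs(rel - rel.mean()).max() <= 1.0
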