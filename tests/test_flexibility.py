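import numpy as np
import pytest

from frqwc import apply_principal_perturbation, phase_amplitude_decompose
from frqwc.flexibility import CHANNELS, FlexibilitySpectrum, ResponseMatrix, singular_spectrum
from tests.conftest import scaled_orbit, shifted_orbit, sinusoidal_orbit


def _matrix_from(arr, wt, ld12_orbit, n=24):
    """Wrap a raw array as a ResponseMatrix with dummy plumbing."""
    base = np.abs(np.sin(np.linspace(0, 2 * np.pi, n, endpoint=False))) + 0.5
    return ResponseMatrix(
        matrix=arr, sample_times=np.linspace(0, 24, n, endpoint=False),
        scales=np.ones(len(CHANNELS)), rel_step=0.01, baseline=ld12_orbit,
        baseline_samples=np.tile(base, (len(CHANNELS), 1)),
        params=wt, protocol=ld12_orbit.protocol,
    )


class TestSingularSpectrum:
    def test_rank_one_matrix(self, wt, ld12_orbit):
        rng = np.random.default_rng(0)
        n = 24
        u = rng.normal(size=len(CHANNELS) * n)
        v = rng.normal(size=33)
        sp = singular_spectrum(_matrix_from(np.outer(u, v), wt, ld12_orbit, n))
        assert sp.sigma[0] == pytest.approx(np.linalg.norm(u) * np.linalg.norm(v), rel=1e-10)
        assert sp.sigma[1] < 1e-10 * sp.sigma[0]

    def test_zero_matrix(self, wt, ld12_orbit):
        n = 24
        sp = singular_spectrum(_matrix_from(np.zeros((len(CHANNELS) * n, 33)), wt, ld12_orbit, n))
        assert np.all(sp.sigma == 0.0)

    def test_matches_eigendecomposition_oracle(self, wt, ld12_orbit):
        rng = np.random.default_rng(42)
        n = 24
        M = rng.normal(size=(len(CHANNELS) * n, 33))
        sp = singular_spectrum(_matrix_from(M, wt, ld12_orbit, n))
        eig = np.sort(np.linalg.eigvalsh(M.T @ M))[::-1]
        np.testing.assert_allclose(sp.sigma, np.sqrt(np.clip(eig, 0, None)), rtol=1e-8)

    def test_singular_vectors_orthonormal(self, wt, ld12_orbit):
        rng = np.random.default_rng(1)
        n = 24
        M = rng.normal(size=(len(CHANNELS) * n, 33))
        sp = singular_spectrum(_matrix_from(M, wt, ld12_orbit, n))
        np.testing.assert_allclose(sp.v.T @ sp.v, np.eye(33), atol=1e-8)
        np.testing.assert_allclose(sp.u.T @ sp.u, np.eye(33), atol=1e-8)

    def test_flexibility_sum_invariant_under_reordering(self, wt, ld12_orbit):
        rng = np.random.default_rng(5)
        n = 24
        M = rng.normal(size=(len(CHANNELS) * n, 33))
        sp = singular_spectrum(_matrix_from(M, wt, ld12_orbit, n))
        perm = _matrix_from(M[:, rng.permutation(33)][rng.permutation(len(CHANNELS) * n)],
                            wt, ld12_orbit, n)
        sp2 = singular_spectrum(perm)
        assert sp2.flexibility_sum == pytest.approx(sp.flexibility_sum, rel=1e-10)


class TestPrincipalPerturbation:
    def test_zero_magnitude_is_identity(self, wt):
        v = np.zeros(33)
        v[0] = 1.0
        assert apply_principal_perturbation(wt, v, 0.0) == wt

    def test_group_inverse(self, wt):
        rng = np.random.default_rng(9)
        v = rng.normal(size=33)
        v /= np.linalg.norm(v)
        there = apply_principal_perturbation(wt, v, 0.02)
        back = apply_principal_perturbation(there, -v, 0.02)
        np.testing.assert_allclose(back.kinetic_array(), wt.kinetic_array(), rtol=1e-12)

    def test_non_unit_direction_rejected(self, wt):
        with pytest.raises(ValueError):
            apply_principal_perturbation(wt, np.ones(33), 0.02)


class TestPhaseAmplitudeDecomposition:
    def test_uniform_phase_shift_recovered(self, wt):
        shift = 0.4
        base = sinusoidal_orbit(wt)
        dec = phase_amplitude_decompose(base, shifted_orbit(base, shift))
        for name, s in dec.s.items():
            assert s == pytest.approx(shift, rel=0.02), name
        for rho in dec.rho.values():
            assert abs(rho) < 0.02
        assert dec.delta_phi_frq == pytest.approx(shift, abs=0.05)

    def test_pure_amplitude_change_recovered(self, wt):
        rho = 0.05
        base = sinusoidal_orbit(wt)
        dec = phase_amplitude_decompose(base, scaled_orbit(base, rho))
        for name in dec.s:
            assert abs(dec.s[name]) < 0.05, name
            assert dec.rho[name] == pytest.approx(rho, rel=0.05), name

    def test_conidiation_phase_shift_tracked_on_model_orbit(self, ld12_orbit):
        # the threshold-crossing phase shifts exactly with the orbit even
        # where the linearised per-channel fit degrades at light transitions
        dec = phase_amplitude_decompose(ld12_orbit, shifted_orbit(ld12_orbit, 0.4))
        assert dec.delta_phi_frq == pytest.approx(0.4, abs=0.02)
        assert dec.s["F_T"] == pytest.approx(0.4, rel=0.05)

    def test_mismatched_periods_rejected(self, wt, ld12_orbit, dd_orbit):
        with pytest.raises(ValueError):
            phase_amplitude_decompose(ld12_orbit, dd_orbit)
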