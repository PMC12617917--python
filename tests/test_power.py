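"""Tests for exact power, noncentrality and the eigenvalue criterion."""

import numpy as np
import pytest

from rhythmdesign import (
    CosinorParams,
    Design,
    PowerSpec,
    SingularDesignError,
    b_inverse,
    design_matrix,
    equispaced_design,
    monte_carlo_power,
    multifreq_objective,
    noncentrality,
    power_fixed,
    power_from_lambda,
    worstcase_eigenvalue,
    worstcase_power_over_acrophase,
)
from rhythmdesign.power import HYPOTHESIS_MATRIX


def _direct_lambda(design, params):
    """Direct evaluation of the noncentrality via explicit matrix inversion."""
    X = design_matrix(design, params.frequency)
    H = HYPOTHESIS_MATRIX
    middle = np.linalg.inv(H @ np.linalg.inv(X.T @ X) @ H.T)
    beta = params.beta
    return beta @ H.T @ middle @ H @ beta / params.sigma**2


class TestNoncentrality:
    @pytest.mark.parametrize("phi", [0.0, 0.5, np.pi, 4.2])
    def test_equispaced_closed_form(self, phi, equi8):
        # equispaced designs give lambda = A^2 N / (2 sigma^2) at any acrophase
        p = CosinorParams(0.0, 1.0, phi, 1.0, 1.0)
        assert noncentrality(equi8, p) == pytest.approx(4.0, abs=1e-10)

    def test_zero_amplitude(self, random_design):
        p = CosinorParams(2.0, 0.0, 1.0, 1.0, 1.0)
        assert noncentrality(random_design, p) == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_matrix_oracle(self, random_design):
        p = CosinorParams(1.0, 2.0, 0.8, 1.7, 1.3)
        assert noncentrality(random_design, p) == pytest.approx(
            _direct_lambda(random_design, p), abs=1e-8
        )

    def test_singular_design_raises(self, equi8):
        p = CosinorParams(0.0, 1.0, 0.0, 4.0, 1.0)  # Nyquist of N=8
        with pytest.raises(SingularDesignError):
            noncentrality(equi8, p)


class TestPowerFixed:
    def test_null_power_equals_alpha(self, equi8):
        p = CosinorParams(0.0, 0.0, 0.0, 1.0, 1.0)
        for alpha in (0.01, 0.05, 0.2):
            assert power_fixed(equi8, p, PowerSpec(alpha=alpha)) == pytest.approx(
                alpha, abs=1e-12
            )

    def test_acrophase_invariance_equispaced(self, equi8):
        spec = PowerSpec(alpha=0.05)
        powers = [
            power_fixed(equi8, CosinorParams(0.0, 2.5, phi, 1.0, 1.0), spec)
            for phi in np.linspace(0, 2 * np.pi, 256, endpoint=False)
        ]
        assert max(powers) - min(powers) < 1e-10

    def test_strictly_increasing_in_amplitude(self, random_design):
        spec = PowerSpec()
        amps = np.linspace(0.1, 4.0, 20)
        powers = [
            power_fixed(random_design, CosinorParams(0, a, 0.3, 1.0, 1.0), spec)
            for a in amps
        ]
        assert np.all(np.diff(powers) > 0)

    def test_scale_invariance(self, random_design):
        # multiplying A and sigma by the same constant leaves power unchanged
        spec = PowerSpec()
        p1 = CosinorParams(0, 1.5, 0.9, 1.0, 1.0)
        p2 = CosinorParams(0, 1.5 * 7.3, 0.9, 1.0, 7.3)
        assert power_fixed(random_design, p1, spec) == pytest.approx(
            power_fixed(random_design, p2, spec), abs=1e-10
        )

    def test_matches_monte_carlo(self, random_design):
        params = CosinorParams(0.5, 2.0, 1.2, 1.0, 1.0)
        spec = PowerSpec()
        est, se = monte_carlo_power(random_design, params, spec,
                                    n_sim=20_000, seed=11)
        assert abs(power_fixed(random_design, params, spec) - est) < 3 * se


class TestBInverse:
    def test_equispaced_is_half_n_identity(self, equi8):
        assert np.allclose(b_inverse(equi8, 1.0), 4.0 * np.eye(2), atol=1e-9)

    def test_degenerate_design_rank_deficient(self):
        d = Design([0.3, 0.3, 0.3, 0.3], allow_duplicates=True)
        M = b_inverse(d, 1.0)
        assert np.linalg.eigvalsh(M)[0] == pytest.approx(0.0, abs=1e-12)

    def test_schur_identity_oracle(self, random_design):
        # equals the explicit inverse of H (X'X)^-1 H' when well conditioned
        X = design_matrix(random_design, 1.3)
        H = HYPOTHESIS_MATRIX
        oracle = np.linalg.inv(H @ np.linalg.inv(X.T @ X) @ H.T)
        assert np.allclose(b_inverse(random_design, 1.3), oracle, atol=1e-8)

    def test_always_psd(self, rng):
        for _ in range(50):
            t = np.sort(rng.random(6))
            M = b_inverse(Design(t, allow_duplicates=True), float(rng.integers(1, 5)))
            assert np.linalg.eigvalsh(M)[0] >= -1e-9


class TestWorstcaseEigenvalue:
    def test_equispaced_attains_bound(self, equi8):
        assert worstcase_eigenvalue(equi8, 1.0) == pytest.approx(4.0, abs=1e-9)

    def test_zero_at_nyquist(self, equi8):
        assert worstcase_eigenvalue(equi8, 4.0) == pytest.approx(0.0, abs=1e-9)

    def test_universal_bound_random_designs(self, rng):
        # xi_min <= N/2 for any design (Elfving-type bound)
        for n in (8, 12):
            for _ in range(200):
                t = np.sort(rng.random(n))
                f = float(rng.integers(1, n))
                assert worstcase_eigenvalue(Design(t, allow_duplicates=True), f) \
                    <= n / 2 + 1e-9

    def test_rotation_and_reflection_invariance(self, rng, random_design):
        base = worstcase_eigenvalue(random_design, 2.0)
        for shift in rng.random(5):
            assert worstcase_eigenvalue(random_design.rotated(shift), 2.0) == \
                pytest.approx(base, abs=1e-9)
        assert worstcase_eigenvalue(random_design.reversed(), 2.0) == \
            pytest.approx(base, abs=1e-9)


class TestMultifreqObjective:
    def test_single_frequency_reduces(self, random_design):
        rep = multifreq_objective(random_design, [1.0])
        assert rep.j_value == pytest.approx(
            worstcase_eigenvalue(random_design, 1.0))

    def test_decomposes_over_frequencies(self, random_design):
        rep = multifreq_objective(random_design, [1.0, 2.0, 3.0])
        singles = [worstcase_eigenvalue(random_design, f) for f in (1.0, 2.0, 3.0)]
        assert rep.j_value == pytest.approx(min(singles), abs=1e-12)
        assert rep.j_value == min(rep.per_frequency_xi_min.values())

    def test_conversion_identity(self, equi8):
        spec = PowerSpec(alpha=0.05, amplitude=2.0, sigma=0.5)
        rep = multifreq_objective(equi8, [1.0], spec=spec)
        assert rep.worst_case_lambda == pytest.approx(16 * rep.j_value)
        assert rep.worst_case_power == pytest.approx(
            power_from_lambda(rep.worst_case_lambda, 8, 0.05))

    def test_bound_respected(self, equi8):
        rep = multifreq_objective(equi8, [1.0, 2.0, 3.0])
        assert rep.j_value <= 8 / 2 + 1e-9


class TestAcrophaseScan:
    def test_equispaced_flat(self, equi8):
        spec = PowerSpec(amplitude=2.5)
        _, _, delta = worstcase_power_over_acrophase(equi8, 1.0, spec, 256)
        assert delta == pytest.approx(0.0, abs=1e-8)

    def test_min_bounded_by_eigen_route(self, random_design):
        spec = PowerSpec(amplitude=2.0)
        lo, hi, _ = worstcase_power_over_acrophase(random_design, 1.0, spec, 512)
        exact_worst = power_from_lambda(
            spec.snr2 * worstcase_eigenvalue(random_design, 1.0),
            random_design.n, spec.alpha)
        assert lo >= exact_worst - 1e-6
        assert lo == pytest.approx(exact_worst, abs=1e-4)
        assert hi >= lo


class TestMonteCarloPower:
    def test_size_under_null(self, equi8):
        p = CosinorParams(0.0, 0.0, 0.0, 1.0, 1.0)
        est, se = monte_carlo_power(equi8, p, PowerSpec(), n_sim=20_000, seed=3)
        assert abs(est - 0.05) < 3 * max(se, np.sqrt(0.05 * 0.95 / 20_000))

    def test_matches_closed_form_equispaced(self, equi8):
        p = CosinorParams(0.0, 2.5, 0.6, 1.0, 1.0)
        spec = PowerSpec()
        est, se = monte_carlo_power(equi8, p, spec, n_sim=20_000, seed=4)
        assert abs(est - power_fixed(equi8, p, spec)) < 3 * se

    def test_seed_reproducible(self, equi8):
        p = CosinorParams(0.0, 1.0, 0.0, 1.0, 1.0)
        a = monte_carlo_power(equi8, p, PowerSpec(), n_sim=500, seed=9)
        b = monte_carlo_power(equi8, p, PowerSpec(), n_sim=500, seed=9)
        assert a == b
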