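"""Vector fields, Jacobian and second additive compound."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from seirvax import (
    AbsoluteState,
    Parameters,
    ProportionState,
    integrate,
    integrate_full,
    jacobian_reduced,
    rhs_full,
    rhs_reduced,
    sample_random_params,
    second_additive_compound,
)
from seirvax.exceptions import ConfigurationError, InvalidInputError

from conftest import interior_simplex_points


class TestParametersValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidInputError):
            Parameters(b=-1e-5, alpha=0.0, beta=0.1, gamma=0.1, epsilon=0.1, q=1.0, sigma_a=0.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            Parameters(b=np.nan, alpha=0.0, beta=0.1, gamma=0.1, epsilon=0.1, q=1.0, sigma_a=0.0)

    def test_sigma_a_product_consistency(self):
        with pytest.raises(ConfigurationError):
            Parameters(b=0.1, alpha=0.0, beta=0.1, gamma=0.1, epsilon=0.1, q=1.0,
                       sigma_a=0.3, sigma=0.5, a=0.4)
        # consistent product is accepted
        Parameters(b=0.1, alpha=0.0, beta=0.1, gamma=0.1, epsilon=0.1, q=1.0,
                   sigma_a=0.2, sigma=0.5, a=0.4)

    def test_sigma_outside_unit_interval_rejected(self):
        with pytest.raises(InvalidInputError):
            Parameters(b=0.1, alpha=0.0, beta=0.1, gamma=0.1, epsilon=0.1, q=1.0,
                       sigma_a=0.1, sigma=1.5)


class TestRhsReduced:
    def test_vanishes_at_disease_free_equilibrium(self):
        for seed in range(5):
            p = sample_random_params(seed)
            state = (p.b / (p.sigma_a + p.b), 0.0, 0.0)
            assert np.abs(rhs_reduced(state, p)).max() < 1e-15

    def test_pure_susceptible_population(self, ref_params):
        # s = 1, e = i = 0: only vaccination drains, s' = b - (sigma_a + b) = -sigma_a
        ds = rhs_reduced((1.0, 0.0, 0.0), ref_params)
        assert ds == pytest.approx([-ref_params.sigma_a, 0.0, 0.0], abs=1e-18)

    def test_near_reported_endemic_point(self, ref_params):
        # the reported endemic coordinates, rounded as printed, are a near-fixed point
        ds = rhs_reduced((0.0910, 0.00018673, 0.0019), ref_params)
        assert np.abs(ds).max() < 1e-6

    def test_rejects_nonfinite_state(self, ref_params):
        with pytest.raises(InvalidInputError):
            rhs_reduced((np.inf, 0.0, 0.0), ref_params)


class TestRhsFull:
    def test_no_infection_without_exposed_or_infective(self, ref_params_absolute):
        p = ref_params_absolute
        n = 1000.0
        dS, dE, dI, dR = rhs_full(AbsoluteState(S=n, E=0, I=0, R=0), p)
        sa = p.sigma * p.a
        assert dS == pytest.approx(p.b * n - (sa + p.d) * n, rel=1e-12)
        assert dE == 0.0
        assert dI == 0.0
        assert dR == pytest.approx(sa * n, rel=1e-12)

    def test_beta_zero_turns_transmission_off(self, ref_params_absolute):
        p = ref_params_absolute.replace(beta=0.0)
        st = AbsoluteState(S=500.0, E=30.0, I=20.0, R=450.0)
        dE = rhs_full(st, p)[1]
        assert dE == pytest.approx(-(p.d + p.epsilon) * st.E, rel=1e-12)

    def test_derivative_sum_matches_population_growth(self, ref_params_absolute, rng):
        p = ref_params_absolute
        for _ in range(20):
            y = rng.uniform(1.0, 100.0, 4)
            st = AbsoluteState(*y)
            total = rhs_full(st, p).sum()
            assert total == pytest.approx((p.b - p.d) * st.N - p.alpha * st.I, rel=1e-9, abs=1e-12)

    def test_requires_sigma_and_a(self, ref_params):
        with pytest.raises(ConfigurationError):
            rhs_full(AbsoluteState(S=1.0, E=0.0, I=0.0, R=0.0), ref_params)

    def test_full_and_reduced_trajectories_agree(self, ref_params_absolute):
        # with d = b the proportions of the absolute system obey the reduced one
        p = ref_params_absolute
        init = AbsoluteState(S=900.0, E=50.0, I=50.0, R=0.0)
        tf = integrate_full(p, init, 1000.0, n_samples=200, rtol=1e-10, atol=1e-12)
        tr = integrate(p, init.proportions(), 1000.0, n_samples=200, rtol=1e-10, atol=1e-12)
        dev = max(
            np.abs(tf.s - tr.s).max(),
            np.abs(tf.e - tr.e).max(),
            np.abs(tf.i - tr.i).max(),
        )
        assert dev < 1e-6


class TestJacobian:
    def test_matches_finite_differences(self, rng):
        h = 1e-7
        for seed in range(4):
            p = sample_random_params(100 + seed)
            for y in interior_simplex_points(rng, 5):
                J = jacobian_reduced(y, p)
                for k in range(3):
                    step = np.zeros(3)
                    step[k] = h
                    col = (rhs_reduced(y + step, p) - rhs_reduced(y - step, p)) / (2 * h)
                    assert np.abs(J[:, k] - col).max() < 1e-6

    def test_structure_at_disease_free_point(self, ref_params):
        p = ref_params
        J = jacobian_reduced((p.b / (p.sigma_a + p.b), 0.0, 0.0), p)
        assert J[2, 1] == p.epsilon
        assert J[2, 0] == 0.0

    def test_disease_free_point_unstable_for_benchmark(self, ref_params):
        p = ref_params
        lam = np.linalg.eigvals(jacobian_reduced((p.b / (p.sigma_a + p.b), 0.0, 0.0), p))
        assert lam.real.max() > 0


class TestSecondAdditiveCompound:
    def test_identity_doubles(self):
        assert np.array_equal(second_additive_compound(np.eye(3)), 2 * np.eye(3))

    @given(st.tuples(*[st.floats(-10, 10) for _ in range(3)]))
    @settings(max_examples=25, derandomize=True)
    def test_diagonal_gives_pairwise_sums(self, d):
        x, y, z = d
        M = second_additive_compound(np.diag([x, y, z]))
        assert np.allclose(M, np.diag([x + y, x + z, y + z]))

    def test_eigenvalues_are_pairwise_sums(self, rng):
        for _ in range(50):
            J = rng.normal(size=(3, 3))
            lam = np.linalg.eigvals(J)
            expected = sorted(
                [lam[0] + lam[1], lam[0] + lam[2], lam[1] + lam[2]],
                key=lambda z: (z.real, z.imag),
            )
            got = sorted(np.linalg.eigvals(second_additive_compound(J)),
                         key=lambda z: (z.real, z.imag))
            assert np.abs(np.array(got) - np.array(expected)).max() < 1e-8

    def test_wrong_shape_rejected(self):
        with pytest.raises(InvalidInputError):
            second_additive_compound(np.eye(2))


class TestSimplexInvariance:
    def test_trajectories_stay_in_simplex(self, rng):
        # forward invariance of T under the reduced flow
        for seed in range(20):
            p = sample_random_params(200 + seed)
            for y0 in interior_simplex_points(rng, 5):
                traj = integrate(p, y0, 500.0, n_samples=120)
                assert traj.states.min() >= -1e-9
                assert traj.states.sum(axis=1).max() <= 1.0 + 1e-9

    def test_susceptible_relaxation_without_transmission(self, ref_params):
        # beta = alpha = 0 decouples s, which relaxes to b/(sigma_a + b)
        p = ref_params.replace(beta=0.0, alpha=0.0)
        s_inf = p.b / (p.sigma_a + p.b)
        t_end = 20.0 / (p.sigma_a + p.b)
        traj = integrate(p, (0.5, 0.2, 0.1), t_end, n_samples=200)
        assert abs(traj.s[-1] - s_inf) < 1e-6
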