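import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from helpers import binom_se, mc_p_infected_given_m, sir_final_size, sir_theta
from ssfir import (
    DegreeDistribution,
    EdgeProbabilities,
    EpidemicParams,
    edge_probabilities,
    outbreak_condition,
    p_infected_given_k,
    p_infected_given_m,
    prevalence,
    solve_theta,
    solve_threshold_beta,
    transmissibility,
)
from ssfir.errors import BracketingError, ParameterError
from ssfir.theory import theta_map

rates = st.floats(0.01, 5.0)
gammas = st.floats(0.0, 1.0)


def _poisson_pk(dist):
    return {int(k): float(p) for k, p in zip(dist.support, dist.probs)}


class TestEpidemicParams:
    def test_validation(self):
        with pytest.raises(ParameterError):
            EpidemicParams(-0.1)
        with pytest.raises(ParameterError):
            EpidemicParams(0.1, beta_f=-1)
        with pytest.raises(ParameterError):
            EpidemicParams(0.1, gamma=1.5)
        with pytest.raises(ParameterError):
            EpidemicParams(0.1, mu=0.0)

    def test_gamma_one_admitted(self):
        EpidemicParams(0.1, 1.0, 1.0, 1.0)  # validation limit, no raise

    def test_beta_f_may_exceed_one(self):
        assert EpidemicParams(0.2, beta_f=50.0).beta_f == 50.0


class TestEdgeProbabilities:
    def test_direct_substitution(self):
        ep = edge_probabilities(EpidemicParams(1.0, 1.0, 0.5, 1.0))
        assert ep.t1 == pytest.approx(1 / 3)
        assert ep.t2 == pytest.approx(1 / 3)
        assert ep.t3 == pytest.approx(1 / 3)

    def test_classical_limit(self):
        ep = edge_probabilities(EpidemicParams(0.4, 0.0, 0.3, 1.0))
        assert ep.t2 == 0.0
        assert ep.t1 == pytest.approx(0.4 / 1.4)

    def test_gamma_zero(self):
        assert edge_probabilities(EpidemicParams(0.4, 1.0, 0.0, 1.0)).t3 == 0.0

    def test_competition_completeness(self):
        p = EpidemicParams(0.7, 2.3, 0.4, 1.3)
        ep = edge_probabilities(p)
        assert ep.t1 + ep.t2 + p.mu / (p.beta + p.beta_f + p.mu) == pytest.approx(1.0)

    def test_zero_rates_valid(self):
        ep = edge_probabilities(EpidemicParams(0.0, 0.0, 0.5, 1.0))
        assert ep.t1 == ep.t2 == ep.t3 == 0.0

    @settings(max_examples=50, deadline=None)
    @given(beta=rates, beta_f=st.floats(0.0, 5.0), gamma=gammas, mu=rates)
    def test_bounds_property(self, beta, beta_f, gamma, mu):
        ep = edge_probabilities(EpidemicParams(beta, beta_f, gamma, mu))
        assert 0.0 <= ep.t1 <= 1.0
        assert 0.0 <= ep.t2 <= 1.0
        assert 0.0 <= ep.t3 <= 1.0
        assert ep.t1 + ep.t2 <= 1.0 + 1e-12


class TestPInfectedGivenM:
    def test_zero_neighbors(self):
        ep = edge_probabilities(EpidemicParams(0.3, 0.8, 0.4, 1.0))
        assert p_infected_given_m(0, ep) == 0.0

    def test_classical_collapse(self):
        ep = edge_probabilities(EpidemicParams(0.3, 0.0, 0.4, 1.0))
        for m in range(6):
            assert p_infected_given_m(m, ep) == pytest.approx(1 - (1 - ep.t1) ** m)

    def test_against_monte_carlo_oracle(self, rng):
        ep = edge_probabilities(EpidemicParams(0.2, 0.3, 0.3, 1.0))
        n_rep = 10**6
        hat = mc_p_infected_given_m(3, ep.t1, ep.t2, ep.t3, n_rep, rng)
        p = p_infected_given_m(3, ep)
        assert abs(hat - p) < 3 * binom_se(p, n_rep)

    def test_degenerate_denominator_continuity(self):
        # T1+T2 = T3 exactly at gamma=1, beta_f=0; approach it from beta_f>0
        exact = p_infected_given_m(4, edge_probabilities(EpidemicParams(0.2, 0.0, 1.0, 1.0)))
        near = p_infected_given_m(4, edge_probabilities(EpidemicParams(0.2, 1e-7, 1.0, 1.0)))
        assert math.isfinite(exact)
        assert exact == pytest.approx(near, abs=1e-6)
        # and the degenerate value matches the classical form (t2=0 there)
        t1 = 0.2 / 1.2
        assert exact == pytest.approx(1 - (1 - t1) ** 4, abs=1e-12)

    @settings(max_examples=60, deadline=None)
    @given(beta=rates, beta_f=st.floats(0.0, 5.0), gamma=gammas, mu=rates)
    def test_monotone_in_m_property(self, beta, beta_f, gamma, mu):
        ep = edge_probabilities(EpidemicParams(beta, beta_f, gamma, mu))
        vals = [p_infected_given_m(m, ep) for m in range(8)]
        assert vals[0] == 0.0
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))


class TestPInfectedGivenK:
    def test_theta_zero(self):
        ep = edge_probabilities(EpidemicParams(0.3, 0.8, 0.4, 1.0))
        for k in range(6):
            assert p_infected_given_k(k, 0.0, ep) == 0.0

    def test_single_neighbor_enumeration(self):
        # infect directly (t1) or alert then infect (t2*t3)
        ep = edge_probabilities(EpidemicParams(0.3, 0.8, 0.4, 1.0))
        assert p_infected_given_k(1, 1.0, ep) == pytest.approx(ep.t1 + ep.t2 * ep.t3, abs=1e-14)

    def test_binomial_sum_k6(self):
        ep = edge_probabilities(EpidemicParams(0.25, 0.6, 0.35, 1.2))
        theta = 0.4
        brute = sum(
            binom.pmf(m, 6, theta) * p_infected_given_m(m, ep) for m in range(7)
        )
        assert p_infected_given_k(6, theta, ep) == pytest.approx(brute, abs=1e-12)

    @pytest.mark.parametrize("k", [1, 5, 17, 50])
    def test_binomial_sum_large_k(self, rng, k):
        for _ in range(5):
            beta, beta_f, mu = rng.uniform(0.05, 2.0, 3)
            gamma = rng.uniform(0.0, 1.0)
            ep = edge_probabilities(EpidemicParams(beta, beta_f, gamma, mu))
            theta = rng.uniform(0.0, 1.0)
            brute = sum(
                binom.pmf(m, k, theta) * p_infected_given_m(m, ep) for m in range(k + 1)
            )
            assert p_infected_given_k(k, theta, ep) == pytest.approx(brute, abs=1e-12)


class TestThetaMap:
    def test_fixes_origin(self, poisson10):
        ep = edge_probabilities(EpidemicParams(0.3, 0.8, 0.4, 1.0))
        assert theta_map(0.0, poisson10, ep) == 0.0

    @settings(max_examples=25, deadline=None)
    @given(beta=rates, beta_f=st.floats(0.0, 5.0), gamma=gammas)
    def test_monotone_nondecreasing_property(self, beta, beta_f, gamma):
        dist = DegreeDistribution.poisson(6.0)
        ep = edge_probabilities(EpidemicParams(beta, beta_f, gamma, 1.0))
        thetas = np.linspace(0, 1, 21)
        vals = [theta_map(t, dist, ep) for t in thetas]
        assert all(0.0 <= v <= 1.0 for v in vals)
        assert all(b >= a - 1e-10 for a, b in zip(vals, vals[1:]))


class TestSolveTheta:
    def test_subcritical_returns_zero(self, poisson10):
        res = solve_theta(poisson10, EpidemicParams(0.05, 0.0, 0.1, 1.0))
        assert res.theta == 0.0
        assert res.converged

    def test_classical_reduction(self, poisson10):
        res = solve_theta(poisson10, EpidemicParams(0.2, 0.0, 0.1, 1.0))
        oracle = sir_theta(_poisson_pk(poisson10), 0.2 / 1.2)
        assert res.theta == pytest.approx(oracle, abs=1e-9)

    def test_residual_contract(self, poisson10):
        for params in [
            EpidemicParams(0.3, 1.0, 0.2, 1.0),
            EpidemicParams(0.5, 4.0, 0.7, 0.8),
            EpidemicParams(1.2, 0.3, 0.0, 2.0),
        ]:
            res = solve_theta(poisson10, params, tol=1e-12)
            ep = edge_probabilities(params)
            assert abs(res.theta - theta_map(res.theta, poisson10, ep)) <= 1e-10
            assert res.converged

    def test_theta_positive_iff_outbreak(self, poisson10):
        beta_c = solve_threshold_beta(poisson10, 1.0, 0.1, 1.0)
        for off in (-0.02, -0.005, 0.005, 0.02):
            params = EpidemicParams(beta_c + off, 1.0, 0.1, 1.0)
            res = solve_theta(poisson10, params)
            if off < 0:
                assert res.theta == 0.0
            else:
                assert res.theta > 1e-6


class TestPrevalence:
    def test_subcritical(self, poisson10):
        res = prevalence(poisson10, EpidemicParams(0.05, 0.0, 0.1, 1.0))
        assert res.prevalence == pytest.approx(0.0, abs=1e-12)

    def test_classical_reduction(self, poisson10):
        res = prevalence(poisson10, EpidemicParams(0.25, 0.0, 0.5, 1.0))
        oracle = sir_final_size(_poisson_pk(poisson10), 0.25 / 1.25)
        assert res.prevalence == pytest.approx(oracle, abs=1e-9)

    def test_equals_degree_sum(self, poisson10):
        params = EpidemicParams(0.35, 1.2, 0.25, 1.0)
        res = prevalence(poisson10, params)
        ep = edge_probabilities(params)
        sum_form = float(
            np.dot(poisson10.probs, p_infected_given_k(poisson10.support, res.theta, ep))
        )
        assert res.prevalence == pytest.approx(sum_form, abs=1e-10)

    def test_monotone_in_gamma(self, poisson10):
        # lowering the discount factor cannot increase the final size
        rs = [
            prevalence(poisson10, EpidemicParams(0.3, 1.0, g, 1.0)).prevalence
            for g in (0.8, 0.5, 0.3, 0.1, 0.0)
        ]
        assert all(b <= a + 1e-10 for a, b in zip(rs, rs[1:]))


class TestOutbreakCondition:
    def test_beta_zero_false(self, poisson10):
        ok, margin = outbreak_condition(poisson10, EpidemicParams(0.0, 2.0, 0.5, 1.0))
        assert not ok
        assert margin < 0

    def test_gamma_one_reduces_to_sir(self, poisson10):
        # at gamma=1 the condition loses all beta_f dependence
        margins = [
            outbreak_condition(poisson10, EpidemicParams(0.2, bf, 1.0, 1.0))[1]
            for bf in (0.0, 1.0, 4.0)
        ]
        assert margins[0] == pytest.approx(margins[1], abs=1e-12)
        assert margins[0] == pytest.approx(margins[2], abs=1e-12)
        # and equals the classical SIR margin beta/(beta+mu) * g1'(1) - 1
        assert margins[0] == pytest.approx(0.2 / 1.2 * 10.0 - 1.0, abs=1e-9)

    def test_two_formula_cross_check(self, rng, poisson10):
        # transmissibility form vs the rate-ratio closed form
        g1p = poisson10.g1_prime_at_1()
        for _ in range(25):
            beta, beta_f, mu = rng.uniform(0.05, 3.0, 3)
            gamma = rng.uniform(0.0, 1.0)
            params = EpidemicParams(beta, beta_f, gamma, mu)
            lhs = (
                beta
                * (mu + gamma * beta + gamma * beta_f)
                / ((mu + gamma * beta) * (mu + beta + beta_f))
            )
            assert transmissibility(params) == pytest.approx(lhs, abs=1e-12)
            _, margin = outbreak_condition(poisson10, params)
            assert margin == pytest.approx(lhs * g1p - 1.0, abs=1e-12)

    def test_all_degrees_at_most_one(self):
        dist = DegreeDistribution(np.array([0, 1]), np.array([0.5, 0.5]))
        ok, margin = outbreak_condition(dist, EpidemicParams(5.0, 0.0, 0.0, 1.0))
        assert not ok
        assert margin == float("-inf")


class TestSolveThresholdBeta:
    def test_classical_poisson(self, poisson10):
        beta_c = solve_threshold_beta(poisson10, 0.0, 0.37, 1.0)
        assert beta_c == pytest.approx(1.0 / 9.0, rel=1e-9)

    def test_gamma_zero_closed_form(self, poisson10):
        beta_c = solve_threshold_beta(poisson10, 0.5, 0.0, 1.0)
        assert beta_c == pytest.approx((1.0 + 0.5) / 9.0, rel=1e-9)

    @pytest.mark.parametrize("beta_f", [0.0, 1.0, 4.0])
    def test_gamma_one_ignores_beta_f(self, poisson10, beta_f):
        beta_c = solve_threshold_beta(poisson10, beta_f, 1.0, 1.0)
        assert beta_c == pytest.approx(1.0 / 9.0, rel=1e-8)

    def test_monotone_in_beta_f_and_gamma(self, poisson10):
        by_bf = [solve_threshold_beta(poisson10, bf, 0.3, 1.0) for bf in np.linspace(0, 4, 9)]
        assert all(b >= a - 1e-12 for a, b in zip(by_bf, by_bf[1:]))
        by_g = [solve_threshold_beta(poisson10, 2.0, g, 1.0) for g in np.linspace(0, 1, 9)]
        assert all(b <= a + 1e-12 for a, b in zip(by_g, by_g[1:]))

    def test_bracketing_error_reports_endpoints(self):
        dist = DegreeDistribution(np.array([2]), np.array([1.0]))  # g1'(1) = 1
        with pytest.raises(BracketingError) as exc:
            solve_threshold_beta(dist, 0.0, 0.0, 1.0)
        assert exc.value.f_lo < 0
        assert exc.value.f_hi < 0


class TestEdgeProbabilitiesType:
    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ParameterError):
            EdgeProbabilities(0.7, 0.7, 0.1)
        with pytest.raises(ParameterError):
            EdgeProbabilities(-0.1, 0.2, 0.1)
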