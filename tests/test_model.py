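"""Likelihood terms and Gibbs sweeps checked against independent oracles."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.special import erf

from svbayes import (CallMatrix, LatentState, McmcConfig, ModelParams,
                     PriorConfig, ToolMeta, censored_score_loglik, exact_pep,
                     full_loglik, position_log_odds, run_mcmc, subset_logprob)
from svbayes.model import (gibbs_step_o, gibbs_step_omega, gibbs_step_pi,
                           gibbs_step_scoreparams, gibbs_step_z)
from svbayes.simulate import make_case, simulate


def _phi(x):  # standard normal CDF via erf, independent of scipy.stats.norm
    return 0.5 * (1.0 + erf(x / math.sqrt(2.0)))


class TestCensoredScoreLoglik:
    def test_interior_density_at_mean(self):
        assert censored_score_loglik(1.3, 1.3, 1.0) == pytest.approx(
            -0.5 * math.log(2 * math.pi))

    def test_lower_bound_atom_symmetry(self):
        assert censored_score_loglik(0.0, 0.0, 1.0, a=0.0) == pytest.approx(
            math.log(0.5))

    def test_upper_bound_atom_mass(self):
        # s at b = 0 with mu = 2: upper-tail mass 1 - Phi(-2)
        expected = math.log(1.0 - _phi(-2.0))
        got = censored_score_loglik(0.0, 2.0, 1.0, b=0.0)
        assert got == pytest.approx(expected, abs=1e-10)
        assert got == pytest.approx(-0.02301, abs=1e-5)

    def test_out_of_bounds_is_domain_error(self):
        with pytest.raises(ValueError):
            censored_score_loglik(-1.0, 0.0, 1.0, a=0.0)
        with pytest.raises(ValueError):
            censored_score_loglik(0.0, 0.0, -1.0)

    @pytest.mark.parametrize("mu,sigma,a,b", [
        (0.0, 1.0, -1.0, 1.5), (2.0, 0.5, 0.0, np.inf),
        (-2.0, 1.0, -np.inf, 0.0), (1.0, 2.0, -3.0, 4.0),
    ])
    def test_total_mass_is_one(self, mu, sigma, a, b):
        """Interior density plus the two boundary atoms integrates to 1."""
        lo = a if np.isfinite(a) else mu - 12 * sigma
        hi = b if np.isfinite(b) else mu + 12 * sigma
        interior, _ = integrate.quad(
            lambda s: math.exp(-0.5 * ((s - mu) / sigma) ** 2)
            / (sigma * math.sqrt(2 * math.pi)), lo, hi)
        mass = interior
        if np.isfinite(a):
            mass += math.exp(censored_score_loglik(a, mu, sigma, a=a, b=b))
        if np.isfinite(b):
            mass += math.exp(censored_score_loglik(b, mu, sigma, a=a, b=b))
        assert mass == pytest.approx(1.0, abs=1e-8)


class TestSubsetLogprob:
    def test_two_tools_equal_weights(self):
        assert subset_logprob([1, 0], 1, [0.5, 0.5]) == pytest.approx(math.log(0.5))

    def test_hand_enumerated_pair(self):
        # weights (.5,.3,.2), set {0,1}: .5*(.3/.5) + .3*(.5/.7)
        expected = 0.5 * (0.3 / 0.5) + 0.3 * (0.5 / 0.7)
        got = subset_logprob([1, 1, 0], 2, [0.5, 0.3, 0.2])
        assert got == pytest.approx(math.log(expected))
        assert math.exp(got) == pytest.approx(0.51429, abs=1e-5)

    @pytest.mark.parametrize("J", [2, 4, 6])
    def test_full_set_is_certain(self, J):
        rng = np.random.default_rng(J)
        w = rng.dirichlet(np.ones(J))
        assert subset_logprob(np.ones(J), J, w) == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_subset_probabilities_sum_to_one(self, k):
        import itertools

        rng = np.random.default_rng(k)
        w = rng.dirichlet(np.ones(4))
        total = 0.0
        for sel in itertools.combinations(range(4), k):
            y = np.zeros(4)
            y[list(sel)] = 1
            total += math.exp(subset_logprob(y, k, w))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_count_mismatch_is_error(self):
        with pytest.raises(ValueError):
            subset_logprob([1, 1, 0], 1, [0.5, 0.3, 0.2])


def _noscore_cm(x_values):
    """A score-free call matrix with the given support counts."""
    x = np.asarray(x_values, dtype=np.int64)
    n, J = len(x), 5
    Y = np.zeros((n, J), dtype=np.int8)
    for i, k in enumerate(x):
        Y[i, :k] = 1
    import pandas as pd

    pos = pd.DataFrame({"chrom": "c", "pos": np.arange(n) + 1,
                        "end": np.arange(n) + 1, "svtype": "DEL", "svlen": -100})
    return CallMatrix(Y=Y, X=x, S=np.full((n, J), np.nan),
                      tools=[ToolMeta(f"T{j}", has_score=False) for j in range(J)],
                      positions=pos)


CASE1 = dict(pi=0.7,
             omega1=np.array([0.05, 0.10, 0.15, 0.25, 0.45]),
             omega0=np.array([0.40, 0.25, 0.15, 0.12, 0.08]))


def _case1_noscore_params(v=None):
    J = 5
    nan = np.full(J, np.nan)
    return ModelParams(pi=CASE1["pi"], omega1=CASE1["omega1"],
                       omega0=CASE1["omega0"], mu1=nan, mu0=nan,
                       sigma1=nan, sigma0=nan, a=np.full(J, -np.inf),
                       b=np.full(J, np.inf), v=v)


class TestPositionLogOddsAndPep:
    def test_case1_printed_parameter_arithmetic(self):
        cm = _noscore_cm([5, 1])
        odds = position_log_odds(cm, _case1_noscore_params())
        assert odds[0] == pytest.approx(math.log(0.7 * 0.45 / (0.3 * 0.08)))
        assert math.exp(odds[0]) == pytest.approx(13.125)
        assert odds[1] == pytest.approx(math.log(0.035 / 0.12))
        pep = exact_pep(cm, _case1_noscore_params())
        assert pep[0] == pytest.approx(1 / (1 + 13.125), abs=1e-6)
        assert pep[0] == pytest.approx(0.0708, abs=2e-4)
        assert pep[1] == pytest.approx(0.12 / 0.155, abs=1e-6)
        assert pep[1] == pytest.approx(0.7742, abs=1e-4)

    def test_mirror_symmetry_at_even_prior(self):
        """With pi = 1/2 and omega0 the mirror of omega1 (and no scores), the
        posterior for x = k is the complement of that for x = J+1-k."""
        cm = _noscore_cm([1, 2, 3, 4, 5])
        w = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        p = _case1_noscore_params()
        p.pi, p.omega1, p.omega0 = 0.5, w, w[::-1].copy()
        pep = exact_pep(cm, p)
        assert np.allclose(pep + pep[::-1], 1.0, atol=1e-12)

    def test_degenerate_prior_forces_zero_pep(self):
        cm = _noscore_cm([1, 3, 5])
        p = _case1_noscore_params()
        p.pi = 1.0
        assert np.all(exact_pep(cm, p) == 0.0)

    def test_pep_strictly_decreasing_in_support_count(self):
        cm = _noscore_cm([1, 2, 3, 4, 5])
        pep = exact_pep(cm, _case1_noscore_params())
        assert np.all(np.diff(pep) < 0)

    def test_pep_invariant_to_inclusion_weights(self, case1_small):
        cm, truth = case1_small
        p1 = truth.params_true
        v2 = np.full((5, 5), 0.1)
        v2[0, :] = 0.6  # a very unbalanced alternative weight matrix
        p2 = ModelParams(pi=p1.pi, omega1=p1.omega1, omega0=p1.omega0,
                         mu1=p1.mu1, mu0=p1.mu0, sigma1=p1.sigma1,
                         sigma0=p1.sigma0, a=p1.a, b=p1.b, v=v2)
        assert np.array_equal(exact_pep(cm, p1), exact_pep(cm, p2))
        # ... while the full likelihood does depend on v
        assert full_loglik(cm, p1) != pytest.approx(full_loglik(cm, p2))


class TestGibbsSteps:
    def test_z_degenerate_prior(self):
        cm = _noscore_cm([1, 2, 5])
        p = _case1_noscore_params()
        p.pi = 1.0
        state = LatentState(z=np.zeros(3, np.int8), o=np.full((3, 5), np.nan))
        z = gibbs_step_z(cm, p, state, np.random.default_rng(0))
        assert z.tolist() == [1, 1, 1]

    def test_z_marginal_matches_exact_pep(self):
        n = 100_000  # identical positions -> n independent draws in one sweep
        cm = _noscore_cm([3] * n)
        p = _case1_noscore_params()
        target = 1.0 - exact_pep(cm, p)[0]
        state = LatentState(z=np.zeros(n, np.int8), o=np.full((n, 5), np.nan))
        draws = gibbs_step_z(cm, p, state, np.random.default_rng(123))
        se = math.sqrt(target * (1 - target) / n)
        assert abs(draws.mean() - target) < 3 * se

    def test_z_deterministic_under_fixed_seed(self, case1_small):
        cm, truth = case1_small
        out = []
        for _ in range(2):
            rng = np.random.default_rng(7)
            state = LatentState(z=np.zeros(cm.n, np.int8),
                                o=np.array(cm.S, dtype=float))
            out.append(gibbs_step_z(cm, truth.params_true, state, rng).copy())
        assert np.array_equal(out[0], out[1])

    def test_o_copies_interior_observations(self, case1_small):
        cm, truth = case1_small
        state = LatentState(z=np.array(truth.z_true),
                            o=np.array(cm.S, dtype=float))
        gibbs_step_o(cm, truth.params_true, state, np.random.default_rng(1))
        j = 2  # unbounded scoring tool: everything interior
        have = ~np.isnan(cm.S[:, j])
        assert np.array_equal(state.o[have, j], cm.S[have, j])

    def test_o_tail_draws_match_quadrature_mean(self):
        """Lower-tail imputation mean vs numeric integration of the density."""
        mu, sigma, a = -2.0, 1.0, 0.0
        tail_mass, _ = integrate.quad(
            lambda x: math.exp(-0.5 * ((x - mu) / sigma) ** 2)
            / (sigma * math.sqrt(2 * math.pi)), -12, a)
        mean_num, _ = integrate.quad(
            lambda x: x * math.exp(-0.5 * ((x - mu) / sigma) ** 2)
            / (sigma * math.sqrt(2 * math.pi)), -12, a)
        expected = mean_num / tail_mass

        n = 100_000
        cm = _scored_cm(s_at_bound=a, n=n)
        p = _scored_params(mu1=mu, mu0=mu - 1.0)
        state = LatentState(z=np.ones(n, np.int8), o=np.array(cm.S))
        gibbs_step_o(cm, p, state, np.random.default_rng(99))
        draws = state.o[:, 0]
        assert np.all(draws <= a)
        se = draws.std() / math.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_o_upper_tail_support(self):
        cm = _scored_cm(s_at_bound=0.0, n=5, upper=True)
        p = _scored_params(mu1=2.0, mu0=-2.0)
        state = LatentState(z=np.ones(5, np.int8), o=np.array(cm.S))
        gibbs_step_o(cm, p, state, np.random.default_rng(3))
        assert np.all(state.o[:, 0] >= 0.0)

    def test_scoreparams_conjugate_posterior_mean(self):
        cm = _scored_cm_interior([1.9, 2.1, -2.2, -1.8])
        z = np.array([1, 1, 0, 0], dtype=np.int8)
        prior = PriorConfig()
        rng = np.random.default_rng(5)
        mus = []
        for _ in range(4000):
            p = _scored_params(mu1=0.5, mu0=-0.5)
            state = LatentState(z=z, o=np.array(cm.S))
            gibbs_step_scoreparams(cm, p, state, prior, rng)
            mus.append(p.mu1[0])
        mus = np.array(mus)
        se = mus.std() / math.sqrt(len(mus))
        assert abs(mus.mean() - 2.0) < max(3 * se, 0.05)

    def test_scoreparams_empty_component_prior_fallback(self):
        cm = _scored_cm_interior([1.9, 2.1])
        state = LatentState(z=np.ones(2, np.int8), o=np.array(cm.S))
        p = _scored_params(mu1=0.5, mu0=-0.5)
        gibbs_step_scoreparams(cm, p, state, PriorConfig(),
                               np.random.default_rng(2))
        assert np.isfinite(p.mu0[0]) and p.sigma0[0] > 0

    def test_scoreparams_constraint_violation_keeps_current(self):
        # component data force mu1 < mu0, so every proposal is rejected
        cm = _scored_cm_interior([-5.0, -5.1, 5.0, 5.1])
        z = np.array([1, 1, 0, 0], dtype=np.int8)
        p = _scored_params(mu1=1.0, mu0=-1.0)
        state = LatentState(z=z, o=np.array(cm.S))
        gibbs_step_scoreparams(cm, p, state, PriorConfig(),
                               np.random.default_rng(8))
        assert p.mu1[0] == 1.0 and p.mu0[0] == -1.0

    def test_omega_draws_sum_to_one_and_respect_order(self):
        cm = _noscore_cm([2] * 10 + [3] * 20 + [4] * 40 + [5] * 80)
        state = LatentState(z=np.ones(cm.n, np.int8),
                            o=np.full((cm.n, 5), np.nan))
        p = _case1_noscore_params()
        rng = np.random.default_rng(0)
        for _ in range(50):
            w1, w0 = gibbs_step_omega(cm, p, state, PriorConfig(), rng)
            assert w1.sum() == pytest.approx(1.0, abs=1e-12)
            assert w0.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(np.diff(w1) > 0) and np.all(np.diff(w0) < 0)

    def test_omega_matches_rejection_sampling_oracle(self):
        """Stationary mean of the omega1 chain vs a brute-force rejection
        sampler from the order-truncated Dirichlet."""
        counts = np.array([0, 10, 20, 40, 80], dtype=float)
        rng = np.random.default_rng(42)
        accepted = []
        while len(accepted) < 3000:
            w = rng.dirichlet(1.0 + counts)
            if np.all(np.diff(w) > 0):
                accepted.append(w)
        oracle = np.mean(accepted, axis=0)

        cm = _noscore_cm([2] * 10 + [3] * 20 + [4] * 40 + [5] * 80)
        state = LatentState(z=np.ones(cm.n, np.int8),
                            o=np.full((cm.n, 5), np.nan))
        p = _case1_noscore_params()
        chain = []
        rng2 = np.random.default_rng(7)
        for _ in range(3000):
            gibbs_step_omega(cm, p, state, PriorConfig(), rng2)
            chain.append(p.omega1.copy())
        chain = np.array(chain)
        assert np.allclose(chain.mean(axis=0), oracle, atol=0.01)

    def test_pi_beta_moments(self):
        state = LatentState(z=np.ones(10, np.int8), o=np.empty((10, 0)))
        rng = np.random.default_rng(3)
        draws = np.array([gibbs_step_pi(state, PriorConfig(), rng)
                          for _ in range(100_000)])
        # Beta(11, 1): mean 11/12
        mean, var = 11 / 12, (11 * 1) / (12 ** 2 * 13)
        assert abs(draws.mean() - mean) < 3 * math.sqrt(var / draws.size)


def _scored_cm(s_at_bound, n, upper=False):
    import pandas as pd

    a = np.inf if upper else s_at_bound
    tools = [ToolMeta("T1", has_score=True,
                      a=-np.inf if upper else s_at_bound,
                      b=s_at_bound if upper else np.inf)]
    Y = np.ones((n, 1), np.int8)
    S = np.full((n, 1), float(s_at_bound))
    pos = pd.DataFrame({"chrom": "c", "pos": np.arange(n) + 1,
                        "end": np.arange(n) + 1, "svtype": "DEL", "svlen": -100})
    return CallMatrix(Y=Y, X=np.ones(n, np.int64), S=S, tools=tools,
                      positions=pos)


def _scored_cm_interior(values):
    import pandas as pd

    n = len(values)
    tools = [ToolMeta("T1", has_score=True)]
    pos = pd.DataFrame({"chrom": "c", "pos": np.arange(n) + 1,
                        "end": np.arange(n) + 1, "svtype": "DEL", "svlen": -100})
    return CallMatrix(Y=np.ones((n, 1), np.int8), X=np.ones(n, np.int64),
                      S=np.array(values, dtype=float)[:, None], tools=tools,
                      positions=pos)


def _scored_params(mu1, mu0, J=1, a=None, b=None):
    return ModelParams(pi=0.5, omega1=np.array([1.0]), omega0=np.array([1.0]),
                       mu1=np.array([mu1]), mu0=np.array([mu0]),
                       sigma1=np.array([1.0]), sigma0=np.array([1.0]),
                       a=np.array([-np.inf if a is None else a]),
                       b=np.array([np.inf if b is None else b]))


class TestRunMcmc:
    def test_fixed_seed_is_reproducible(self, case1_small):
        cm, _ = case1_small
        mcfg = McmcConfig(iterations=300, burn_in=100, n_chains=2, seed=5)
        s1 = run_mcmc(cm, mcfg=mcfg)
        s2 = run_mcmc(cm, mcfg=mcfg)
        assert np.array_equal(s1.pep, s2.pep)
        assert np.array_equal(s1.chains["pi"], s2.chains["pi"])

    def test_clamped_parameters_match_exact_pep(self, case1_small):
        """With parameters fixed at truth, the MCMC PEP is a binomial mean of
        independent z draws around the closed-form PEP."""
        cm, truth = case1_small
        mcfg = McmcConfig(iterations=2500, burn_in=500, n_chains=1, seed=9)
        s = run_mcmc(cm, mcfg=mcfg, init_params=truth.params_true,
                     sample_params=False)
        expected = exact_pep(cm, truth.params_true)
        m = 2000  # retained draws
        se = np.sqrt(np.maximum(expected * (1 - expected), 1e-12) / m)
        assert np.all(np.abs(s.pep - expected) < 4 * se + 5e-3)

    def test_empty_matrix_gives_empty_summary(self):
        cm = _noscore_cm([])
        s = run_mcmc(cm, mcfg=McmcConfig(iterations=10, burn_in=2, n_chains=1))
        assert s.pep.size == 0 and s.param_means is None

    def test_diagnostics_present_and_peps_bounded(self, case1_small):
        cm, _ = case1_small
        s = run_mcmc(cm, mcfg=McmcConfig(iterations=400, burn_in=100,
                                         n_chains=2, seed=2))
        assert np.all((s.pep >= 0) & (s.pep <= 1))
        assert "pi" in s.diagnostics and "rhat" in s.diagnostics["pi"]
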