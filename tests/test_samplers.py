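"""Sampler correctness: acceptance formulas, uniformity, and agreement of the
stochastic-likelihood samplers with quadrature oracles on the toy model."""

import math

import numpy as np
import pytest
from scipy.stats import chisquare, kstest, ks_2samp, norm

from popdesign import (PTConfig, swap_acceptance, indicator_acceptance,
                       adaptive_mh_individual, naive_population_mcmc,
                       slmcmc, pt_slmcmc, toy_problem, wtc_problem, CRNBlock)
from popdesign.objectives import default_crn
from popdesign.diagnostics import posterior_viability_check
from popdesign.samplers import find_viable_individual

EPS, R, SIGMA = 0.5, 1.0, 0.4
LN10 = math.log(10.0)


def _oracle_problem():
    """1-D toy population space: only the log10 median of k is sampled."""
    return toy_problem(epsilon=EPS, r=R, mode="mean-only", fixed_sigma=SIGMA,
                       d_variable=False)


def _viability_prob(x):
    """P(s <= eps) under gamma = (median 10**x, sigma): closed form, since
    log(k/d) ~ Normal(x*ln10, sigma^2)."""
    mu = x * LN10
    return (norm.cdf((math.log(R + EPS) - mu) / SIGMA)
            - norm.cdf((math.log(R - EPS) - mu) / SIGMA))


class TestAcceptanceFormulas:
    def test_swap_acceptance_is_indicator_product(self):
        assert swap_acceptance([1, 1, 1]) == 1.0
        assert swap_acceptance([1, 0, 1]) == 0.0
        assert swap_acceptance([]) == 1.0  # empty product, equal kappas

    def test_symmetric_proposal_reduces_to_indicator_product(self):
        # detailed-balance smoke test on the formula itself
        assert indicator_acceptance([1, 1, 1], [1, 1, 1]) == 1.0
        assert indicator_acceptance([1, 0], [1, 1]) == 0.0
        assert indicator_acceptance([1, 1], [1, 1], q_ratio=0.5) == 0.5

    def test_equal_kappa_ladder_always_swaps(self):
        prob = _oracle_problem()
        chain = pt_slmcmc(prob, PTConfig((3, 3)), 400, seed=1)
        assert chain.meta["swap_rate"] == 1.0

    def test_pt_config_validation(self):
        with pytest.raises(ValueError):
            PTConfig((3,))
        with pytest.raises(ValueError):
            PTConfig((5, 3))
        assert PTConfig((3, 7)).inverse_temperatures == (3 / 7, 1.0)


class TestUniformityWithoutConstraint:
    def test_infinite_threshold_samples_box_uniformly(self):
        """With eps = inf the indicator is always one and the individual
        sampler must be uniform on the box (KS test per dimension)."""
        prob = toy_problem(epsilon=1e12, r=1.0)
        chain = adaptive_mh_individual(prob, 24_000, seed=3)
        lo, hi = prob.layout.sampling_bounds()
        thinned = chain.samples[12_000::40]
        for j in range(2):
            u = (thinned[:, j] - lo[j]) / (hi[j] - lo[j])
            assert kstest(u, "uniform").pvalue > 0.01

    def test_individual_marginal_matches_analytic_interval(self):
        """Viable set {(k, d): |k/d - r| <= eps} in log10 coordinates."""
        prob = toy_problem(epsilon=EPS, r=R)
        chain = adaptive_mh_individual(prob, 6_000, seed=4)
        logk, logd = chain.samples[3_000:, 0], chain.samples[3_000:, 1]
        ratio = 10.0 ** (logk - logd)
        assert np.all(np.abs(ratio - R) <= EPS + 1e-9)
        # both boundary regions are actually reached
        assert ratio.min() < R - 0.8 * EPS
        assert ratio.max() > R + 0.8 * EPS


@pytest.mark.parametrize("sampler,kappa", [
    ("slmcmc", 1),
    ("slmcmc", 3),
    ("pt", (1, 3)),
])
def test_marginal_matches_quadrature_oracle(sampler, kappa):
    """The retained gamma-marginal is proportional to P_gamma^kappa(s <= eps);
    compare a histogram with bin masses computed by quadrature (chi-square)."""
    prob = _oracle_problem()
    n = 40_000
    if sampler == "slmcmc":
        chain = slmcmc(prob, kappa, n, seed=11)
        k_eff = kappa
    else:
        chain = pt_slmcmc(prob, PTConfig(kappa), n, seed=11)
        k_eff = kappa[-1]
    x = chain.samples[n // 2::25, 0]

    edges = np.linspace(-1.0, 1.0, 15)
    grid = np.linspace(-1.0, 1.0, 4001)
    dens = _viability_prob(grid) ** k_eff
    mass = np.array([np.trapezoid(dens[(grid >= a) & (grid <= b)],
                                  grid[(grid >= a) & (grid <= b)])
                     for a, b in zip(edges[:-1], edges[1:])])
    mass /= mass.sum()
    obs, _ = np.histogram(x, bins=edges)
    keep = mass * x.size >= 5
    obs_k = np.append(obs[keep], obs[~keep].sum())
    exp_k = np.append(mass[keep], mass[~keep].sum()) * x.size
    stat, p = chisquare(obs_k, exp_k)
    assert p > 0.01, f"chi2={stat:.1f}, p={p:.4f}"


def test_swap_preserves_invariant_distribution():
    """PT with ladder (1, 3) and plain kappa = 3 must sample the same
    retained marginal (two-sample KS on thinned draws)."""
    prob = _oracle_problem()
    a = slmcmc(prob, 3, 30_000, seed=21).samples[15_000::30, 0]
    b = pt_slmcmc(prob, PTConfig((1, 3)), 30_000, seed=22).samples[15_000::30, 0]
    assert ks_2samp(a, b).pvalue > 0.01


class TestNaiveSampler:
    def test_accepted_region_matches_analytic_boundary(self):
        """Every retained gamma satisfies the analytic c(gamma) <= delta up to
        the CRN Monte-Carlo error."""
        prob = toy_problem(epsilon=EPS, r=R, d_variable=False)
        crn = default_crn(prob, 300, 31)
        chain = naive_population_mcmc(prob, 3_000, seed=31, crn=crn)
        mc_err = 3.0 * math.sqrt(0.2 * 0.8 / 300)
        for x, sig_log10 in chain.samples[1_500:]:
            sigma = 10.0 ** sig_log10
            mu = x * LN10
            c_true = 1.0 - (norm.cdf((math.log(R + EPS) - mu) / sigma)
                            - norm.cdf((math.log(R - EPS) - mu) / sigma))
            assert c_true <= prob.thresholds.delta + mc_err

    def test_output_passes_own_viability_check(self):
        """Under the shared CRN the a-posteriori check rejects nothing."""
        prob = toy_problem(epsilon=EPS, r=R, d_variable=False)
        seed = 33
        chain = naive_population_mcmc(prob, 2_000, seed=seed)
        rejected, costs, viable, _ = posterior_viability_check(
            chain.burn_in(0.5), prob, n_check=200, N=300, seed=seed)
        assert rejected == 0.0
        assert np.all(costs <= prob.thresholds.delta)

    def test_delta_one_accepts_every_in_bounds_proposal(self):
        prob = toy_problem(epsilon=EPS, r=R, d_variable=False, delta=0.999999)
        chain = naive_population_mcmc(prob, 1_500, seed=35, adapt=False)
        lo, hi = prob.pop_layout.sampling_bounds()
        assert np.all(chain.samples >= lo) and np.all(chain.samples <= hi)
        # with the narrow unadapted proposal essentially every step is
        # in bounds, hence accepted
        assert chain.acceptance_rate > 0.9


class TestChainContracts:
    def test_states_always_viable_indicator(self):
        prob = _oracle_problem()
        chain = slmcmc(prob, 2, 500, seed=41)
        assert chain.indicator_state.all()

    def test_csv_round_trip(self, tmp_path):
        prob = _oracle_problem()
        chain = slmcmc(prob, 1, 300, seed=42)
        path = tmp_path / "chain.csv"
        chain.to_csv(path)
        from popdesign import Chain
        back = Chain.from_csv(path)
        np.testing.assert_array_equal(back.samples, chain.samples)
        np.testing.assert_array_equal(back.accepted, chain.accepted)
        assert back.names == chain.names

    def test_viable_start_is_viable(self):
        prob = wtc_problem()
        rng = np.random.default_rng(43)
        x = find_viable_individual(prob, rng)
        assert prob.cost_at_vector(x) <= prob.thresholds.epsilon

    def test_error_when_no_viable_start_exists(self):
        prob = toy_problem(epsilon=1e-9, r=123.456)  # r far outside k/d range
        with pytest.raises(RuntimeError):
            find_viable_individual(prob, np.random.default_rng(0), budget=512)


def test_wtc_repression_strengths_not_both_weak():
    """In the WTC viable space, the two repression coefficients cannot both
    take high values: some repression is required for a linear response."""
    prob = wtc_problem()
    chain = adaptive_mh_individual(prob, 4_000, seed=51)
    s = chain.samples[2_000:]
    names = list(chain.names)
    th_tet = s[:, names.index("theta_Tet")]
    th_tup = s[:, names.index("theta_Tup")]
    both_high = (th_tet > 4.0) & (th_tup > 0.9)  # log10, near upper bounds
    assert both_high.mean() == 0.0
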