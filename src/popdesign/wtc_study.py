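"""End-to-end study computations for the WTC case study.

Convenience wrappers that assemble the design problem, run the relevant
computation and reduce it to the headline quantity: the population cost of
the fitted circuit under a given coefficient of variation, the best
achievable individual cost for an extended input dynamic range, and the
admissible-variability ceiling / a-posteriori rejection rate of an SLMCMC
run.  Used by the acceptance script and the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .circuits import WTC_FIXED, WTC_FITTED, WTC_VARIABLE
from .objectives import CRNBlock, DesignProblem, wtc_problem
from .population import PopulationParams, cv_to_sigma, sigma_to_cv
from .samplers import Chain, slmcmc, pt_slmcmc, PTConfig
from .diagnostics import posterior_viability_check

__all__ = [
    "fitted_population",
    "population_cost_at_cv",
    "min_extended_idr_cost",
    "SLMCMCStudy",
    "slmcmc_study",
]


def fitted_population(cv: float = 0.10, cov_mode: str = "scalar") -> PopulationParams:
    """Population gamma with medians at the fitted WTC values and common CV."""
    medians = {**WTC_FIXED, **WTC_FITTED}
    mean_log = np.log([medians[name] for name in WTC_VARIABLE])
    sigma = float(cv_to_sigma(cv))
    cov = sigma ** 2 if cov_mode == "scalar" else np.full(6, sigma ** 2)
    return PopulationParams(
        variable=WTC_VARIABLE, mean_log=mean_log, cov_mode=cov_mode, cov=cov,
        shared={"theta_Tet": WTC_FITTED["theta_Tet"],
                "theta_Tup": WTC_FITTED["theta_Tup"],
                "n_Tet": WTC_FIXED["n"], "n_Tup": WTC_FIXED["n"],
                "K_a": WTC_FIXED["K_a"]},
    )


def population_cost_at_cv(cv: float = 0.10, n_cells: int = 1000, seed: int = 0,
                          epsilon: float = 6.0) -> float:
    """Fraction of cells with individual cost >= epsilon in the fitted population.

    Monte-Carlo estimate over ``n_cells`` cells whose six variable parameters
    are log-normal with the given common CV around the fitted medians.
    """
    problem = wtc_problem(epsilon=epsilon)
    gamma = fitted_population(cv)
    crn = CRNBlock.from_seed(n_cells, len(WTC_VARIABLE), seed)
    return problem.population_cost(gamma, crn)


def min_extended_idr_cost(max_idr: float = 600.0, n_starts: int = 50,
                          seed: int = 0, slope: float = 0.4,
                          dose_step: float = 25.0) -> float:
    """Best achievable individual cost for an extended reference line.

    Multi-start bounded minimization (L-BFGS-B in log10 coordinates) of the
    RMS cost over the four sampled WTC parameters against the slope-0.4
    reference extended to ``max_idr``; returns the smallest cost found (nM).
    """
    problem = wtc_problem(max_idr=max_idr, slope=slope, dose_step=dose_step)
    lo, hi = problem.layout.sampling_bounds()
    rng = np.random.default_rng(seed)
    best = math.inf
    for _ in range(n_starts):
        x0 = rng.uniform(lo, hi)
        res = minimize(problem.cost_at_vector, x0, method="L-BFGS-B",
                       bounds=list(zip(lo, hi)))
        best = min(best, float(res.fun))
    return best


@dataclass
class SLMCMCStudy:
    """Reduced outcome of one SLMCMC population-design run."""

    chain: Chain
    rejected_fraction: float
    checked_costs: np.ndarray
    viable_cv_percent: np.ndarray
    cv_p99_percent: float


def slmcmc_study(epsilon: float = 6.0, n_samples: int = 20_000, seed: int = 0,
                 kappa=3, delta: float = 0.2, n_check: int = 600,
                 N: int = 300, cov_mode: str = "scalar") -> SLMCMCStudy:
    """Run SLMCMC (or PT-SLMCMC for a kappa sequence) and post-process.

    Removes the first half as burn-in, evaluates the CRN population-cost
    estimator on ``n_check`` regularly thinned samples, and reports the
    rejected fraction and the 99th percentile of the common CV among the
    checked samples that pass the hard criterion.
    """
    problem = wtc_problem(epsilon=epsilon, delta=delta, cov_mode=cov_mode)
    kappas = tuple(np.atleast_1d(kappa).astype(int))
    if len(kappas) == 1:
        chain = slmcmc(problem, int(kappas[0]), n_samples, seed)
    else:
        chain = pt_slmcmc(problem, PTConfig(kappas), n_samples, seed)
    post = chain.burn_in(0.5)
    rejected, costs, viable, idx = posterior_viability_check(
        post, problem, n_check=n_check, N=N, seed=seed)
    sigma_col = list(post.names).index("sigma")
    sig = post.samples[idx, sigma_col][viable]
    if problem.pop_layout.sigma_log10:
        sig = 10.0 ** sig
    cv = sigma_to_cv(sig) * 100.0
    p99 = float(np.percentile(cv, 99)) if cv.size else math.nan
    return SLMCMCStudy(chain=chain, rejected_fraction=rejected,
                       checked_costs=costs, viable_cv_percent=cv,
                       cv_p99_percent=p99)
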