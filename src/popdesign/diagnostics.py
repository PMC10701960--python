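"""Convergence and efficiency diagnostics for the population samplers.

Effective sample size uses Geyer's initial-positive-sequence truncation of
the autocovariance sum (an autocovariance-based estimator of the same family
as the classic spectral estimators); the Gelman-Rubin statistic is the
classic potential scale reduction factor.  The a-posteriori viability check
re-evaluates the CRN population-cost estimator on a thinned subsample of an
SLMCMC chain, since that sampler only targets viable regions softly.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .objectives import CRNBlock, DesignProblem, default_crn
from .samplers import Chain

__all__ = [
    "effective_sample_size",
    "min_ess",
    "gelman_rubin",
    "posterior_viability_check",
    "EfficiencyReport",
    "efficiency_report",
]


def _ess_1d(x: np.ndarray) -> float:
    """Geyer initial-positive-sequence ESS for one dimension.

    Sums autocovariances in adjacent pairs while the pair-sum stays positive;
    n/ess = 1 + 2*sum(rho_k).  An antithetic chain can legitimately report
    ess > n under this convention.
    """
    n = x.size
    x = x - x.mean()
    var = x @ x / n
    if var == 0.0:
        warnings.warn("constant chain dimension; ESS set to chain length")
        return float(n)
    # FFT autocovariance
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[:n].real / n
    rho = acov / acov[0]
    # Pair sums Gamma_m = rho_{2m} + rho_{2m+1}; keep while positive.
    # Integrated autocorrelation time tau = 2*sum_m Gamma_m - 1.
    total = 0.0
    for m in range(0, (n - 1) // 2 + 1):
        g = rho[2 * m] + (rho[2 * m + 1] if 2 * m + 1 < n else 0.0)
        if g < 0.0:
            break
        total += g
    tau = max(2.0 * total - 1.0, 1e-12)
    return float(n / tau)


def effective_sample_size(chain) -> dict:
    """Per-dimension ESS for a Chain (or (n, d) array); chains >= 100 long."""
    if isinstance(chain, Chain):
        samples, names = chain.samples, chain.names
    else:
        samples = np.atleast_2d(np.asarray(chain, dtype=float))
        if samples.shape[0] == 1 and samples.size > 1:
            samples = samples.T
        names = tuple(f"dim{i}" for i in range(samples.shape[1]))
    if samples.shape[0] < 100:
        raise ValueError("need a chain of length >= 100 for a stable ESS estimate")
    return {name: _ess_1d(samples[:, j]) for j, name in enumerate(names)}


def min_ess(chain) -> float:
    """Minimum ESS across dimensions (the Table-style efficiency statistic)."""
    return min(effective_sample_size(chain).values())


def gelman_rubin(chains) -> dict:
    """Classic potential scale reduction factor R-hat per dimension.

    ``chains`` is a sequence of >= 2 equal-length Chains or (n, d) arrays.
    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B/n the between-chain variance of the means.
    """
    arrs = []
    names = None
    for c in chains:
        if isinstance(c, Chain):
            arrs.append(c.samples)
            names = names or c.names
        else:
            a = np.atleast_2d(np.asarray(c, dtype=float))
            arrs.append(a if a.shape[0] > 1 else a.T)
    if len(arrs) < 2:
        raise ValueError("Gelman-Rubin requires at least two chains")
    n = arrs[0].shape[0]
    if any(a.shape != arrs[0].shape for a in arrs):
        raise ValueError("chains must have equal length and dimension")
    stacked = np.stack(arrs)              # (m, n, d)
    means = stacked.mean(axis=1)          # (m, d)
    W = stacked.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B_over_n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W == 0.0, 1.0, rhat)
    if names is None:
        names = tuple(f"dim{i}" for i in range(stacked.shape[2]))
    return {name: float(rhat[j]) for j, name in enumerate(names)}


def converged(chains, threshold: float = 1.1) -> bool:
    """Convergence flag: all R-hat below ``threshold``."""
    return all(v < threshold for v in gelman_rubin(chains).values())


def posterior_viability_check(chain: Chain, problem: DesignProblem,
                              n_check: int = 600, N: int = 300, seed=0,
                              crn: CRNBlock | None = None,
                              selection: str = "thin"):
    """A-posteriori hard-criterion check for SLMCMC output.

    Evaluates the CRN population-cost estimator on a subsample of the chain
    (burn-in already removed), flags samples with c_hat > delta, and returns
    ``(rejected_fraction, costs, viable_mask, indices)``.  ``selection`` is
    "thin" (regular thinning; reproducible default) or "random".
    """
    n = len(chain)
    if n == 0:
        raise ValueError("empty chain")
    n_check = min(n_check, n)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    if selection == "thin":
        idx = np.unique(np.linspace(0, n - 1, n_check).round().astype(int))
    elif selection == "random":
        idx = np.sort(rng.choice(n, size=n_check, replace=False))
    else:
        raise ValueError(f"unknown selection {selection!r}")
    if crn is None:
        crn = default_crn(problem, N, seed)
    pop = problem.pop_layout
    delta = problem.thresholds.delta
    costs = np.array([problem.population_cost(pop.gamma_from_vector(chain.samples[i]), crn)
                      for i in idx])
    viable = costs <= delta
    return float(np.mean(~viable)), costs, viable, idx


@dataclass
class EfficiencyReport:
    """Sampling-efficiency summary (times in seconds)."""

    sampler: str
    n_samples: int
    run_time_s: float
    checking_time_s: float
    rejected_fraction: float
    min_ess: float
    time_per_sample: float
    time_per_min_ess: float
    sampling_efficiency: float

    def to_dict(self) -> dict:
        return asdict(self)


def efficiency_report(chain: Chain, problem: DesignProblem, *,
                      n_check: int = 600, N: int = 300, seed=0,
                      burn_in_frac: float = 0.5,
                      check: bool = True) -> EfficiencyReport:
    """Table-style efficiency report for one sampler run.

    Ratios involving time sum run time and checking time; sampling efficiency
    is minESS divided by the number of retained (post burn-in) samples.
    """
    post = chain.burn_in(burn_in_frac)
    run_time = float(chain.meta.get("run_time_s", np.nan))
    t0 = time.perf_counter()
    if check and chain.meta.get("sampler") in ("slmcmc", "pt_slmcmc"):
        rejected, *_ = posterior_viability_check(post, problem, n_check=n_check,
                                                 N=N, seed=seed)
    else:
        rejected = 0.0
    checking_time = time.perf_counter() - t0 if check else 0.0
    m = min_ess(post)
    n_kept = len(post)
    total = run_time + checking_time
    return EfficiencyReport(
        sampler=str(chain.meta.get("sampler", "unknown")),
        n_samples=n_kept,
        run_time_s=run_time,
        checking_time_s=checking_time,
        rejected_fraction=rejected,
        min_ess=m,
        time_per_sample=total / max(1, len(chain)),
        time_per_min_ess=total / m,
        sampling_efficiency=m / n_kept,
    )
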