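"""MCMC samplers for viable individual and population parameter spaces.

Four procedures:

* :func:`adaptive_mh_individual` -- adaptive Metropolis-Hastings on the
  individual space with the indicator pseudo-likelihood 1(s(beta) <= eps),
  sampling uniformly on the individual viable region.
* :func:`naive_population_mcmc` -- Metropolis-Hastings on the population
  space with pseudo-likelihood 1(c_hat(gamma) <= delta), where c_hat is the
  CRN population-cost estimator; every retained sample satisfies the hard
  population criterion under the run's CRN.
* :func:`slmcmc` -- stochastic-likelihood MCMC: joint sampling over
  population and kappa individual parameters whose proposal draws the
  individuals directly from the proposed population distribution, so the
  acceptance probability collapses to the product of viability indicators.
  The gamma-marginal targets P_gamma^kappa(s <= eps).
* :func:`pt_slmcmc` -- parallel tempering over SLMCMC chains with
  kappa_1 < ... < kappa_r as inverse temperatures; the swap acceptance is the
  indicator product over the kappa' - kappa extra individuals drawn from the
  lower-kappa chain's current population parameter.

All samplers use a Gaussian random-walk proposal whose covariance is adapted
Haario-style from the chain history during the first half of the run (the
burn-in) and frozen afterwards, keeping the retained chain Markovian.
Proposals outside the box bounds are rejected, except on dimensions marked
for reflection (the sigma coordinates), which are folded back into bounds.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .objectives import CRNBlock, DesignProblem, default_crn

logger = logging.getLogger("popdesign")
LOG_EVERY = 1_000


def _log_progress(name: str, i: int, accepted: np.ndarray) -> None:
    if (i + 1) % LOG_EVERY == 0:
        rate = accepted[max(0, i + 1 - LOG_EVERY):i + 1].mean()
        logger.info("%s: iteration %d, acceptance rate %.3f (last %d)",
                    name, i + 1, rate, LOG_EVERY)

__all__ = [
    "Chain",
    "PTConfig",
    "swap_acceptance",
    "indicator_acceptance",
    "adaptive_mh_individual",
    "naive_population_mcmc",
    "slmcmc",
    "pt_slmcmc",
]

TARGET_ACCEPTANCE = 0.23


@dataclass
class Chain:
    """Ordered MCMC samples with acceptance and indicator bookkeeping."""

    names: tuple
    samples: np.ndarray
    accepted: np.ndarray
    indicator_state: np.ndarray
    seed: object = None
    proposal_cov: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.names = tuple(self.names)
        self.samples = np.asarray(self.samples, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)
        self.indicator_state = np.asarray(self.indicator_state, dtype=bool)
        n = self.samples.shape[0]
        if not (self.accepted.shape == self.indicator_state.shape == (n,)):
            raise ValueError("bookkeeping arrays must match the number of samples")
        if self.samples.shape[1] != len(self.names):
            raise ValueError("sample dimension must match names")

    def __len__(self) -> int:
        return self.samples.shape[0]

    @property
    def acceptance_rate(self) -> float:
        return float(self.accepted.mean()) if len(self) else math.nan

    def burn_in(self, frac: float = 0.5) -> "Chain":
        """Chain with the first ``frac`` of samples removed."""
        k = int(len(self) * frac)
        return Chain(self.names, self.samples[k:], self.accepted[k:],
                     self.indicator_state[k:], seed=self.seed,
                     proposal_cov=self.proposal_cov, meta=dict(self.meta))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.samples, columns=list(self.names))

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["accepted"] = self.accepted.astype(int)
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "Chain":
        df = pd.read_csv(path, float_precision="round_trip")
        accepted = df.pop("accepted").to_numpy(dtype=bool) if "accepted" in df \
            else np.zeros(len(df), dtype=bool)
        return cls(tuple(df.columns), df.to_numpy(dtype=float), accepted,
                   np.ones(len(df), dtype=bool))

    def summary(self) -> pd.DataFrame:
        """Per-dimension posterior summary (mean, sd, quantiles)."""
        df = self.to_dataframe()
        out = df.describe(percentiles=[0.01, 0.25, 0.5, 0.75, 0.99]).T
        out["acceptance_rate"] = self.acceptance_rate
        return out


@dataclass(frozen=True)
class PTConfig:
    """Parallel-tempering ladder: strictly increasing positive kappa values."""

    kappa_list: tuple

    def __post_init__(self):
        ks = tuple(int(k) for k in self.kappa_list)
        # equal adjacent kappas are allowed as a degenerate ladder (swap free)
        if len(ks) < 2 or any(k <= 0 for k in ks) or any(
                b < a for a, b in zip(ks, ks[1:])):
            raise ValueError("kappa_list must be positive and non-decreasing")
        object.__setattr__(self, "kappa_list", ks)

    @property
    def kappa_max(self) -> int:
        return self.kappa_list[-1]

    @property
    def inverse_temperatures(self) -> tuple:
        return tuple(k / self.kappa_max for k in self.kappa_list)


def swap_acceptance(indicators) -> float:
    """Closed-form replica-swap acceptance: the product of the viability
    indicators of the kappa' - kappa extra individuals (empty product = 1)."""
    return float(np.prod(np.asarray(indicators, dtype=float)))


def indicator_acceptance(ind_new, ind_old, q_ratio: float = 1.0) -> float:
    """General MH acceptance for indicator pseudo-likelihoods.

    With a symmetric proposal (q_ratio = 1) the ratio reduces to the product
    of the proposed indicators whenever the current state is viable.
    """
    num = float(np.prod(np.asarray(ind_new, dtype=float))) * q_ratio
    den = float(np.prod(np.asarray(ind_old, dtype=float)))
    if den == 0.0:
        return 1.0
    return min(1.0, num / den)


# ---------------------------------------------------------------------------
# Adaptive random-walk proposal
# ---------------------------------------------------------------------------

class _AdaptiveRW:
    """Haario-style adaptive Gaussian random walk on a bounded box.

    The proposal covariance is (scale * 2.38^2 / d) * (Cov_hat + eps I),
    re-estimated from the chain history at fixed intervals during burn-in;
    a global log-scale factor is nudged toward a ~0.23 acceptance rate.
    After ``freeze_at`` iterations the proposal is frozen.
    """

    def __init__(self, lower, upper, reflect_mask=None, adapt_interval: int = 200,
                 freeze_at: int | None = None):
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.d = self.lower.size
        self.reflect = (np.zeros(self.d, dtype=bool) if reflect_mask is None
                        else np.asarray(reflect_mask, dtype=bool))
        self.adapt_interval = adapt_interval
        self.freeze_at = freeze_at
        width = self.upper - self.lower
        self.base_cov = np.diag((width / 50.0) ** 2)
        self.log_scale = 0.0
        self._recent_accepts: list = []

    def cov(self) -> np.ndarray:
        return math.exp(self.log_scale) * self.base_cov

    def chol(self) -> np.ndarray:
        return np.linalg.cholesky(self.cov() + 1e-18 * np.eye(self.d))

    def propose(self, x, rng) -> np.ndarray:
        step = self.chol() @ rng.standard_normal(self.d)
        y = np.asarray(x, dtype=float) + step
        return self._fold(y)

    def _fold(self, y: np.ndarray) -> np.ndarray:
        if not self.reflect.any():
            return y
        out = y.copy()
        lo, hi = self.lower[self.reflect], self.upper[self.reflect]
        width = hi - lo
        z = np.mod(out[self.reflect] - lo, 2.0 * width)
        out[self.reflect] = lo + np.where(z > width, 2.0 * width - z, z)
        return out

    def in_bounds(self, x) -> bool:
        return bool(np.all(x >= self.lower) & np.all(x <= self.upper))

    def record(self, accepted: bool) -> None:
        self._recent_accepts.append(bool(accepted))

    def maybe_adapt(self, i: int, history: np.ndarray) -> None:
        if self.freeze_at is not None and i >= self.freeze_at:
            return
        if i == 0 or i % self.adapt_interval:
            return
        h = history[i // 3:i]  # full history less the earliest third
        if h.shape[0] >= 10:
            emp = np.cov(h.T) if self.d > 1 else np.array([[np.var(h[:, 0])]])
            emp = np.atleast_2d(emp) + 1e-12 * np.eye(self.d)
            self.base_cov = (2.38 ** 2 / self.d) * emp
        if self._recent_accepts:
            rate = float(np.mean(self._recent_accepts[-self.adapt_interval:]))
            self.log_scale += 0.5 * (rate - TARGET_ACCEPTANCE)
            self.log_scale = float(np.clip(self.log_scale, -10.0, 5.0))
        self._recent_accepts.clear()


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def find_viable_individual(problem: DesignProblem, rng, budget: int = 10_000):
    """Rejection-sample the individual box for a viable point (sampling coords).

    Candidates are drawn uniformly and evaluated in vectorized batches."""
    layout = problem.layout
    lo, hi = layout.sampling_bounds()
    eps = problem.thresholds.epsilon
    batch = 256
    for _ in range(0, budget, batch):
        X = rng.uniform(lo, hi, size=(batch, lo.size))
        nat = np.where(layout.log10, 10.0 ** X, X)
        p = dict(layout.fixed)
        p.update({name: nat[:, j] for j, name in enumerate(layout.names)})
        costs = problem.costs_for(p)
        hits = np.flatnonzero(costs <= eps)
        if hits.size:
            return X[hits[0]]
    raise RuntimeError(f"no viable individual parameter found in {budget} draws")


def _initial_population_vector(problem: DesignProblem, rng, check,
                               budget: int = 10_000, sigma0: float = 0.005):
    """Population start: means at a viable individual point, small sigma.

    ``check`` is a predicate on the candidate vector (the sampler-specific
    viability notion); candidate individual points are redrawn until it holds.
    """
    pop = problem.pop_layout
    lo, hi = pop.sampling_bounds()
    sigma_mask = pop.sigma_mask
    name_to_idx = {n: i for i, n in enumerate(problem.layout.names)}
    for _ in range(budget):
        x_ind = find_viable_individual(problem, rng, budget=budget)
        x = np.empty(pop.ndim)
        for j, name in enumerate(pop.mean_names):
            if name in name_to_idx:
                x[j] = x_ind[name_to_idx[name]]
            else:  # mean dimension without an individual counterpart
                x[j] = rng.uniform(lo[j], hi[j])
        if sigma_mask.any():
            s0 = math.log10(sigma0) if getattr(pop, "sigma_log10", False) else sigma0
            x[sigma_mask] = s0
        x = np.clip(x, lo, hi)
        if check(x):
            return x
    raise RuntimeError(f"no viable population start found in {budget} attempts")


# ---------------------------------------------------------------------------
# Samplers
# ---------------------------------------------------------------------------

def _spawn(seed, n):
    return np.random.SeedSequence(seed).spawn(n)


def adaptive_mh_individual(problem: DesignProblem, n_samples: int, seed,
                           x0=None, adapt: bool = True) -> Chain:
    """Uniform sampling of the individual viable region V_ind.

    Pseudo-likelihood 1(s(beta) <= epsilon); proposals are Gaussian in the
    layout's sampling coordinates (log10 where flagged) and rejected outside
    the box.  Returns the full chain (no burn-in removed).
    """
    ss_init, ss_run = _spawn(seed, 2)
    rng = np.random.default_rng(ss_run)
    lo, hi = problem.layout.sampling_bounds()
    if x0 is None:
        x0 = find_viable_individual(problem, np.random.default_rng(ss_init))
    x = np.asarray(x0, dtype=float)
    if not problem.indicator_at_vector(x):
        raise ValueError("x0 is not a viable starting point")

    rw = _AdaptiveRW(lo, hi, freeze_at=(n_samples // 2 if adapt else 0))
    eps = problem.thresholds.epsilon
    samples = np.empty((n_samples, lo.size))
    accepted = np.zeros(n_samples, dtype=bool)
    t0 = time.perf_counter()
    for i in range(n_samples):
        rw.maybe_adapt(i, samples)
        y = rw.propose(x, rng)
        ok = rw.in_bounds(y) and problem.cost_at_vector(y) <= eps
        if ok:
            x = y
        accepted[i] = ok
        rw.record(ok)
        samples[i] = x
        _log_progress("adaptive_mh_individual", i, accepted)
    return Chain(problem.layout.names, samples, accepted,
                 np.ones(n_samples, dtype=bool), seed=seed,
                 proposal_cov=rw.cov(),
                 meta={"sampler": "adaptive_mh_individual",
                       "epsilon": eps,
                       "run_time_s": time.perf_counter() - t0})


def naive_population_mcmc(problem: DesignProblem, n_samples: int, seed,
                          N: int = 300, crn: CRNBlock | None = None,
                          x0=None, adapt: bool = True) -> Chain:
    """Naive population sampler: 1(c_hat(gamma) <= delta) pseudo-likelihood.

    The population cost is estimated with a fixed CRN block of ``N`` cells,
    so every retained sample satisfies the hard criterion under that CRN.
    """
    ss_init, ss_run = _spawn(seed, 2)
    pop = problem.pop_layout
    if crn is None:
        crn = default_crn(problem, N, seed)
    rng = np.random.default_rng(ss_run)
    delta = problem.thresholds.delta
    lo, hi = pop.sampling_bounds()

    def viable(x):
        return problem.population_cost(pop.gamma_from_vector(x), crn) <= delta

    if x0 is None:
        x0 = _initial_population_vector(problem, np.random.default_rng(ss_init),
                                        viable)
    x = np.asarray(x0, dtype=float)
    if not viable(x):
        raise ValueError("x0 does not satisfy the population criterion")

    rw = _AdaptiveRW(lo, hi, reflect_mask=pop.sigma_mask,
                     freeze_at=(n_samples // 2 if adapt else 0))
    samples = np.empty((n_samples, pop.ndim))
    accepted = np.zeros(n_samples, dtype=bool)
    t0 = time.perf_counter()
    for i in range(n_samples):
        rw.maybe_adapt(i, samples)
        y = rw.propose(x, rng)
        ok = rw.in_bounds(y) and viable(y)
        if ok:
            x = y
        accepted[i] = ok
        rw.record(ok)
        samples[i] = x
        _log_progress("naive_population_mcmc", i, accepted)
    return Chain(pop.names, samples, accepted, np.ones(n_samples, dtype=bool),
                 seed=seed, proposal_cov=rw.cov(),
                 meta={"sampler": "naive_population_mcmc", "N": crn.N,
                       "delta": delta,
                       "run_time_s": time.perf_counter() - t0})


def _slmcmc_core(problem, kappa, n_samples, rng, x0, adapt=True):
    """Shared single-chain SLMCMC loop (used directly and inside PT)."""
    pop = problem.pop_layout
    lo, hi = pop.sampling_bounds()
    rw = _AdaptiveRW(lo, hi, reflect_mask=pop.sigma_mask,
                     freeze_at=(n_samples // 2 if adapt else 0))
    x = np.asarray(x0, dtype=float)
    samples = np.empty((n_samples, pop.ndim))
    accepted = np.zeros(n_samples, dtype=bool)
    for i in range(n_samples):
        rw.maybe_adapt(i, samples)
        y = rw.propose(x, rng)
        ok = (rw.in_bounds(y)
              and problem.draw_indicator_product(pop.gamma_from_vector(y),
                                                 kappa, rng))
        if ok:
            x = y
        accepted[i] = ok
        rw.record(ok)
        samples[i] = x
        _log_progress("slmcmc", i, accepted)
    return samples, accepted, rw


def _slmcmc_start(problem, kappa, rng):
    def viable(x):
        return problem.draw_indicator_product(
            problem.pop_layout.gamma_from_vector(x), kappa, rng)
    return _initial_population_vector(problem, rng, viable)


def slmcmc(problem: DesignProblem, kappa: int, n_samples: int, seed,
           x0=None, adapt: bool = True) -> Chain:
    """Stochastic-likelihood MCMC targeting P_gamma^kappa(s(beta) <= eps).

    Each step proposes gamma' from the adapted random walk, then draws kappa
    fresh individuals from P_gamma'; because the individuals are proposed from
    their own conditional, the population densities cancel and the move is
    accepted iff all kappa individuals are viable (early termination at the
    first failure).  Only the gamma component is stored; every stored state
    has indicator product one.
    """
    if kappa < 1:
        raise ValueError("kappa must be >= 1")
    ss_init, ss_run = _spawn(seed, 2)
    rng = np.random.default_rng(ss_run)
    if x0 is None:
        x0 = _slmcmc_start(problem, kappa, np.random.default_rng(ss_init))
    t0 = time.perf_counter()
    samples, accepted, rw = _slmcmc_core(problem, kappa, n_samples, rng, x0,
                                         adapt=adapt)
    return Chain(problem.pop_layout.names, samples, accepted,
                 np.ones(n_samples, dtype=bool), seed=seed,
                 proposal_cov=rw.cov(),
                 meta={"sampler": "slmcmc", "kappa": kappa,
                       "epsilon": problem.thresholds.epsilon,
                       "run_time_s": time.perf_counter() - t0})


def pt_slmcmc(problem: DesignProblem, pt: PTConfig, n_samples: int, seed,
              adapt: bool = True) -> Chain:
    """Parallel-tempered SLMCMC; the highest-kappa chain is retained.

    Per iteration every chain performs one SLMCMC step with its own kappa;
    then one uniformly chosen adjacent pair (kappa < kappa') attempts a state
    swap: kappa' - kappa fresh individuals are drawn from the lower chain's
    current population parameter and the swap is accepted iff all are viable
    (the closed-form indicator-product swap probability).
    """
    kappas = pt.kappa_list
    r = len(kappas)
    ss = _spawn(seed, r + 2)
    rngs = [np.random.default_rng(s) for s in ss[:r]]
    rng_swap = np.random.default_rng(ss[r])
    rng_init = np.random.default_rng(ss[r + 1])

    pop = problem.pop_layout
    lo, hi = pop.sampling_bounds()
    states = [_slmcmc_start(problem, k, rng_init) for k in kappas]
    rws = [_AdaptiveRW(lo, hi, reflect_mask=pop.sigma_mask,
                       freeze_at=(n_samples // 2 if adapt else 0))
           for _ in kappas]

    samples = np.empty((n_samples, pop.ndim))
    accepted = np.zeros(n_samples, dtype=bool)
    histories = [np.empty((n_samples, pop.ndim)) for _ in kappas]
    swap_attempts = 0
    swap_accepts = 0
    t0 = time.perf_counter()
    for i in range(n_samples):
        for c in range(r):
            rws[c].maybe_adapt(i, histories[c])
            y = rws[c].propose(states[c], rngs[c])
            ok = (rws[c].in_bounds(y)
                  and problem.draw_indicator_product(pop.gamma_from_vector(y),
                                                     kappas[c], rngs[c]))
            if ok:
                states[c] = y
            rws[c].record(ok)
            histories[c][i] = states[c]
            if c == r - 1:
                accepted[i] = ok
        # swap attempt between one random adjacent pair
        j = int(rng_swap.integers(0, r - 1))
        k_lo, k_hi = kappas[j], kappas[j + 1]
        extra = k_hi - k_lo
        swap_attempts += 1
        gamma_lo = pop.gamma_from_vector(states[j])
        if extra == 0 or problem.draw_indicator_product(gamma_lo, extra, rng_swap):
            states[j], states[j + 1] = states[j + 1], states[j]
            histories[j][i] = states[j]
            histories[j + 1][i] = states[j + 1]
            swap_accepts += 1
        samples[i] = states[r - 1]
        _log_progress("pt_slmcmc", i, accepted)
    return Chain(pop.names, samples, accepted, np.ones(n_samples, dtype=bool),
                 seed=seed, proposal_cov=rws[-1].cov(),
                 meta={"sampler": "pt_slmcmc", "kappa_list": list(kappas),
                       "epsilon": problem.thresholds.epsilon,
                       "swap_rate": swap_accepts / max(1, swap_attempts),
                       "run_time_s": time.perf_counter() - t0})
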