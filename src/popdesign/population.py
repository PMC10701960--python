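"""Log-normal population layer of the nonlinear mixed-effects (NLME) model.

Each cell draws its variable parameters from a multivariate log-normal
distribution: the log-parameters are normal with mean vector ``mean_log`` and
covariance ``cov`` (scalar sigma^2*I, diagonal, or full).  Non-variable
parameters (e.g. the repression coefficients theta_Tet/theta_Tup of the WTC)
are shared by every cell; structurally fixed constants (Hill coefficient,
aTc affinity) are carried alongside.

The coefficient of variation of a log-normal with log-scale standard
deviation sigma is ``CV = sqrt(exp(sigma^2) - 1)``; for sigma <= 0.1 the
approximation CV ~ sigma is accurate to < 0.6%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal

__all__ = [
    "PopulationParams",
    "PopulationSpaceLayout",
    "sigma_to_cv",
    "cv_to_sigma",
    "sample_individuals",
    "log_density",
    "SIGMA_MAX",
    "wtc_population_layout",
    "toy_population_layout",
]

#: Upper bound on the log-scale standard deviation, equivalent to CV = 1.
SIGMA_MAX = math.sqrt(math.log(2.0))


def sigma_to_cv(sigma):
    """CV of a log-normal from the log-scale standard deviation sigma."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")
    return np.sqrt(np.expm1(sigma ** 2))


def cv_to_sigma(cv):
    """Inverse of :func:`sigma_to_cv`: sigma = sqrt(log(1 + CV^2))."""
    cv = np.asarray(cv, dtype=float)
    if np.any(cv < 0):
        raise ValueError("CV must be non-negative")
    return np.sqrt(np.log1p(cv ** 2))


@dataclass(frozen=True)
class PopulationParams:
    """Population parameters gamma of the log-normal cell distribution.

    ``variable`` names the cell-to-cell variable parameters (canonical order);
    ``mean_log`` holds their natural-log location parameters, so ``exp(mean_log)``
    is the per-parameter median.  ``cov`` is the covariance of the underlying
    normal: a scalar variance (mode "scalar"), a vector of per-parameter
    variances ("diagonal"), or a full matrix ("full").  ``shared`` maps
    zero-variance parameters shared by all cells to their values.
    """

    variable: tuple
    mean_log: np.ndarray
    cov_mode: str
    cov: object
    shared: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "variable", tuple(self.variable))
        object.__setattr__(self, "mean_log",
                           np.asarray(self.mean_log, dtype=float))
        k = len(self.variable)
        if self.mean_log.shape != (k,):
            raise ValueError("mean_log must match the number of variable parameters")
        if self.cov_mode not in ("scalar", "diagonal", "full"):
            raise ValueError(f"unknown cov_mode {self.cov_mode!r}")
        if self.cov_mode == "scalar":
            c = float(self.cov)
            if c < 0:
                raise ValueError("scalar variance must be non-negative")
            object.__setattr__(self, "cov", c)
        elif self.cov_mode == "diagonal":
            c = np.asarray(self.cov, dtype=float)
            if c.shape != (k,) or np.any(c < 0):
                raise ValueError("diagonal covariance needs k non-negative variances")
            object.__setattr__(self, "cov", c)
        else:
            c = np.asarray(self.cov, dtype=float)
            if c.shape != (k, k):
                raise ValueError("full covariance must be k x k")
            object.__setattr__(self, "cov", c)

    @property
    def ndim(self) -> int:
        return len(self.variable)

    def cov_matrix(self) -> np.ndarray:
        k = self.ndim
        if self.cov_mode == "scalar":
            return self.cov * np.eye(k)
        if self.cov_mode == "diagonal":
            return np.diag(self.cov)
        return np.array(self.cov)

    def chol(self) -> np.ndarray:
        """Lower-triangular Cholesky factor of the underlying normal covariance."""
        k = self.ndim
        if self.cov_mode == "scalar":
            return math.sqrt(self.cov) * np.eye(k)
        if self.cov_mode == "diagonal":
            return np.diag(np.sqrt(self.cov))
        try:
            return np.linalg.cholesky(self.cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance matrix is not positive definite") from exc

    def sigmas(self) -> np.ndarray:
        """Per-parameter log-scale standard deviations (diagonal of cov)."""
        if self.cov_mode == "scalar":
            return np.full(self.ndim, math.sqrt(self.cov))
        if self.cov_mode == "diagonal":
            return np.sqrt(self.cov)
        return np.sqrt(np.diag(self.cov))

    def cvs(self) -> np.ndarray:
        """Per-parameter coefficients of variation."""
        return sigma_to_cv(self.sigmas())


def sample_individuals(gamma: PopulationParams, n: int, rng_or_crn) -> dict:
    """Draw ``n`` individual parameter sets from the population distribution.

    ``rng_or_crn`` is either a :class:`numpy.random.Generator` (fresh draws)
    or a fixed (n, k) block of standard-normal variates (common random
    numbers), in which case the output is a deterministic function of gamma.
    Returns a dict mapping parameter name -> array (variable parameters) or
    scalar (shared parameters); all values strictly positive.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = gamma.ndim
    if isinstance(rng_or_crn, np.random.Generator):
        S = rng_or_crn.standard_normal((n, k))
    else:
        S = np.asarray(rng_or_crn, dtype=float)
        if S.shape[0] < n or S.shape[1] != k:
            raise ValueError(f"CRN block must be at least ({n}, {k})")
        S = S[:n]
    L = gamma.chol()
    log_beta = gamma.mean_log + S @ L.T
    beta = np.exp(log_beta)
    out = {name: beta[:, j] for j, name in enumerate(gamma.variable)}
    out.update(gamma.shared)
    return out


def log_density(gamma: PopulationParams, beta) -> float:
    """Multivariate log-normal log-density of one cell's variable parameters.

    ``beta`` is a dict (name -> value) or an array in the canonical variable
    order.  Returns -inf for any non-positive coordinate.
    """
    if isinstance(beta, dict):
        b = np.array([beta[name] for name in gamma.variable], dtype=float)
    else:
        b = np.asarray(beta, dtype=float)
    if b.shape != (gamma.ndim,):
        raise ValueError("beta must have one value per variable parameter")
    if np.any(b <= 0):
        return -np.inf
    log_b = np.log(b)
    normal = multivariate_normal(mean=gamma.mean_log, cov=gamma.cov_matrix(),
                                 allow_singular=False)
    return float(normal.logpdf(log_b) - log_b.sum())


# ---------------------------------------------------------------------------
# Population-space layout (sampled gamma coordinates)
# ---------------------------------------------------------------------------

@dataclass
class PopulationSpaceLayout:
    """Bounded box of sampled population-parameter dimensions.

    Sampled dimensions are the free means (log10 scale where flagged)
    followed by the log-scale standard deviations: a single common ``sigma``
    (scalar covariance) or one ``sigma_<name>`` per variable parameter
    (diagonal covariance).  ``fixed_means`` holds medians of variable
    parameters whose location is not sampled; ``shared_sampled`` names sampled
    dimensions that are zero-variance shared parameters rather than means of
    variable ones.  ``fixed_sigma`` freezes the variability instead of
    sampling it (used by analytic fixtures).
    """

    variable: tuple
    mean_names: tuple
    mean_lower: np.ndarray
    mean_upper: np.ndarray
    mean_log10: np.ndarray
    fixed_means: dict
    shared_sampled: tuple = ()
    fixed_shared: dict = field(default_factory=dict)
    cov_mode: str = "scalar"
    sigma_bounds: tuple = (1e-3, SIGMA_MAX)
    sigma_log10: bool = True
    fixed_sigma: object = None

    def __post_init__(self):
        self.variable = tuple(self.variable)
        self.mean_names = tuple(self.mean_names)
        self.shared_sampled = tuple(self.shared_sampled)
        self.mean_lower = np.asarray(self.mean_lower, dtype=float)
        self.mean_upper = np.asarray(self.mean_upper, dtype=float)
        self.mean_log10 = np.asarray(self.mean_log10, dtype=bool)
        m = len(self.mean_names)
        if not (self.mean_lower.shape == self.mean_upper.shape
                == self.mean_log10.shape == (m,)):
            raise ValueError("mean bounds/flags must match mean_names")
        if self.cov_mode not in ("scalar", "diagonal"):
            raise ValueError("sampled layouts support scalar or diagonal covariance")
        for name in self.shared_sampled:
            if name not in self.mean_names:
                raise ValueError(f"shared sampled dimension {name!r} missing from mean_names")
        missing = set(self.variable) - set(self.mean_names) - set(self.fixed_means)
        if missing:
            raise ValueError(f"no location for variable parameters: {sorted(missing)}")

    @property
    def sigma_names(self) -> tuple:
        if self.fixed_sigma is not None:
            return ()
        if self.cov_mode == "scalar":
            return ("sigma",)
        return tuple(f"sigma_{name}" for name in self.variable)

    @property
    def names(self) -> tuple:
        return self.mean_names + self.sigma_names

    @property
    def ndim(self) -> int:
        return len(self.names)

    @property
    def sigma_mask(self) -> np.ndarray:
        """Boolean mask over sampled dimensions marking the sigma coordinates."""
        n_sig = len(self.sigma_names)
        return np.concatenate([np.zeros(len(self.mean_names), dtype=bool),
                               np.ones(n_sig, dtype=bool)])

    def sampling_bounds(self):
        lo = np.where(self.mean_log10, np.log10(self.mean_lower), self.mean_lower)
        hi = np.where(self.mean_log10, np.log10(self.mean_upper), self.mean_upper)
        n_sig = len(self.sigma_names)
        if n_sig:
            s_lo, s_hi = self.sigma_bounds
            if self.sigma_log10:
                s_lo, s_hi = math.log10(s_lo), math.log10(s_hi)
            lo = np.concatenate([lo, np.full(n_sig, s_lo)])
            hi = np.concatenate([hi, np.full(n_sig, s_hi)])
        return lo, hi

    def in_bounds(self, x) -> bool:
        lo, hi = self.sampling_bounds()
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= lo) & np.all(x <= hi))

    def gamma_from_vector(self, x) -> PopulationParams:
        """Build the PopulationParams for a sampling-coordinate vector."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.ndim,):
            raise ValueError(f"expected vector of length {self.ndim}")
        m = len(self.mean_names)
        mean_part = np.where(self.mean_log10, 10.0 ** x[:m], x[:m])
        by_name = dict(zip(self.mean_names, mean_part))

        shared = dict(self.fixed_shared)
        for name in self.shared_sampled:
            shared[name] = by_name[name]

        medians = []
        for name in self.variable:
            if name in by_name and name not in self.shared_sampled:
                medians.append(by_name[name])
            else:
                medians.append(self.fixed_means[name])
        mean_log = np.log(np.asarray(medians, dtype=float))

        if self.fixed_sigma is not None:
            sig = self.fixed_sigma
        elif self.cov_mode == "scalar":
            sig = 10.0 ** float(x[m]) if self.sigma_log10 else float(x[m])
        else:
            sig = 10.0 ** x[m:] if self.sigma_log10 else x[m:]
        if self.cov_mode == "scalar":
            cov = float(np.asarray(sig)) ** 2
        else:
            cov = np.asarray(sig, dtype=float) ** 2
        return PopulationParams(variable=self.variable, mean_log=mean_log,
                                cov_mode=self.cov_mode, cov=cov, shared=shared)

    def vector_from_gamma(self, gamma: PopulationParams) -> np.ndarray:
        medians = dict(zip(gamma.variable, np.exp(gamma.mean_log)))
        vals = []
        for name, is_log in zip(self.mean_names, self.mean_log10):
            v = gamma.shared[name] if name in self.shared_sampled else medians[name]
            vals.append(math.log10(v) if is_log else v)
        if self.fixed_sigma is None:
            sigs = ([math.sqrt(gamma.cov)] if self.cov_mode == "scalar"
                    else list(np.sqrt(gamma.cov)))
            if self.sigma_log10:
                sigs = [math.log10(s) for s in sigs]
            vals.extend(sigs)
        return np.asarray(vals, dtype=float)


def wtc_population_layout(cov_mode: str = "scalar",
                          n_Tup: float | None = None) -> PopulationSpaceLayout:
    """Population space of the WTC design problem.

    Sampled means: d_Tet, d_C (cell-variable) and theta_Tet, theta_Tup
    (shared, zero variance), all in log10 within their individual bounds.
    The six variable parameters {k_Tet, k_Tup, k_C, d_Tup, d_Tet, d_C} carry
    a common sigma (scalar mode, 5 sampled dimensions) or one sigma each
    (diagonal mode, 10 dimensions), with CV bounded by one.
    """
    from .circuits import WTC_FIXED, WTC_VARIABLE

    fixed_shared = {
        "n_Tet": WTC_FIXED["n"], "n_Tup": WTC_FIXED["n"], "K_a": WTC_FIXED["K_a"],
    }
    if n_Tup is not None:
        fixed_shared["n_Tup"] = n_Tup
    return PopulationSpaceLayout(
        variable=WTC_VARIABLE,
        mean_names=("d_Tet", "d_C", "theta_Tet", "theta_Tup"),
        mean_lower=np.array([3e-3, 3e-3, 1e-3, 1e-6]),
        mean_upper=np.array([0.1, 0.1, 1e6, 20.0]),
        mean_log10=np.array([True, True, True, True]),
        fixed_means={"k_Tet": WTC_FIXED["k_Tet"], "k_Tup": WTC_FIXED["k_Tup"],
                     "k_C": WTC_FIXED["k_C"], "d_Tup": WTC_FIXED["d_Tup"]},
        shared_sampled=("theta_Tet", "theta_Tup"),
        fixed_shared=fixed_shared,
        cov_mode=cov_mode,
    )


def toy_population_layout(mode: str = "mean-and-sigma", fixed_sigma=None,
                          k_bounds=(0.1, 10.0), d_median: float = 1.0,
                          cov_mode: str = "scalar",
                          d_variable: bool = True) -> PopulationSpaceLayout:
    """Toy population space: the median of k is sampled (log10); d is fixed.

    With ``mode="mean-only"`` (requires ``fixed_sigma``) the space is 1-D,
    which makes sampler targets amenable to quadrature oracles; with
    ``d_variable=False`` only k varies across cells, so log(k/d) is exactly
    normal with variance sigma^2.
    """
    if mode == "mean-only" and fixed_sigma is None:
        raise ValueError("mean-only mode requires fixed_sigma")
    if d_variable:
        variable, fixed_means, fixed_shared = ("k", "d"), {"d": d_median}, {}
    else:
        variable, fixed_means, fixed_shared = ("k",), {}, {"d": d_median}
    return PopulationSpaceLayout(
        variable=variable,
        mean_names=("k",),
        mean_lower=np.array([k_bounds[0]]),
        mean_upper=np.array([k_bounds[1]]),
        mean_log10=np.array([True]),
        fixed_means=fixed_means,
        fixed_shared=fixed_shared,
        cov_mode=cov_mode,
        fixed_sigma=fixed_sigma if mode == "mean-only" else None,
    )
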