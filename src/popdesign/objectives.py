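"""Reference behavior, individual and population cost functions.

The individual cost s(beta) is the root-mean-square deviation of a cell's
steady-state dose-response from the reference curve over a regular dose grid;
a cell is viable when s(beta) <= epsilon.  The population cost c(gamma) is the
fraction of cells in population gamma that are *not* viable, estimated with a
fixed block of common random numbers (CRN) so that repeated evaluations at
the same gamma are bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .circuits import (IndividualParams, ParamSpaceLayout, WTCModel, ToyModel,
                       wtc_individual_layout, toy_individual_layout)
from .population import (PopulationParams, PopulationSpaceLayout,
                         sample_individuals, wtc_population_layout,
                         toy_population_layout)

__all__ = [
    "ReferenceCurve",
    "ConstantReference",
    "DesignThresholds",
    "CRNBlock",
    "reference_value",
    "individual_cost",
    "batch_individual_costs",
    "is_viable",
    "population_cost",
    "DesignProblem",
    "wtc_problem",
    "toy_problem",
]


@dataclass(frozen=True)
class ReferenceCurve:
    """Ideal linear dose-response through the origin.

    The base objective is the line through (0 nM, 0 nM) and (150 nM, 60 nM):
    slope 0.4 nM Citrine per nM aTc over the input dynamic range
    [0, maxIDR].  Extended-IDR variants keep the slope and dose step and
    raise ``max_idr``.
    """

    slope: float = 0.4
    max_idr: float = 150.0
    dose_step: float = 25.0

    def __post_init__(self):
        if self.slope <= 0 or self.max_idr <= 0 or self.dose_step <= 0:
            raise ValueError("slope, max_idr and dose_step must be positive")

    @property
    def doses(self) -> np.ndarray:
        return np.arange(0.0, self.max_idr + 0.5 * self.dose_step, self.dose_step)

    @property
    def values(self) -> np.ndarray:
        return self.slope * self.doses


@dataclass(frozen=True)
class ConstantReference:
    """Dose-independent reference (used by the closed-form toy fixture)."""

    value: float
    doses: tuple = (0.0,)

    @property
    def values(self) -> np.ndarray:
        return np.full(len(self.doses), self.value)


def reference_value(a: float, ref: ReferenceCurve) -> float:
    """Reference output slope*a at dose ``a`` inside the input dynamic range."""
    if not 0.0 <= a <= ref.max_idr:
        raise ValueError(f"dose {a} outside the input dynamic range [0, {ref.max_idr}]")
    return ref.slope * a


@dataclass(frozen=True)
class DesignThresholds:
    """epsilon: individual cost threshold (nM); delta: population threshold."""

    epsilon: float = 6.0
    delta: float = 0.2

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie strictly between 0 and 1")


@dataclass(frozen=True)
class CRNBlock:
    """Fixed block of N standard-normal vectors (common random numbers).

    Generated once per run; makes the population-cost estimator a
    deterministic function of gamma.
    """

    samples: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "samples",
                           np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 2:
            raise ValueError("CRN block must be a 2-D array")

    @property
    def N(self) -> int:
        return self.samples.shape[0]

    @property
    def dim(self) -> int:
        return self.samples.shape[1]

    @classmethod
    def from_seed(cls, n: int, dim: int, seed) -> "CRNBlock":
        rng = np.random.default_rng(seed)
        return cls(rng.standard_normal((n, dim)))


def default_crn(problem: "DesignProblem", N: int, seed) -> CRNBlock:
    """The canonical CRN block for a run seed.

    Derived from a dedicated spawn key so that a sampler run and a later
    a-posteriori check given the same integer seed share the same block.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(0x63726e,))
    return CRNBlock.from_seed(N, len(problem.pop_layout.variable), ss)


def individual_cost(params, ref, model=None, method: str = "fastpath") -> float:
    """RMS deviation of the steady-state dose-response from the reference.

    ``params`` is an :class:`IndividualParams` (WTC) or a name->value dict
    matching the model's parameters.  Non-converged doses give +inf.
    """
    if model is None:
        model = WTCModel(method=method)
    dr = model.response(params, ref.doses)
    if not np.all(dr.converged):
        return math.inf
    return float(np.sqrt(np.mean((dr.outputs - ref.values) ** 2)))


def batch_individual_costs(p: dict, ref, model) -> np.ndarray:
    """Vectorized individual costs for a batch of cells (dict of arrays)."""
    out = model.batch_response(p, ref.doses)  # (N, D)
    return np.sqrt(np.mean((out - ref.values[np.newaxis, :]) ** 2, axis=1))


def is_viable(params, ref, thresholds: DesignThresholds, model=None,
              method: str = "fastpath") -> bool:
    """Indicator 1(s(beta) <= epsilon); the boundary counts as viable."""
    return individual_cost(params, ref, model=model, method=method) <= thresholds.epsilon


def population_cost(gamma: PopulationParams, problem: "DesignProblem",
                    crn: CRNBlock) -> float:
    """CRN estimate of c(gamma): the fraction of cells with s(beta) > epsilon.

    Individual parameters are reconstructed as exp(mu + L S_i) from the fixed
    standard-normal block, so the estimate is deterministic in gamma.
    """
    p = sample_individuals(gamma, crn.N, crn.samples)
    costs = problem.costs_for(p)
    return float(np.mean(costs > problem.thresholds.epsilon))


@dataclass
class DesignProblem:
    """Bundle of model, parameter-space layouts, reference and thresholds."""

    model: object
    layout: ParamSpaceLayout
    pop_layout: PopulationSpaceLayout
    reference: object
    thresholds: DesignThresholds = field(default_factory=DesignThresholds)

    # -- individual level ---------------------------------------------------
    def costs_for(self, p: dict) -> np.ndarray:
        """Individual costs for a batch of cells given as dict of arrays."""
        full = {**self.layout.fixed, **p}
        return batch_individual_costs(full, self.reference, self.model)

    def cost_at_vector(self, x) -> float:
        """Individual cost at a point in the layout's sampling coordinates."""
        return float(self.costs_for(self.layout.params_from_vector(x))[0])

    def indicator_at_vector(self, x) -> bool:
        return self.cost_at_vector(x) <= self.thresholds.epsilon

    # -- population level ---------------------------------------------------
    def population_cost(self, gamma: PopulationParams, crn: CRNBlock) -> float:
        return population_cost(gamma, self, crn)

    def draw_indicator_product(self, gamma: PopulationParams, kappa: int,
                               rng: np.random.Generator) -> bool:
        """Draw kappa fresh cells from gamma; True iff all are viable.

        The kappa standard-normal blocks are drawn up front (fixed RNG stream
        consumption) and the costs are evaluated in one vectorized
        steady-state solve; the result equals the product of per-cell
        viability indicators.
        """
        S = rng.standard_normal((kappa, gamma.ndim))
        p = sample_individuals(gamma, kappa, S)
        return bool(np.all(self.costs_for(p) <= self.thresholds.epsilon))


def wtc_problem(epsilon: float = 6.0, delta: float = 0.2,
                cov_mode: str = "scalar", max_idr: float = 150.0,
                slope: float = 0.4, dose_step: float = 25.0,
                n_Tup: float | None = None) -> DesignProblem:
    """The WTC design problem with the printed defaults.

    ``n_Tup`` overrides the Hill coefficient of TetR-Tup1 repression (the
    increased-cooperativity variant uses 5) while TetR keeps n = 1.57.
    """
    model = WTCModel() if n_Tup is None else WTCModel(n_Tup=n_Tup)
    layout = wtc_individual_layout()
    if n_Tup is not None:
        layout.fixed["n_Tup"] = n_Tup
    return DesignProblem(
        model=model,
        layout=layout,
        pop_layout=wtc_population_layout(cov_mode=cov_mode, n_Tup=n_Tup),
        reference=ReferenceCurve(slope=slope, max_idr=max_idr, dose_step=dose_step),
        thresholds=DesignThresholds(epsilon=epsilon, delta=delta),
    )


def toy_problem(epsilon: float = 0.5, delta: float = 0.2, r: float = 1.0,
                mode: str = "mean-and-sigma", fixed_sigma=None,
                d_variable: bool = True, cov_mode: str = "scalar") -> DesignProblem:
    """Closed-form toy design problem: constant output k/d against constant r."""
    return DesignProblem(
        model=ToyModel(mode="constant"),
        layout=toy_individual_layout(),
        pop_layout=toy_population_layout(mode=mode, fixed_sigma=fixed_sigma,
                                         d_variable=d_variable, cov_mode=cov_mode),
        reference=ConstantReference(r),
        thresholds=DesignThresholds(epsilon=epsilon, delta=delta),
    )
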