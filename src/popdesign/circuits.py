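"""Individual-cell circuit models and steady-state dose-response extraction.

The central model is the well-tempered controller (WTC): a transcriptional
controller in which the fluorescent reporter Citrine is repressed both by
autorepressed TetR and by constitutively expressed TetR-Tup1, with the inducer
anhydrotetracycline (aTc) inactivating both repressors.  The ODE system tracks
the total concentrations of TetR (``R_Tet``), TetR-Tup1 (``R_Tup``) and
Citrine (``C``); repressor activity enters through a rapid-equilibrium
aTc-binding fraction ``f``.

A closed-form toy model (single production/degradation pair, optionally with a
Michaelis-type dose dependence) is provided as an analytically tractable
fixture for the cost and sampler machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "WTC_FIXED",
    "WTC_FITTED",
    "IndividualParams",
    "ParamSpaceLayout",
    "DoseResponse",
    "active_fraction",
    "wtc_rhs",
    "steady_state_output",
    "dose_response",
    "wtc_batch_steady_state",
    "WTCModel",
    "ToyModel",
    "toy_model_output",
    "wtc_individual_layout",
    "toy_individual_layout",
    "get_model",
]

# Fixed WTC parameters (production rates nM/min, degradation 1/min, Hill
# coefficient dimensionless, aTc association constant 1/nM, scaling nM/unit).
WTC_FIXED = {
    "k_Tet": 1.12,
    "k_Tup": 0.79,
    "k_C": 0.84,
    "d_Tup": 1.28,
    "n": 1.57,
    "K_a": 144.37,
    "U_sc": 0.76,
}

# Estimated values for the four sampled parameters of the fitted circuit.
WTC_FITTED = {
    "d_C": 0.006,
    "d_Tet": 0.0087,
    "theta_Tet": 0.006,
    "theta_Tup": 0.5e-4,
}

#: Canonical order of the six cell-to-cell variable WTC parameters.
WTC_VARIABLE = ("k_Tet", "k_Tup", "k_C", "d_Tup", "d_Tet", "d_C")


@dataclass(frozen=True)
class IndividualParams:
    """One cell's full parameter vector for the WTC circuit.

    Units: ``k_*`` in nM/min, ``d_*`` in 1/min, ``theta_*`` in nM,
    ``K_a`` in 1/nM, Hill coefficients dimensionless, ``U_sc`` in nM/unit
    (carried for completeness; not used in cost computations).
    """

    k_Tet: float = WTC_FIXED["k_Tet"]
    k_Tup: float = WTC_FIXED["k_Tup"]
    k_C: float = WTC_FIXED["k_C"]
    d_Tup: float = WTC_FIXED["d_Tup"]
    d_Tet: float = WTC_FITTED["d_Tet"]
    d_C: float = WTC_FITTED["d_C"]
    theta_Tet: float = WTC_FITTED["theta_Tet"]
    theta_Tup: float = WTC_FITTED["theta_Tup"]
    n_Tet: float = WTC_FIXED["n"]
    n_Tup: float = WTC_FIXED["n"]
    K_a: float = WTC_FIXED["K_a"]
    U_sc: float = WTC_FIXED["U_sc"]

    def __post_init__(self):
        for name in ("k_Tet", "k_Tup", "k_C", "d_Tup", "d_Tet", "d_C",
                     "theta_Tet", "theta_Tup", "n_Tet", "n_Tup", "K_a"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"parameter {name} must be finite and > 0, got {v!r}")

    def replace(self, **kw) -> "IndividualParams":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d) -> "IndividualParams":
        d = dict(d)
        if "n" in d:  # shared Hill coefficient shorthand
            n = d.pop("n")
            d.setdefault("n_Tet", n)
            d.setdefault("n_Tup", n)
        return cls(**d)


@dataclass(frozen=True)
class DoseResponse:
    """Steady-state dose-response: aTc doses (nM) -> Citrine (nM)."""

    doses: np.ndarray
    outputs: np.ndarray
    converged: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "doses", np.asarray(self.doses, dtype=float))
        object.__setattr__(self, "outputs", np.asarray(self.outputs, dtype=float))
        object.__setattr__(self, "converged", np.asarray(self.converged, dtype=bool))
        if not (self.doses.shape == self.outputs.shape == self.converged.shape):
            raise ValueError("doses, outputs, converged must have identical shape")


def active_fraction(R_Tet, R_Tup, a, K_a):
    """Rapid-equilibrium fraction of repressor (TetR + TetR-Tup1) not bound to aTc.

    With total repressor ``T = R_Tet + R_Tup`` and total aTc ``a``::

        f = 1/2 - (1 + K_a*a - sqrt((1 + K_a*(T - a))**2 + 4*K_a*a)) / (2*K_a*T)

    which is the physical root of the bimolecular binding quadratic.  As
    ``T -> 0`` the expression tends to ``1/(1 + K_a*a)``; that limit is used
    at ``T == 0``.  ``0 <= f <= 1`` and ``f(a=0) = 1``.
    """
    R_Tet = np.asarray(R_Tet, dtype=float)
    R_Tup = np.asarray(R_Tup, dtype=float)
    a = np.asarray(a, dtype=float)
    T = R_Tet + R_Tup
    with np.errstate(divide="ignore", invalid="ignore"):
        disc = np.sqrt((1.0 + K_a * (T - a)) ** 2 + 4.0 * K_a * a)
        f = 0.5 - (1.0 + K_a * a - disc) / (2.0 * K_a * T)
        f = np.where(T > 0.0, f, 1.0 / (1.0 + K_a * a))
    return np.clip(f, 0.0, 1.0)


def _hill_denominator(R_Tet, R_Tup, a, p: IndividualParams):
    f = active_fraction(R_Tet, R_Tup, a, p.K_a)
    return (1.0
            + (f * R_Tet / p.theta_Tet) ** p.n_Tet
            + (f * R_Tup / p.theta_Tup) ** p.n_Tup)


def wtc_rhs(state, a, params: IndividualParams):
    """Time derivatives (nM/min) of (R_Tet, R_Tup, C) at constant aTc dose ``a``.

    TetR and Citrine production share the same OR-gate Hill denominator in the
    active repressor concentrations; TetR-Tup1 is constitutive
    (``dR_Tup/dt = k_Tup - d_Tup*R_Tup``).
    """
    R_Tet, R_Tup, C = state
    den = _hill_denominator(R_Tet, R_Tup, a, params)
    return np.array([
        params.k_Tet / den - params.d_Tet * R_Tet,
        params.k_Tup - params.d_Tup * R_Tup,
        params.k_C / den - params.d_C * C,
    ])


# ---------------------------------------------------------------------------
# Steady-state solvers
# ---------------------------------------------------------------------------

def _wtc_root_steady_state(params: IndividualParams, a: float):
    """Scalar fast path: reduce the steady state to a 1-D root find.

    At steady state R_Tup* = k_Tup/d_Tup, R_Tet* solves
    ``k_Tet = d_Tet * R * den(R)`` (monotone in R, bracketed by
    ``[0, k_Tet/d_Tet]``), and Citrine follows from the shared denominator:
    ``C* = k_C / (d_C * den(R*))``.
    """
    out = wtc_batch_steady_state(
        np.array([a], dtype=float),
        **{name: np.array([getattr(params, name)]) for name in WTC_VARIABLE},
        theta_Tet=params.theta_Tet, theta_Tup=params.theta_Tup,
        n_Tet=params.n_Tet, n_Tup=params.n_Tup, K_a=params.K_a,
    )
    return float(out[0, 0])


def wtc_batch_steady_state(doses, *, k_Tet, k_Tup, k_C, d_Tup, d_Tet, d_C,
                           theta_Tet, theta_Tup, n_Tet, n_Tup, K_a,
                           n_iter: int = 52):
    """Vectorized steady-state Citrine for a batch of cells over a dose grid.

    Per-cell parameters are 1-D arrays of length N (scalars broadcast);
    ``theta_*``, ``n_*`` and ``K_a`` may be scalars or length-N arrays.
    Returns an (N, D) array of steady-state Citrine concentrations (nM).

    The TetR fixed point is the unique zero of the strictly decreasing
    residual ``g(R) = k_Tet - d_Tet * R * den(R)`` on ``(0, k_Tet/d_Tet]``;
    it is bracketed in log-concentration (the root can sit many decades
    below the unrepressed level when repression is strong) and bisected:
    ``n_iter`` halvings of a 36-ln-unit bracket leave ~1e-11 relative width,
    far below the 1e-6 agreement guaranteed against integration.
    """
    doses = np.atleast_1d(np.asarray(doses, dtype=float))

    def col(v):
        return np.atleast_1d(np.asarray(v, dtype=float)).reshape(-1, 1)

    k_Tet, k_Tup, k_C = col(k_Tet), col(k_Tup), col(k_C)
    d_Tup, d_Tet, d_C = col(d_Tup), col(d_Tet), col(d_C)
    theta_Tet, theta_Tup = col(theta_Tet), col(theta_Tup)
    n_Tet, n_Tup, K_a = col(n_Tet), col(n_Tup), col(K_a)

    R_Tup = k_Tup / d_Tup
    a = doses[np.newaxis, :]

    def den_of(R):
        f = active_fraction(R, R_Tup, a, K_a)
        return (1.0
                + (f * R / theta_Tet) ** n_Tet
                + (f * R_Tup / theta_Tup) ** n_Tup)

    shape = np.broadcast_shapes(
        k_Tet.shape, d_Tet.shape, R_Tup.shape, theta_Tet.shape,
        theta_Tup.shape, (1, doses.size),
    )
    # bisect u = ln R; g(exp(u_hi)) <= 0 since den >= 1, g(exp(u_lo)) > 0
    # because R*den(R) -> 0 as R -> 0 (den is bounded near 0).
    u_hi = np.broadcast_to(np.log(k_Tet / d_Tet), shape).copy()
    u_lo = u_hi - 36.0
    for _ in range(n_iter):
        mid = 0.5 * (u_lo + u_hi)
        R = np.exp(mid)
        g = k_Tet - d_Tet * R * den_of(R)
        take = g > 0.0
        u_lo = np.where(take, mid, u_lo)
        u_hi = np.where(take, u_hi, mid)
    R_star = np.exp(0.5 * (u_lo + u_hi))
    return np.asarray(k_C / (d_C * den_of(R_star)))


def _wtc_integrate_steady_state(params: IndividualParams, a: float, *,
                                t_final: float = 2.5e7, window: float = 500.0,
                                rel_tol: float = 1e-10, max_extensions: int = 10,
                                rtol: float = 1e-10, atol: float = 1e-12):
    """Reference semantics: integrate the ODEs from x0 = (0, 0, 0) nM.

    Integrates to ``t_final`` = 2.5e7 min and extends the horizon while the
    relative variation of Citrine over the trailing ``window`` = 500 min
    exceeds ``rel_tol`` = 1e-10, up to ``max_extensions`` times.
    Returns (Citrine, converged).
    """
    x0 = np.zeros(3)
    t0 = 0.0
    rhs = lambda t, x: wtc_rhs(x, a, params)
    C_end = np.nan
    for _ in range(max_extensions + 1):
        sol = solve_ivp(rhs, (t0, t0 + t_final), x0, method="LSODA",
                        rtol=rtol, atol=atol, dense_output=True)
        if not sol.success:
            return np.nan, False
        t_end = sol.t[-1]
        C_end = sol.y[2, -1]
        C_prev = sol.sol(t_end - window)[2]
        denom = max(abs(C_end), atol)
        if abs(C_end - C_prev) / denom <= rel_tol:
            return float(C_end), True
        t0, x0 = t_end, sol.y[:, -1]
    return float(C_end), False


def steady_state_output(params: IndividualParams, a: float,
                        method: str = "fastpath", **kw):
    """Steady-state Citrine concentration (nM) at constant aTc dose ``a``.

    ``method="integrate"`` follows the reference protocol (long-horizon stiff
    integration with trailing-window convergence checks); ``"fastpath"``
    (default) solves the equivalent steady-state algebraic system by bracketed
    root finding, which agrees with integration to better than 1e-6 relative.
    Returns ``(citrine, converged)``.
    """
    if a < 0:
        raise ValueError("aTc dose must be non-negative")
    if method == "fastpath":
        return _wtc_root_steady_state(params, a), True
    if method == "integrate":
        return _wtc_integrate_steady_state(params, a, **kw)
    raise ValueError(f"unknown method {method!r}")


def dose_response(params: IndividualParams, doses, method: str = "fastpath") -> DoseResponse:
    """Steady-state dose-response over a non-negative, sorted dose grid."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    if np.any(np.diff(doses) < 0):
        raise ValueError("doses must be sorted ascending")
    if method == "fastpath":
        out = wtc_batch_steady_state(
            doses,
            **{name: np.array([getattr(params, name)]) for name in WTC_VARIABLE},
            theta_Tet=params.theta_Tet, theta_Tup=params.theta_Tup,
            n_Tet=params.n_Tet, n_Tup=params.n_Tup, K_a=params.K_a,
        )[0]
        return DoseResponse(doses, out, np.ones_like(doses, dtype=bool))
    outs, conv = zip(*(steady_state_output(params, a, method=method) for a in doses))
    return DoseResponse(doses, np.array(outs), np.array(conv))


# ---------------------------------------------------------------------------
# Model classes
# ---------------------------------------------------------------------------

class WTCModel:
    """Well-tempered controller circuit with steady-state dose-response output.

    ``n_Tup`` can be raised (e.g. to 5) to study increased cooperativity of
    constitutive repression while TetR keeps the shared Hill coefficient.
    """

    name = "wtc"
    variable_params = WTC_VARIABLE

    def __init__(self, n_Tet: float = WTC_FIXED["n"], n_Tup: float = WTC_FIXED["n"],
                 K_a: float = WTC_FIXED["K_a"], method: str = "fastpath"):
        self.n_Tet = n_Tet
        self.n_Tup = n_Tup
        self.K_a = K_a
        self.method = method

    def response(self, params, doses) -> DoseResponse:
        if not isinstance(params, IndividualParams):
            params = IndividualParams.from_dict(
                {k: v for k, v in dict(params).items()
                 if k in IndividualParams.__dataclass_fields__ or k == "n"})
        return dose_response(params, doses, method=self.method)

    def batch_response(self, p: dict, doses) -> np.ndarray:
        """(N, D) steady-state outputs; ``p`` maps param name -> scalar or (N,)."""
        return wtc_batch_steady_state(
            doses,
            k_Tet=p["k_Tet"], k_Tup=p["k_Tup"], k_C=p["k_C"],
            d_Tup=p["d_Tup"], d_Tet=p["d_Tet"], d_C=p["d_C"],
            theta_Tet=p["theta_Tet"], theta_Tup=p["theta_Tup"],
            n_Tet=p.get("n_Tet", self.n_Tet), n_Tup=p.get("n_Tup", self.n_Tup),
            K_a=p.get("K_a", self.K_a),
        )


def toy_model_output(k, d, a, a_half: float = 50.0, mode: str = "constant"):
    """Closed-form toy output: ``k/d`` (constant mode) or ``(k/d)*a/(a_half+a)``."""
    k = np.asarray(k, dtype=float)
    d = np.asarray(d, dtype=float)
    base = k / d
    if mode == "constant":
        return base * np.ones_like(np.asarray(a, dtype=float))
    if mode == "hill":
        a = np.asarray(a, dtype=float)
        return base * a / (a_half + a)
    raise ValueError(f"unknown toy mode {mode!r}")


class ToyModel:
    """Two-parameter production/degradation model with closed-form steady state.

    Serves as an analytic oracle: ``log(k/d)`` is normal under a log-normal
    population, so viability probabilities have closed forms.
    """

    name = "toy"
    variable_params = ("k", "d")

    def __init__(self, mode: str = "constant", a_half: float = 50.0):
        if mode not in ("constant", "hill"):
            raise ValueError(f"unknown toy mode {mode!r}")
        self.mode = mode
        self.a_half = a_half

    def response(self, params, doses) -> DoseResponse:
        doses = np.asarray(doses, dtype=float)
        out = toy_model_output(params["k"], params["d"], doses,
                               a_half=self.a_half, mode=self.mode)
        return DoseResponse(doses, out, np.ones_like(doses, dtype=bool))

    def batch_response(self, p: dict, doses) -> np.ndarray:
        doses = np.atleast_1d(np.asarray(doses, dtype=float))
        k = np.atleast_1d(np.asarray(p["k"], dtype=float)).reshape(-1, 1)
        d = np.atleast_1d(np.asarray(p["d"], dtype=float)).reshape(-1, 1)
        return toy_model_output(k, d, doses[np.newaxis, :],
                                a_half=self.a_half, mode=self.mode)


# ---------------------------------------------------------------------------
# Parameter-space layout
# ---------------------------------------------------------------------------

@dataclass
class ParamSpaceLayout:
    """Bounded box of sampled individual-parameter dimensions.

    ``names`` are the sampled dimensions; bounds are in natural units with a
    per-dimension log10 flag controlling the sampling scale.  ``fixed`` holds
    the values of non-sampled parameters; ``variable`` marks the cell-to-cell
    variable parameters of the population layer.
    """

    names: tuple
    lower: np.ndarray
    upper: np.ndarray
    log10: np.ndarray
    fixed: dict = field(default_factory=dict)
    variable: tuple = ()

    def __post_init__(self):
        self.names = tuple(self.names)
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.log10 = np.asarray(self.log10, dtype=bool)
        k = len(self.names)
        if not (self.lower.shape == self.upper.shape == self.log10.shape == (k,)):
            raise ValueError("bounds/log10 must match the number of sampled names")
        if not np.all(np.isfinite(self.lower) & np.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if not np.all(self.lower < self.upper):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def ndim(self) -> int:
        return len(self.names)

    def sampling_bounds(self):
        """(lower, upper) in sampling coordinates (log10 where flagged)."""
        lo = np.where(self.log10, np.log10(self.lower), self.lower)
        hi = np.where(self.log10, np.log10(self.upper), self.upper)
        return lo, hi

    def in_bounds(self, x) -> bool:
        lo, hi = self.sampling_bounds()
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= lo) & np.all(x <= hi))

    def to_natural(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return np.where(self.log10, 10.0 ** x, x)

    def to_sampling(self, values) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        return np.where(self.log10, np.log10(values), values)

    def params_from_vector(self, x) -> dict:
        """Full natural-units parameter dict from a sampling-coordinate vector."""
        nat = self.to_natural(x)
        out = dict(self.fixed)
        out.update(dict(zip(self.names, nat)))
        return out


def wtc_individual_layout(epsilon_free: bool = False) -> ParamSpaceLayout:
    """The 4-D sampled WTC space: (d_Tet, d_C, theta_Tet, theta_Tup), log10 scale.

    Degradation constants are bounded below by 3e-3 1/min (dilution by growth);
    other parameters are fixed to their estimated values.
    """
    return ParamSpaceLayout(
        names=("d_Tet", "d_C", "theta_Tet", "theta_Tup"),
        lower=np.array([3e-3, 3e-3, 1e-3, 1e-6]),
        upper=np.array([0.1, 0.1, 1e6, 20.0]),
        log10=np.array([True, True, True, True]),
        fixed={k: v for k, v in WTC_FIXED.items() if k != "n"}
        | {"n_Tet": WTC_FIXED["n"], "n_Tup": WTC_FIXED["n"]},
        variable=WTC_VARIABLE,
    )


def toy_individual_layout(k_bounds=(0.1, 10.0), d_bounds=(0.1, 10.0),
                          log10=True) -> ParamSpaceLayout:
    return ParamSpaceLayout(
        names=("k", "d"),
        lower=np.array([k_bounds[0], d_bounds[0]]),
        upper=np.array([k_bounds[1], d_bounds[1]]),
        log10=np.array([log10, log10]),
        fixed={},
        variable=("k", "d"),
    )


def get_model(name: str, **kw):
    """Model factory: ``"wtc"`` or ``"toy"``."""
    if name == "wtc":
        return WTCModel(**kw)
    if name == "toy":
        return ToyModel(**kw)
    raise ValueError(f"unknown model {name!r}")
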