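# Methods

This note documents the models, the numerical choices and the design
decisions behind `popdesign`, and what the bundled tests do and do not
establish.

## Individual-cell model

The well-tempered controller (WTC) is modeled by three ODEs for the total
concentrations of TetR (R_Tet), TetR-Tup1 (R_Tup) and Citrine (C), all in nM,
time in minutes:

    dR_Tet/dt = k_Tet / den − d_Tet · R_Tet
    dR_Tup/dt = k_Tup − d_Tup · R_Tup
    dC/dt     = k_C  / den − d_C · C

with the shared OR-gate repression term

    den = 1 + (f·R_Tet/θ_Tet)^n_Tet + (f·R_Tup/θ_Tup)^n_Tup .

The active (aTc-free) repressor fraction f follows from rapid-equilibrium
bimolecular binding of the inducer aTc (association constant K_a) to the
pooled repressors; it is the physical root of the binding quadratic,

    f = 1/2 − (1 + K_a·a − sqrt((1 + K_a(T − a))² + 4·K_a·a)) / (2·K_a·T),

with T = R_Tet + R_Tup. At T = 0 we use the continuous limit
f = 1/(1 + K_a·a) (the expression multiplies zero concentrations there, so
the convention is observationally irrelevant; it keeps f continuous and
satisfies f(a=0) = 1).

### Parameters

Fixed values (production nM/min, degradation 1/min): k_Tet = 1.12,
k_Tup = 0.79, k_C = 0.84, d_Tup = 1.28, Hill coefficient n = 1.57
(shared by both repression terms; `n_Tup` can be raised independently, e.g.
to 5, to study stronger constitutive-repression cooperativity),
K_a = 144.37 nM⁻¹, scaling constant U_sc = 0.76 nM/unit
(carried, not used in costs). Sampled parameters and box bounds, all explored
in log10: d_Tet, d_C ∈ [3e-3, 0.1] min⁻¹ (lower bound = dilution by growth),
θ_Tet ∈ [1e-3, 1e6] nM, θ_Tup ∈ [1e-6, 20] nM. The fitted estimates are
d_Tet = 0.0087, d_C = 0.006, θ_Tet = 0.006, θ_Tup = 5e-5.

### Steady states

Reference semantics: integrate from x⁰ = (0, 0, 0) nM (the model's steady
state is unique, so the choice of x⁰ is immaterial; this was verified against
the algebraic solution) to t = 2.5e7 min with LSODA (rtol 1e-10, atol 1e-12),
extending the horizon while the relative Citrine change over the trailing
500 min exceeds 1e-10, at most 10 extensions before flagging
non-convergence. Non-converged doses map to infinite individual cost rather
than aborting a run.

Fast path (default): at steady state R_Tup* = k_Tup/d_Tup exactly; R_Tet* is
the unique zero of the strictly decreasing residual
g(R) = k_Tet − d_Tet·R·den(R) on (0, k_Tet/d_Tet]; and Citrine reuses the
same denominator, C* = k_C/(d_C·den(R*)). The root is found by bisection in
log-concentration (the root can lie many decades below the unrepressed level
under strong repression): 52 halvings of a 36-ln-unit bracket leave ~1e-11
relative width. The whole computation is vectorized over (cells × doses),
which is what makes MCMC with embedded population sampling affordable in
pure NumPy. Agreement between the two routes is tested at 1e-6 relative
tolerance on 100 random parameter sets across the full box.

### Toy model

A closed-form fixture with output k/d (optionally (k/d)·a/(a_half+a)) makes
every downstream quantity analytic: under a log-normal population,
log(k/d) is normal, so viability probabilities and population costs have
closed forms. All sampler correctness tests (χ² against quadrature,
naive-sampler boundary checks) run on this model.

## Design objective

Reference behavior: the line through (0 nM, 0 nM) and (150 nM, 60 nM) —
slope 0.4, dose step 25 nM, i.e. 7 doses. Extended-input variants keep slope
and step and raise maxIDR to 300/450/600 nM (13/19/25 doses). The individual
cost is the RMS deviation over the grid; s = ε counts as viable (the
boundary is measure-zero; the indicator convention follows the viable-region
definition). Defaults: ε = 6 nM (≈10% of the target output range), stricter
variant ε = 3 nM; population threshold δ = 0.2.

## Population layer

The six cell-to-cell variable parameters {k_Tet, k_Tup, k_C, d_Tup, d_Tet,
d_C} are jointly log-normal. Table values are interpreted as exp(μ), i.e.
medians of the log-normal (at CV ≤ 10% the median/mean distinction is
< 0.5% and does not change any reported quantity materially). θ_Tet and
θ_Tup are sampled as zero-variance shared parameters. Covariance modes:
scalar σ²I (5 sampled dimensions: 4 means + common σ), diagonal (10
dimensions), full (supported, not exercised by the case study).

CV = sqrt(exp(σ²) − 1), inverse σ = sqrt(ln(1 + CV²)); for σ ≤ 0.1,
CV ≈ σ to < 0.6%.

σ coordinates are sampled in log10, like every other population parameter,
with CV ∈ [1e-3, 1]. The upper bound (CV = 1 ⇔ σ = sqrt(ln 2)) caps the
admissible variability; the lower bound is a choice — 0.1% cell-to-cell
variation is practically deterministic, three decades below the cap,
mirroring the generous style of the individual-parameter bounds. This
measure matters: the marginal mass the κ-tilted SLMCMC target places on
non-viable populations depends directly on how much room the σ prior gives
to near-zero variability (see "Known limitations").

The population-cost estimator ĉ(γ) uses N = 300 common random numbers
(CRN): a fixed block of standard-normal 6-vectors S_i, transformed per γ as
β_i = exp(μ + L·S_i) with L the lower Cholesky factor, so ĉ is a
deterministic, bit-stable function of γ. The CRN block is derived from the
run seed with a dedicated spawn key, so a sampler run and a later check that
share an integer seed share the block.

## Samplers

All four samplers use a Gaussian random walk in the sampling coordinates
(log10 where flagged). The proposal covariance is adapted Haario-style —
(2.38²/d)·Σ̂ from the chain history (earliest third discarded), with a
global scale factor nudged toward ~23% acceptance — every 200 iterations
during the first half of the run, then frozen so the retained half is
Markovian; the first half is discarded as burn-in before any downstream use.
Out-of-bounds proposals are rejected, except σ dimensions, which reflect
(fold) at their bounds in sampling coordinates.

* **Individual sampler**: indicator pseudo-likelihood 1(s ≤ ε); samples
  uniformly on the viable region. Initialization by vectorized rejection
  sampling of the box (budget 10,000 candidates).
* **Naive population sampler**: indicator 1(ĉ(γ) ≤ δ) with the CRN
  estimator; every retained sample satisfies the hard criterion under the
  run's CRN. Initialization: means at a viable individual point, σ small
  (0.005), retried until the criterion holds.
* **SLMCMC**: per step, propose γ′, then draw κ individuals from P_γ′; the
  conditional proposal cancels the density terms, and with a symmetric
  γ-proposal the acceptance probability is exactly Π 1(s(βⱼ) ≤ ε). The κ
  standard-normal blocks are drawn up front each step (fixed RNG stream
  consumption) and evaluated in one vectorized steady-state solve — the
  per-cell early stop that pays off with scalar ODE integrations is
  superseded by batching here. Only γ and the (always-one) indicator product
  are stored.
* **PT-SLMCMC**: r chains with κ₁ < … < κ_r; each iteration advances every
  chain one SLMCMC step, then attempts one swap between a uniformly chosen
  adjacent pair: κ′−κ fresh individuals from the lower chain's γ, swap
  accepted iff all viable (the closed-form indicator-product probability;
  equal-κ ladders swap for free). Only the κ_max chain is returned. Each
  chain has its own RNG stream and proposal adaptation; per-pair draw budget
  is κ₁+κ₂ for updates plus κ₂−κ₁ for the swap.

The paper-facing algorithmic listing of the swap schedule is not fully
specified anywhere; one adjacent-pair attempt per iteration is this
package's choice.

## Diagnostics

ESS per dimension uses Geyer's initial-positive-sequence truncation of the
autocovariance sum (FFT autocovariances; pair sums kept while positive).
Constant dimensions report ESS = chain length with a warning; antithetic
chains may legitimately report ESS > n. minESS is the minimum across
dimensions; sampling efficiency = minESS / retained samples; time ratios sum
run time and checking time. The Gelman–Rubin statistic is the classic
potential scale reduction factor (identical chains give sqrt((n−1)/n), not
exactly 1), with a 1.1 convergence cutoff. The a-posteriori check evaluates
ĉ on a regularly thinned subsample (default 600; uniform-random selection
available) and flags ĉ > δ.

## Study sizes and defaults

The bundled end-to-end computations use: 5,000 cells for the fitted-circuit
population cost at CV = 10% (Monte-Carlo s.d. ≈ 0.007); 50 random starts of
L-BFGS-B in log10 coordinates for the extended-input feasibility bound;
20,000-sample SLMCMC runs (κ = 3, scalar covariance) with the first half
discarded and 600 thinned samples re-checked with the N = 300 CRN estimator.
These sizes keep a full reproduction in the minutes range on one CPU while
leaving the Monte-Carlo error well inside the tolerances asserted in the
tests.

## Known limitations

* The a-posteriori rejected fraction of the κ = 3 sampler is sensitive to
  the σ-prior measure. Under the log10-σ measure with CV ∈ [1e-3, 1] the
  equilibrium value is 13–15% (stable across seeds, adaptation settings and
  200,000-sample runs); smaller reported values would require either a much
  wider σ prior toward zero variability or a sampler that under-explores the
  high-σ region. The CV ceilings and all other headline quantities are
  robust to this choice.
* The synthetic populations are exactly log-normal with independent (scalar/
  diagonal) components; real cell populations have correlated parameters,
  and negative correlations would admit higher CVs than the ceilings
  reported here. Passing tests show correctness of the machinery and
  reproduction of the case-study geometry, not realism of any particular
  biological variability structure.
* MCMC efficiency degrades with dimension; the diagonal-covariance (10-D)
  problem roughly halves minESS relative to the scalar case. Chains should
  always be judged with the bundled ESS/R̂ diagnostics rather than sample
  counts.
* SBML import/export, stochastic kinetics, and NLME inference of γ from
  single-cell data are out of scope.
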