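# Methods

## Model

A k-dimensional biomarker `Y(t)` evolves as a mean-reverting linear
diffusion, `dY = a(t)(Y − f1(t))dt + b dW`, and mortality follows the
quadratic hazard `μ(t, Y) = μ0(t) + (Y − f(t))ᵀ Q(t) (Y − f(t))`. The
biological reading of the coefficients: `a` (per year, eigenvalues expected
negative) is the homeostatic feedback rate — how fast a perturbed biomarker
returns to its long-term mean; `f1` (biomarker units) is the allostatic
trajectory the process actually reverts to; `f` (biomarker units) is the
risk-minimizing norm, generally different from `f1`; `Q`
(1/(biomarker² · year)) sets the curvature of the U-shaped risk — larger
`Q` means less tolerance for deviations; `μ0` (1/year) is the hazard on the
optimal trajectory; when `θ ≠ 0`, both `μ0` and `Q` are multiplied by
`e^{θt}` so baseline risk grows Gompertz-like with age (doubling time
`log 2/θ`).

The discrete-time variant replaces the diffusion by the one-step
autoregression `Y(t+1) = u + R Y(t) + ε`, `ε ~ N(0, diag(Σ²))`, with the
per-interval death probability `1 − exp(−μ(t, Y(t))·Δt)`. For unit
intervals the two coefficient sets are linked exactly by `a = R − I`,
`f1 = −a⁻¹u`, `b = Σ`, `f = −½Q⁻¹b_d`, `μ0_c = μ0_d − fᵀQf`, `θ_c = θ_d`;
`quadhaz.params` implements the map and its inverse and refuses non-unit
steps rather than silently mis-converting.

## Likelihood (continuous time)

Between measurements the conditional law of `Y` among survivors stays
Gaussian; its moments obey the ODEs given in the README and the marginal
hazard is `μ̄ = μ0 + (m−f)ᵀQ(m−f) + Tr(Qγ)`. A subject contributes

* the Gaussian log-density of each observation `y_j` under
  `N(m(t_j⁻), γ(t_j⁻))`,
* `δ·log μ̄(τ)` if follow-up ends in death at `τ`,
* `−∫ μ̄ du` from the first observation to `τ`.

Measurements are treated as exact: after each observation the state resets
to `m := y_j`, `γ := 0`. The first observation per subject is scored under
the population initial law, estimated once as the sample mean and covariance
of first observations; because that law is not a function of the model
parameters the term is a constant added to the reported log-likelihood, not
part of the optimization. (Consequence: the slope of a time-dependent `f1`
is identified only through the transition densities and the survival terms,
not through the initial values — see “Identifiability” below.)

## Numerics

* **Integrator.** Fixed-substep classical RK4 with
  `h = min(0.05 yr, interval/4)`, rounded so each interval lands exactly on
  its endpoint. Fixed steps are chosen over adaptive control for bit-level
  reproducibility; adequacy is enforced by a test that halving the substep
  changes a 100-subject log-likelihood by ≤ 1e−6. `γ` is re-symmetrized
  after every step.
* **Fast path.** The per-interval independence created by the
  exact-observation reset lets all intervals integrate in parallel. For
  k = 1 a numba-compiled kernel does this; a vectorized numpy
  implementation is the reference and fallback, and a test asserts the two
  agree with the per-subject ODE evaluation to ~1e−13.
* **Optimizer.** Nelder–Mead (scipy), coordinates scaled by `max(|x0|, 1)`
  so curvatures ~1e−6 and means ~1e2 move on comparable scales, one restart
  from the optimum, convergence at relative simplex spread 1e−6.
  Positivity is enforced by searching `log μ0` and a Cholesky factor of
  `Q`; `b` enters only as `b²` and is reported as `|b|`. Linear-in-age
  coefficients are searched as (value at the mean observation age, slope) —
  a pure reparameterization that removes the intercept/slope collinearity;
  the reported intercept is the value at age 0.
* **Starting values.** Discrete-time fit of the same data (OLS dynamics; a
  log-link binomial GLM provides the Gompertz-rate start, a least-squares
  projection of `event·e^{−θ0 t}/Δt` on `[1, y, quad(y)]` the hazard-bracket
  start), converted to the continuous set; slopes start at 0. The exact
  Bernoulli likelihood is always re-maximized — the GLM cannot represent
  the bracketed quadratic hazard and is never the reported estimator.
* **Degenerate inputs.** Death probabilities are clamped to
  `[1e−12, 1−1e−12]` during the discrete search (equivalently the
  cumulative hazard is clamped), so transiently negative hazards are
  penalized, not fatal; the final fit is checked for nonnegativity over the
  observed covariate range and warns otherwise. Singular `γ(t⁻)` or
  nonpositive `μ̄` at a death time yield −∞ likelihood and the simplex
  retreats.

## Data preparation

Input is a long-format visit table (id, death indicator, age, next age,
covariates measured at age). Preparation produces native-interval pairs
(continuous-time estimator) and a fixed-grid resampling (discrete-time
estimator): the grid is anchored at each subject's own first visit,
covariates are linearly interpolated between observed visits and never
extrapolated, and the terminal (death or exactly-censored) interval carries
the event flag with no end-of-interval measurement. Interior missing
covariate values are filled by within-subject linear interpolation when
imputation is on; leading/trailing gaps are dropped. Event counts are never
invented: each subject contributes at most its one observed death.

## Simulator

The simulator is the model run forward, and defines the verification
conditions used throughout the tests: cohorts start at age 30 (default)
with `Y0 ~ N(f1(t_start), σ0²)`, `σ0 = 1`; visits are yearly, either fixed
or jittered by ±10% of the step; continuous-time dynamics advance by
Euler–Maruyama with a 0.01-year substep and the interval survival uses the
trapezoid rule on the same substeps, so hazard and dynamics share one
discretization; deaths are recorded at the interval end, with no
within-interval refinement; censoring occurs at `t_max` (default 105) or
after an optional visit cap. The random stream order (initial values; then
per interval: jitter, survival uniform, dynamics noise) is fixed, so a seed
pins the output byte-for-byte.

What the generator does **not** emulate about real cohort data: measurement
error on covariates, staggered/late entry, informative visit schedules,
missingness mechanisms beyond interior gaps, competing risks, or
between-subject parameter heterogeneity. Passing recovery tests therefore
demonstrate correctness of the estimators under the model's own assumptions,
not robustness to their violation.

## Recovery studies and problem sizes

The test suite re-runs the three published-design recovery studies at sizes
chosen to keep the default run practical: 1D and 2D discrete-time, 20
replicates × 5,000 subjects each (the original studies used 100
replicates); time-dependent `f1(t) = f1a + f1b·t`, 10 replicates × 1,000
subjects (original 100 × 5,000). Replicate means are compared against the
published empirical confidence intervals.

**Identifiability at reduced size.** With 1,000 subjects and ~90% yearly
mortality in the time-dependent design, the profile likelihood is nearly
flat in `Q` over [1e−6, 1e−4] (with `μ0` compensating), and `f` is
essentially unidentified — their estimates scatter widely while `a`, `f1a`,
`f1b` and `b` remain informative; the recovery test asserts only the
informative set. The slope `f1b` is the borderline case: under the
exact-observation reset its information comes from ~10 one-year transitions
per subject over a ~6-year effective age spread, giving a per-replicate
sampling SD near 0.08 at this size, so the 10-replicate mean has an SE
(~0.025) comparable to the published CI half-width; single replicates at
5,000 subjects center on the truth (0.107, 0.088 on two seeds around 0.1).
Replicate seeds are fixed in the test file.

**A note on the 2D interval widths.** The published 2D table's intervals
are as narrow as ±2·SD/√100 (intervals for the *mean* of that study's 100
replicates), unlike the 1D tables whose intervals are ±2SD percentile bands
of single estimates. An independent 20-replicate mean has an SE about
twice such a half-width, so individual parameters can fall outside those
bands by sampling noise alone even for an exact re-implementation; the 2D
test nevertheless uses the published bands unchanged.

## Design choices

* Kaplan–Meier estimation and Greenwood confidence bands delegate to
  lifelines; age-binned covariate means among subjects under observation
  use the simulation step as bin width.
* The fixed-interval conversion step must be exactly 1 year; `fit_discrete`
  infers the step from the data's median interval.
* Death probability in the discrete model uses the hazard at the interval
  start — the covariate at death is unobserved.
* `Q` is symmetrized by construction (off-diagonal design columns enter
  doubled), matching the symmetric printed estimates.
* Optional SAS (`.sas7bdat`) ingestion reuses the CSV loader contract via
  pandas.

## Limitations

One-dimensional only for time-dependent coefficients (linear-in-age forms);
no measurement-error observation model; no random effects, hidden
heterogeneity, multi-state outcomes or competing risks; conversion between
parameterizations is defined for constant coefficients and unit steps only.
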