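# quadhaz

Joint modelling of longitudinal biomarker trajectories and mortality with
**quadratic-hazard stochastic process models** (SPM): a biomarker
`Y(t)` (blood pressure, body-mass index, blood glucose, ...) follows a
mean-reverting stochastic process, and the hazard of death is a quadratic
(U-shaped) function of its deviation from an optimal trajectory. The
framework is used in aging research to estimate biologically interpretable
quantities — adaptive capacity, the allostatic (long-term mean) trajectory,
the physiological norm and stress resistance — jointly from repeated
measurements and survival follow-up.

The package is aimed at biostatisticians and epidemiologists analysing
long-format follow-up tables (one row per visit interval with a death
indicator), and at methodologists who need a transparent simulation and
parameter-recovery engine for this model class.

## The model

Continuous-time form: the biomarker follows the mean-reverting diffusion

    dY(t) = a(t) (Y(t) − f1(t)) dt + b dW(t),

and the conditional hazard of death is

    μ(t, Y) = μ0(t) + (Y − f(t))ᵀ Q(t) (Y − f(t)),

with `a` the negative-feedback (adaptive-capacity) matrix, `f1` the mean
allostatic trajectory, `f` the risk-minimizing physiological norm, `Q` the
hazard curvature (stress resistance), and optionally
`μ0(t) = μ0·e^{θt}`, `Q(t) = Q·e^{θt}` (Gompertz aging of the baseline
risk). Between measurements, the mean `m(t)` and covariance `γ(t)` of the
biomarker among survivors obey

    dm/dt = a(m − f1) − 2 γ Q (m − f),
    dγ/dt = a γ + γ aᵀ + b bᵀ − 2 γ Q γ,

and the likelihood of a subject's data combines Gaussian densities of each
observation under `N(m(t⁻), γ(t⁻))`, the marginal hazard
`μ̄ = μ0 + (m−f)ᵀQ(m−f) + Tr(Qγ)` at death, and `exp(−∫ μ̄ du)` for
survival (observations reset the state exactly: `m := y`, `γ := 0`).

Discrete-time form (fixed 1-year visits): `Y(t+1) = u + R Y(t) + ε`,
`μ(t, Y) = [μ0 + bᵀY + YᵀQY]·e^{θt}`; the two coefficient sets are
algebraically equivalent (`a = R − I`, `f1 = −a⁻¹u`, `f = −½Q⁻¹b_d`, ...)
and the package converts between them exactly.

Three estimators are provided:

* `fit_discrete` — autoregression by OLS plus exact Bernoulli maximum
  likelihood for the hazard (a log-link binomial GLM supplies starting
  values); returns both parameterizations;
* `fit_continuous` — moment-ODE maximum likelihood for arbitrary
  (e.g. jittered) visit intervals, any number of covariates;
* `fit_time_dependent` — the one-covariate variant with linear-in-age
  coefficients, e.g. `f1(t) = f1a + f1b·t`.

Plus a cohort simulator (`simulate_cohort`, the verification engine) and
projections (`project`: Kaplan–Meier survival with Greenwood bands and
age-specific covariate means).

## Worked example

Simulate a 5,000-subject cohort under a known truth (adaptive capacity
a = −0.05/yr, allostatic mean f1 = 80, norm f = 80, curvature Q = 1e−6,
diffusion b = 5, baseline hazard μ0 = 1e−5 growing at θ = 0.1/yr), prepare
it, and re-estimate:

```python
import quadhaz as q

truth = q.ContinuousParams(a=[[-0.05]], f1=[80.0], b=[5.0], mu0=1e-5,
                           f=[80.0], Q=[[1e-6]], theta=0.1)
plan = q.SimulationPlan(n_subjects=5000, t_start=30.0, seed=42)
cohort = q.simulate_cohort(q.continuous_to_discrete(truth), plan)
fixed, arbitrary = q.prepare_data(cohort, interval=1.0)
d, c = q.fit_discrete(fixed)
print(f"a  = {c.a[0,0]:+.4f}   (truth -0.0500)")
print(f"f1 = {c.f1[0]:7.3f}   (truth 80.000)")
print(f"Q  = {c.Q[0,0]:.3e} (truth 1.000e-06)")
print(f"f  = {c.f[0]:7.3f}   (truth 80.000)")
print(f"b  = {c.b[0]:+.4f}   (truth +5.0000)")
print(f"mu0= {c.mu0:.3e} (truth 1.000e-05)")
print(f"th = {c.theta:+.4f}   (truth +0.1000)")
```

prints

```
a  = -0.0489   (truth -0.0500)
f1 =  79.975   (truth 80.000)
Q  = 9.422e-07 (truth 1.000e-06)
f  =  79.859   (truth 80.000)
b  = +5.0056   (truth +5.0000)
mu0= 9.161e-06 (truth 1.000e-05)
th = +0.1009   (truth +0.1000)
```

— a single replicate recovers every coefficient to within its sampling
error: the organism reverts to its allostatic mean at ~5%/yr, the mortality
minimum sits at the norm 80, and baseline mortality doubles roughly every
7 years (log 2/θ). The same workflow is available from the shell:

```bash
quadhaz prepare --input cohort.csv --interval 1 --output-prefix prep
quadhaz fit --model discrete --data prep_fixed.csv --out fit.json
quadhaz project --params fit.json --n 5000 --tstart 30 --mean0 80 \
        --seed 1 --summary-out projection.csv
```

## Layout

- `quadhaz.data` — long-format table I/O, validation, interval pairing
  (fixed-grid resampling by linear interpolation, native-interval pairs)
- `quadhaz.params` — both coefficient sets + exact conversion
- `quadhaz.discrete` — discrete-time estimator
- `quadhaz.continuous` — moment-ODE likelihood and continuous-time /
  time-dependent fits
- `quadhaz.simulate` — cohort simulation, Kaplan–Meier, projections
- `quadhaz.cli` — `quadhaz prepare|fit|simulate|project`

See `docs/methods.md` for the modelling and numerical details.
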