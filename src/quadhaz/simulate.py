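"""Cohort simulation under the model and survival/trajectory projections.

Simulation follows the generating process the estimators assume: initial
covariates drawn from ``N(f1(t_start), sigma0^2)``; per interval, the
conditional survival probability ``S = exp(−∫ mu ds)`` (continuous-time
dynamics, trapezoid rule on the Euler–Maruyama substeps) or
``S = exp(−mu(t, Y(t))·dt)`` (discrete-time) is compared against a uniform
draw — the subject dies at the interval end if the draw exceeds S — and
survivors advance either by the autoregression or by Euler–Maruyama with an
internal 0.01-year substep.  Observation intervals are either fixed at
``step`` or jittered uniformly within ±10% of it.

The random number stream is consumed in a fixed order (all initial values,
then per interval: jitter, survival uniforms, dynamics noise), so a seed
pins the output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LongitudinalRecords
from .errors import SimulationError
from .params import ContinuousParams, DiscreteParams

__all__ = [
    "SimulationPlan",
    "ProjectionSummary",
    "simulate_cohort",
    "project",
    "kaplan_meier",
]

_EM_SUBSTEP = 0.01  # years; Euler–Maruyama internal step


@dataclass
class SimulationPlan:
    """Observational plan of a simulated cohort."""

    n_subjects: int
    t_start: float = 30.0
    t_max: float = 105.0
    step: float = 1.0
    mode: str = "fixed"           # "fixed" or "jittered"
    sigma0: float | np.ndarray = 1.0
    max_obs_per_subject: int | None = None
    seed: int = 0

    def __post_init__(self):
        self.n_subjects = int(self.n_subjects)
        self.t_start = float(self.t_start)
        self.t_max = float(self.t_max)
        self.step = float(self.step)
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.t_max > self.t_start:
            raise ValueError(f"t_max ({self.t_max}) must exceed t_start ({self.t_start})")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.mode not in ("fixed", "jittered"):
            raise ValueError(f"mode must be 'fixed' or 'jittered', got {self.mode!r}")


@dataclass
class ProjectionSummary:
    """Survival curve and age-specific covariate means of a projected cohort."""

    ages: np.ndarray
    survival: pd.DataFrame      # age, survival, lower, upper, n_at_risk
    mean_by_age: pd.DataFrame   # age, n_at_risk, <covariate means>
    n_at_risk: np.ndarray


def _default_y0_mean(params, t_start: float) -> np.ndarray:
    if isinstance(params, ContinuousParams):
        return np.atleast_1d(params.coeff_at("f1", t_start))
    return np.linalg.solve(np.eye(params.k) - params.R, params.u)


def simulate_cohort(params, plan: SimulationPlan, *,
                    y0_mean=None, y0_sd=None,
                    covariate_names=None) -> LongitudinalRecords:
    """Simulate a follow-up cohort under the model.

    ``params`` selects the dynamics: :class:`DiscreteParams` advances by the
    autoregression with per-interval survival ``exp(−mu·dt)``;
    :class:`ContinuousParams` integrates the SDE by Euler–Maruyama and the
    hazard integral by the trapezoid rule on the same substeps.  Death times
    are recorded at the interval end.  Deterministic under ``plan.seed``.
    """
    rng = np.random.default_rng(plan.seed)
    k = params.k
    names = list(covariate_names) if covariate_names else [f"y{i + 1}" for i in range(k)]
    mean0 = (np.atleast_1d(np.asarray(y0_mean, float)) if y0_mean is not None
             else _default_y0_mean(params, plan.t_start))
    sd0 = np.broadcast_to(np.atleast_1d(np.asarray(
        y0_sd if y0_sd is not None else plan.sigma0, float)), (k,))
    n = plan.n_subjects
    Y = mean0 + sd0 * rng.standard_normal((n, k))

    discrete = isinstance(params, DiscreteParams)
    rows_id, rows_ev, rows_t1, rows_t2 = [], [], [], []
    rows_y = []
    alive = np.arange(n)
    t_cur = np.full(n, plan.t_start)
    n_obs = np.zeros(n, dtype=int)

    if discrete:
        theta, mu0, bvec, Q = params.theta, params.mu0, params.b, params.Q
    else:
        theta, mu0 = params.theta, params.mu0

    while len(alive):
        ya = Y[alive]
        ta = t_cur[alive]
        # interval lengths (jitter drawn first)
        if plan.mode == "jittered":
            dt = plan.step + rng.uniform(-0.1 * plan.step, 0.1 * plan.step, len(alive))
        else:
            dt = np.full(len(alive), plan.step)
        r = rng.uniform(size=len(alive))
        if discrete:
            bracket = mu0 + ya @ bvec + np.einsum("ni,ij,nj->n", ya, Q, ya)
            mu = np.maximum(bracket * np.exp(theta * ta), 0.0)
            cumhaz = mu * dt
            y_next = (params.u + ya @ params.R.T
                      + params.Sigma * rng.standard_normal(ya.shape))
        else:
            y_next, cumhaz = _advance_sde(params, ya, ta, dt, rng)
        if not np.isfinite(y_next).all():
            bad = alive[~np.isfinite(y_next).all(axis=1)][0]
            raise SimulationError(
                f"non-finite trajectory for subject {bad} near t={ta.max():.2f}")
        died = r > np.exp(-cumhaz)
        t_next = ta + dt
        rows_id.append(alive)
        rows_ev.append(died.astype(int))
        rows_t1.append(ta)
        rows_t2.append(t_next)
        rows_y.append(ya)
        n_obs[alive] += 1
        censored = (t_next >= plan.t_max - 1e-9)
        if plan.max_obs_per_subject is not None:
            censored |= n_obs[alive] >= plan.max_obs_per_subject
        keep = ~(died | censored)
        Y[alive[keep]] = y_next[keep]
        t_cur[alive] = t_next
        alive = alive[keep]

    frame = pd.DataFrame({
        "id": np.concatenate(rows_id),
        "event": np.concatenate(rows_ev),
        "t1": np.concatenate(rows_t1),
        "t2": np.concatenate(rows_t2),
    })
    ymat = np.concatenate(rows_y, axis=0)
    for j, c in enumerate(names):
        frame[c] = ymat[:, j]
    return LongitudinalRecords(frame=frame, covariate_names=names)


def _advance_sde(params: ContinuousParams, y: np.ndarray, t0: np.ndarray,
                 dt: np.ndarray, rng) -> tuple:
    """One observation interval of Euler–Maruyama dynamics.

    Returns the covariates at the interval end and the per-subject hazard
    integral ``∫ mu(s, Y(s)) ds`` accumulated by the trapezoid rule on the
    same substeps (hazard clamped at 0).
    """
    n, k = y.shape
    nh = np.maximum(np.round(dt / _EM_SUBSTEP).astype(int), 1)
    h = dt / nh
    theta = params.theta
    sa, sf1, sQ, sf = (params.slope(nm) for nm in ("a", "f1", "Q", "f"))

    def hazard(tt, yy):
        Q_t = params.Q + sQ * tt[:, None, None] if sQ else params.Q
        f_t = params.f + sf * tt[:, None] if sf else params.f
        d = yy - f_t
        if sQ:
            quad = np.einsum("ni,nij,nj->n", d, Q_t, d)
        else:
            quad = np.einsum("ni,ij,nj->n", d, params.Q, d)
        mu = params.mu0 + quad
        if theta:
            mu = mu * np.exp(theta * tt)
        return np.maximum(mu, 0.0)

    acc = np.zeros(n)
    t = t0.copy()
    prev_mu = hazard(t, y)
    y = y.copy()
    for s in range(int(nh.max())):
        hs = np.where(s < nh, h, 0.0)
        if k == 1 and (sa or sf1):
            a_t = params.a[0, 0] + sa * t
            f1_t = params.f1[0] + sf1 * t
            y = y + (a_t * (y[:, 0] - f1_t) * hs)[:, None]
        else:
            y = y + ((y - params.f1) @ params.a.T) * hs[:, None]
        y = y + params.b * np.sqrt(hs)[:, None] * rng.standard_normal((n, k))
        t = t + hs
        mu = hazard(t, y)
        acc += 0.5 * (prev_mu + mu) * hs
        prev_mu = mu
    return y, acc


def kaplan_meier(times, events) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood 95% confidence band.

    Returns a frame with columns ``time, survival, lower, upper, n_at_risk``
    at the distinct observed times (lifelines backend).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if len(times) == 0:
        raise ValueError("kaplan_meier requires at least one observation")
    if times.min() <= 0:
        raise ValueError("times must be positive")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    sf = kmf.survival_function_
    ci = kmf.confidence_interval_
    at_risk = kmf.event_table["at_risk"].reindex(sf.index)
    out = pd.DataFrame({
        "time": sf.index.to_numpy(float),
        "survival": sf.iloc[:, 0].to_numpy(float),
        "lower": ci.iloc[:, 0].to_numpy(float),
        "upper": ci.iloc[:, 1].to_numpy(float),
        "n_at_risk": at_risk.to_numpy(float),
    })
    return out.reset_index(drop=True)


def project(params, plan: SimulationPlan, initial_mean, initial_sd=None):
    """Simulate a cohort with a chosen initial covariate law and summarize it.

    Returns ``(LongitudinalRecords, ProjectionSummary)``: the simulated
    trajectories, the Kaplan–Meier survival curve (ages on the original
    scale) and per-age-bin covariate means among subjects still under
    observation.
    """
    records = simulate_cohort(params, plan, y0_mean=initial_mean,
                              y0_sd=initial_sd)
    df = records.frame
    last = df.groupby("id", sort=False).tail(1)
    durations = last["t2"].to_numpy(float) - plan.t_start
    events = last["event"].to_numpy(int)
    km = kaplan_meier(durations, events)
    km["age"] = plan.t_start + km["time"]
    km = km[["age", "survival", "lower", "upper", "n_at_risk"]]

    bins = np.floor((df["t1"].to_numpy(float) - plan.t_start) / plan.step + 1e-9)
    tmp = df[records.covariate_names].copy()
    tmp["_bin"] = bins
    agg = tmp.groupby("_bin").agg(["mean", "size"])
    bin_idx = agg.index.to_numpy(float)
    ages = plan.t_start + bin_idx * plan.step
    counts = agg[(records.covariate_names[0], "size")].to_numpy(int)
    mean_by_age = pd.DataFrame({"age": ages, "n_at_risk": counts})
    for c in records.covariate_names:
        mean_by_age[c] = agg[(c, "mean")].to_numpy(float)
    summary = ProjectionSummary(ages=ages, survival=km,
                                mean_by_age=mean_by_age, n_at_risk=counts)
    return records, summary
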