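"""Continuous-time model: moment-ODE likelihood and maximum-likelihood fits.

Between measurements the conditional distribution of the biomarker among
survivors stays Gaussian; its mean ``m(t)`` and covariance ``gamma(t)``
follow the coupled ODEs

    dm/dt     = a(t)(m − f1(t)) − 2 gamma Q(t) (m − f(t))
    dgamma/dt = a(t) gamma + gamma a(t)ᵀ + b bᵀ − 2 gamma Q(t) gamma

and the marginal hazard among survivors is

    mubar(t) = mu0(t) + (m − f(t))ᵀ Q(t) (m − f(t)) + Tr(Q(t) gamma).

Each subject's log-likelihood is the sum of Gaussian log-densities of the
observed values under ``N(m(t⁻), gamma(t⁻))`` — the state is reset to the
exact observation (``m := y``, ``gamma := 0``) after each measurement — plus
``delta·log mubar(tau)`` and minus the accumulated hazard integral.

Integration is fixed-substep classical Runge–Kutta (RK4) with substep
``h = min(0.05 years, interval/4)``: reproducible, and accurate to well below
optimizer noise at these time scales (see the substep-halving test).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from . import _fast1d
from .data import LongitudinalRecords, PairedObservations
from .errors import (ConvergenceError, EstimationError, NumericalError,
                     UnsupportedConfigurationError, ValidationError)
from .optim import nelder_mead
from .params import ContinuousParams, DiscreteParams, discrete_to_continuous

__all__ = [
    "CoefficientFunction",
    "MomentState",
    "SPMFit",
    "marginal_hazard",
    "propagate_moments",
    "subject_log_likelihood",
    "total_log_likelihood",
    "fit_continuous",
    "fit_time_dependent",
]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class CoefficientFunction:
    """Linear-in-time coefficient ``base + slope·t`` (slope 0 = constant)."""

    base: float | None = None
    slope: float = 0.0

    def __call__(self, t):
        if self.base is None:
            raise ValueError("CoefficientFunction has no base value")
        return self.base + self.slope * t


@dataclass
class MomentState:
    """Conditional mean, covariance and accumulated hazard integral."""

    m: np.ndarray
    gamma: np.ndarray
    H: float = 0.0

    def __post_init__(self):
        self.m = np.atleast_1d(np.asarray(self.m, dtype=float))
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim == 0:
            g = g.reshape(1, 1)
        self.gamma = g
        self.H = float(self.H)

    @property
    def k(self) -> int:
        return self.m.shape[0]


def marginal_hazard(params: ContinuousParams, state: MomentState, t: float) -> float:
    """Hazard averaged over the conditional biomarker law among survivors."""
    if state.k != params.k:
        raise ValueError(f"state dimension {state.k} != parameter dimension {params.k}")
    Q_t = params.coeff_at("Q", t)
    mu0_t = params.coeff_at("mu0", t)
    d = state.m - params.coeff_at("f", t)
    return float(mu0_t + d @ Q_t @ d + np.sum(Q_t * state.gamma))


# ---------------------------------------------------------------------------
# single-state RK4 (reference path, any k)


def _rhs_single(params: ContinuousParams, bbT: np.ndarray, t: float,
                m: np.ndarray, g: np.ndarray):
    a_t = params.coeff_at("a", t)
    f1_t = params.coeff_at("f1", t)
    Q_t = params.coeff_at("Q", t)
    f_t = params.coeff_at("f", t)
    mu0_t = params.coeff_at("mu0", t)
    d = m - f_t
    Qd = Q_t @ d
    dm = a_t @ (m - f1_t) - 2.0 * (g @ Qd)
    gQ = g @ Q_t
    dg = a_t @ g + g @ a_t.T + bbT - 2.0 * (gQ @ g)
    dH = mu0_t + float(d @ Qd) + float(np.sum(Q_t * g))
    return dm, dg, dH


def _n_substeps(dt: float, h_max: float) -> int:
    h0 = min(h_max, dt / 4.0)
    return max(1, int(math.ceil(dt / h0 - 1e-9)))


def propagate_moments(params: ContinuousParams, state0: MomentState,
                      t0: float, t1: float, h_max: float = 0.05) -> MomentState:
    """Integrate the moment ODEs plus ``dH/dt = mubar`` from t0 to t1⁻.

    Classical RK4 with fixed substep ``h = min(h_max, (t1−t0)/4)`` (the
    substep count is rounded so the integration lands exactly on ``t1``).
    """
    if not t1 > t0:
        raise ValueError(f"t1 must exceed t0, got [{t0}, {t1}]")
    if state0.k != params.k:
        raise ValueError("state dimension does not match parameters")
    bbT = np.outer(params.b, params.b)
    n = _n_substeps(t1 - t0, h_max)
    h = (t1 - t0) / n
    m = state0.m.copy()
    g = state0.gamma.copy()
    H = state0.H
    t = t0
    for _ in range(n):
        k1m, k1g, k1H = _rhs_single(params, bbT, t, m, g)
        k2m, k2g, k2H = _rhs_single(params, bbT, t + h / 2, m + h / 2 * k1m, g + h / 2 * k1g)
        k3m, k3g, k3H = _rhs_single(params, bbT, t + h / 2, m + h / 2 * k2m, g + h / 2 * k2g)
        k4m, k4g, k4H = _rhs_single(params, bbT, t + h, m + h * k3m, g + h * k3g)
        m = m + h / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m)
        g = g + h / 6.0 * (k1g + 2 * k2g + 2 * k3g + k4g)
        g = 0.5 * (g + g.T)
        H = H + h / 6.0 * (k1H + 2 * k2H + 2 * k3H + k4H)
        t += h
        if not (np.isfinite(m).all() and np.isfinite(g).all() and np.isfinite(H)):
            raise NumericalError(f"moment ODE integration blew up at t={t:.4f}", t=t)
    return MomentState(m=m, gamma=g, H=H)


def _gauss_logpdf(y: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> float:
    k = y.shape[0]
    if k == 1:
        v = cov[0, 0]
        if v <= 0:
            raise EstimationError("singular conditional covariance gamma(t-)")
        return -0.5 * (_LOG2PI + math.log(v) + (y[0] - mean[0]) ** 2 / v)
    sign, logdet = np.linalg.slogdet(cov)
    if sign <= 0:
        raise EstimationError("singular conditional covariance gamma(t-)")
    r = y - mean
    return float(-0.5 * (k * _LOG2PI + logdet + r @ np.linalg.solve(cov, r)))


def subject_log_likelihood(params: ContinuousParams, subject,
                           t_start: float | None = None,
                           initial_law: tuple | None = None,
                           h_max: float = 0.05) -> float:
    """Log-likelihood contribution of one subject.

    ``subject`` is a single-subject :class:`LongitudinalRecords` or a frame
    with the canonical columns.  ``initial_law = (m0, gamma0)`` is the
    population law of the first observation; when given, the first value
    contributes its Gaussian log-density under that law (propagated from
    ``t_start`` if that precedes the first observation).  The hazard
    integral runs from the first observation (or ``t_start``) to the
    lifespan/censoring age ``tau``.
    """
    df = subject.frame if isinstance(subject, LongitudinalRecords) else subject
    if df["id"].nunique() != 1:
        raise ValueError("subject_log_likelihood expects a single subject")
    names = (subject.covariate_names if isinstance(subject, LongitudinalRecords)
             else [c for c in df.columns if c not in ("id", "event", "t1", "t2")])
    times = df["t1"].to_numpy(float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("observation times must be strictly increasing")
    Y = df[names].to_numpy(float)
    tau = float(df["t2"].to_numpy(float)[-1])
    delta = int(df["event"].to_numpy()[-1])
    if tau < times[-1]:
        raise ValidationError("tau precedes the last observation time")

    ll = 0.0
    H_total = 0.0
    if initial_law is not None:
        m0, g0 = initial_law
        m0 = np.atleast_1d(np.asarray(m0, float))
        g0 = np.atleast_2d(np.asarray(g0, float))
        if t_start is not None and t_start < times[0] - 1e-12:
            st = propagate_moments(params, MomentState(m0, g0), t_start, times[0], h_max)
            ll += _gauss_logpdf(Y[0], st.m, st.gamma)
            H_total += st.H
        else:
            ll += _gauss_logpdf(Y[0], m0, g0)
    state = MomentState(Y[0], np.zeros((params.k, params.k)))
    for j in range(1, len(times)):
        st = propagate_moments(params, state, times[j - 1], times[j], h_max)
        ll += _gauss_logpdf(Y[j], st.m, st.gamma)
        H_total += st.H
        state = MomentState(Y[j], np.zeros((params.k, params.k)))
    if tau > times[-1] + 1e-12:
        st = propagate_moments(params, state, times[-1], tau, h_max)
        H_total += st.H
        state = MomentState(st.m, st.gamma)
    if delta:
        mubar = marginal_hazard(params, state, tau)
        if mubar <= 0:
            return -np.inf
        ll += math.log(mubar)
    return ll - H_total


# ---------------------------------------------------------------------------
# flattened-row likelihood (fast path used by the fitters)


@dataclass
class _Rows:
    t1: np.ndarray
    t2: np.ndarray
    y1: np.ndarray      # (N, k)
    y2: np.ndarray      # (N, k), NaN where unobserved
    death: np.ndarray   # (N,) bool
    has_y2: np.ndarray  # (N,) bool


def _rows_from_arrays(t1, t2, y1, y2, death) -> _Rows:
    ok = np.isfinite(y1).all(axis=1)
    t1, t2, y1, y2, death = (x[ok] for x in (t1, t2, y1, y2, death))
    has_y2 = np.isfinite(y2).all(axis=1)
    return _Rows(t1=t1, t2=t2, y1=y1, y2=y2,
                 death=death.astype(bool), has_y2=has_y2)


def _build_rows(data):
    """Returns (rows, y_first (n_subj, k), k, names)."""
    if isinstance(data, PairedObservations):
        rows = _rows_from_arrays(data.t1, data.t2, data.y1, data.y2,
                                 data.case.astype(bool))
        firsts = data.frame.groupby("id", sort=False).head(1)
        y_first = firsts[data.covariate_names].to_numpy(float)
        y_first = y_first[np.isfinite(y_first).all(axis=1)]
        return rows, y_first, data.k, data.covariate_names
    if isinstance(data, LongitudinalRecords):
        names = data.covariate_names
        k = data.k
        df = data.frame
        ids = df["id"].to_numpy()
        t1 = df["t1"].to_numpy(float)
        t2 = df["t2"].to_numpy(float)
        Y = df[names].to_numpy(float)
        ev = df["event"].to_numpy(int)
        n = len(df)
        # y2 = next row's covariates when it belongs to the same subject
        y2 = np.full((n, k), np.nan)
        if n > 1:
            same = ids[:-1] == ids[1:]
            y2[:-1][same] = Y[1:][same]
        first = np.ones(n, dtype=bool)
        if n > 1:
            first[1:] = ids[1:] != ids[:-1]
        y_first = Y[first]
        y_first = y_first[np.isfinite(y_first).all(axis=1)]
        rows = _rows_from_arrays(t1, t2, Y, y2, ev.astype(bool))
        return rows, y_first, k, names
    raise TypeError("data must be LongitudinalRecords or PairedObservations")


def _substep_plan(rows: _Rows, h_max: float):
    dt = rows.t2 - rows.t1
    h0 = np.minimum(h_max, dt / 4.0)
    n = np.ceil(dt / h0 - 1e-9).astype(np.int64)
    np.maximum(n, 1, out=n)
    return n, dt / n


def _loglik_rows_1d(rows: _Rows, a, f1, b2, Q, f, mu0, theta,
                    sa, sf1, sQ, sf, h_max) -> float:
    n_steps, h_full = _substep_plan(rows, h_max)
    if _fast1d.AVAILABLE:
        ll = _fast1d.loglik_1d(
            rows.t1, rows.t2, n_steps, h_full, rows.y1[:, 0],
            np.ascontiguousarray(rows.y2[:, 0]), rows.has_y2, rows.death,
            float(a), float(f1), float(b2), float(Q), float(f), float(mu0),
            float(theta), float(sa), float(sf1), float(sQ), float(sf))
        return ll if np.isfinite(ll) else -np.inf
    m = rows.y1[:, 0].copy()
    g = np.zeros_like(m)
    H = np.zeros_like(m)
    t = rows.t1.copy()

    def rhs(tt, mm, gg):
        a_t = a + sa * tt if sa else a
        f1_t = f1 + sf1 * tt if sf1 else f1
        Q_t = Q + sQ * tt if sQ else Q
        f_t = f + sf * tt if sf else f
        if theta:
            et = np.exp(theta * tt)
            Q_t = Q_t * et
            mu0_t = mu0 * et
        else:
            mu0_t = mu0
        d = mm - f_t
        gQ = gg * Q_t
        dm = a_t * (mm - f1_t) - 2.0 * gQ * d
        dg = 2.0 * a_t * gg + b2 - 2.0 * gQ * gg
        dH = mu0_t + Q_t * d * d + gQ
        return dm, dg, dH

    for s in range(int(n_steps.max())):
        hs = np.where(s < n_steps, h_full, 0.0)
        h2 = 0.5 * hs
        k1m, k1g, k1H = rhs(t, m, g)
        k2m, k2g, k2H = rhs(t + h2, m + h2 * k1m, g + h2 * k1g)
        k3m, k3g, k3H = rhs(t + h2, m + h2 * k2m, g + h2 * k2g)
        k4m, k4g, k4H = rhs(t + hs, m + hs * k3m, g + hs * k3g)
        w = hs / 6.0
        m += w * (k1m + 2 * k2m + 2 * k3m + k4m)
        g += w * (k1g + 2 * k2g + 2 * k3g + k4g)
        H += w * (k1H + 2 * k2H + 2 * k3H + k4H)
        t += hs

    ll = 0.0
    obs = rows.has_y2
    gobs = g[obs]
    if len(gobs) and gobs.min() <= 0:
        return -np.inf
    r = rows.y2[obs, 0] - m[obs]
    ll -= 0.5 * np.sum(_LOG2PI + np.log(gobs) + r * r / gobs)
    if rows.death.any():
        td = t[rows.death]
        Q_t = Q + sQ * td if sQ else Q
        f_t = f + sf * td if sf else f
        if theta:
            et = np.exp(theta * td)
            Q_t, mu0_t = Q_t * et, mu0 * et
        else:
            mu0_t = mu0
        d = m[rows.death] - f_t
        mubar = mu0_t + Q_t * d * d + Q_t * g[rows.death]
        if np.min(mubar) <= 0:
            return -np.inf
        ll += np.sum(np.log(mubar))
    ll -= H.sum()
    return ll if np.isfinite(ll) else -np.inf


def _loglik_rows_nd(rows: _Rows, a, f1, bbT, Q, f, mu0, theta, h_max) -> float:
    n_steps, h_full = _substep_plan(rows, h_max)
    N, k = rows.y1.shape
    m = rows.y1.copy()
    g = np.zeros((N, k, k))
    H = np.zeros(N)
    t = rows.t1.copy()
    aT = a.T.copy()

    def rhs(tt, mm, gg):
        et = np.exp(theta * tt) if theta else None
        d = mm - f
        Qd = d @ Q
        gQd = np.einsum("nij,nj->ni", gg, Qd)
        gQ = gg @ Q
        gQg = np.matmul(gQ, gg)
        if et is None:
            dm = (mm - f1) @ aT - 2.0 * gQd
            dg = np.matmul(a[None], gg) + np.matmul(gg, aT) + bbT - 2.0 * gQg
            dH = mu0 + np.einsum("ni,ni->n", d, Qd) + (gg * Q).sum(axis=(1, 2))
        else:
            dm = (mm - f1) @ aT - 2.0 * et[:, None] * gQd
            dg = (np.matmul(a[None], gg) + np.matmul(gg, aT) + bbT
                  - 2.0 * et[:, None, None] * gQg)
            dH = et * (mu0 + np.einsum("ni,ni->n", d, Qd)
                       + (gg * Q).sum(axis=(1, 2)))
        return dm, dg, dH

    for s in range(int(n_steps.max())):
        hs = np.where(s < n_steps, h_full, 0.0)
        h1 = hs[:, None]
        h2m = 0.5 * h1
        h2g = 0.5 * hs[:, None, None]
        h1g = hs[:, None, None]
        k1m, k1g, k1H = rhs(t, m, g)
        k2m, k2g, k2H = rhs(t + 0.5 * hs, m + h2m * k1m, g + h2g * k1g)
        k3m, k3g, k3H = rhs(t + 0.5 * hs, m + h2m * k2m, g + h2g * k2g)
        k4m, k4g, k4H = rhs(t + hs, m + h1 * k3m, g + h1g * k3g)
        m += h1 / 6.0 * (k1m + 2 * k2m + 2 * k3m + k4m)
        g += h1g / 6.0 * (k1g + 2 * k2g + 2 * k3g + k4g)
        g = 0.5 * (g + np.swapaxes(g, 1, 2))
        H += hs / 6.0 * (k1H + 2 * k2H + 2 * k3H + k4H)
        t += hs

    ll = 0.0
    obs = rows.has_y2
    if obs.any():
        cov = g[obs]
        sign, logdet = np.linalg.slogdet(cov)
        if np.any(sign <= 0):
            return -np.inf
        r = rows.y2[obs] - m[obs]
        sol = np.linalg.solve(cov, r[:, :, None])[:, :, 0]
        ll -= 0.5 * np.sum(k * _LOG2PI + logdet + np.einsum("ni,ni->n", r, sol))
    if rows.death.any():
        td = t[rows.death]
        d = m[rows.death] - f
        Qd = d @ Q
        mubar = mu0 + np.einsum("ni,ni->n", d, Qd) + (g[rows.death] * Q).sum(axis=(1, 2))
        if theta:
            mubar = mubar * np.exp(theta * td)
        if np.min(mubar) <= 0:
            return -np.inf
        ll += np.sum(np.log(mubar))
    ll -= H.sum()
    return ll if np.isfinite(ll) else -np.inf


def _rows_loglik(params: ContinuousParams, rows: _Rows, h_max: float) -> float:
    if params.k == 1:
        return _loglik_rows_1d(
            rows, float(params.a[0, 0]), float(params.f1[0]),
            float(params.b[0]) ** 2, float(params.Q[0, 0]), float(params.f[0]),
            params.mu0, params.theta, params.slope("a"), params.slope("f1"),
            params.slope("Q"), params.slope("f"), h_max)
    return _loglik_rows_nd(rows, params.a, params.f1,
                           np.outer(params.b, params.b), params.Q, params.f,
                           params.mu0, params.theta, h_max)


def _initial_law(y_first: np.ndarray):
    if len(y_first) < 2:
        return None
    m0 = y_first.mean(axis=0)
    g0 = np.atleast_2d(np.cov(y_first, rowvar=False, ddof=1))
    if np.linalg.slogdet(g0)[0] <= 0:
        return None
    return m0, g0


def total_log_likelihood(params: ContinuousParams, data,
                         initial_law=None, h_max: float = 0.05) -> float:
    """Total log-likelihood of a dataset (fast flattened-interval path).

    ``initial_law``: ``(m0, gamma0)`` for the first-observation density term,
    ``"sample"`` to estimate it from the data, or ``None`` to omit it.
    """
    rows, y_first, k, _ = _build_rows(data)
    ll = _rows_loglik(params, rows, h_max)
    if initial_law is not None:
        law = _initial_law(y_first) if (isinstance(initial_law, str)
                                        and initial_law == "sample") else initial_law
        if law is not None:
            m0 = np.atleast_1d(np.asarray(law[0], float))
            g0 = np.atleast_2d(np.asarray(law[1], float))
            ll += sum(_gauss_logpdf(y, m0, g0) for y in y_first)
    return ll


# ---------------------------------------------------------------------------
# fitting


@dataclass
class SPMFit:
    """Result of a continuous-time maximum-likelihood fit."""

    params: ContinuousParams
    loglik: float
    success: bool
    message: str
    nfev: int
    simplex_spread: float
    initial_law: tuple | None = None
    n_rows: int = 0
    n_events: int = 0


def _chol_flat(Q: np.ndarray) -> np.ndarray:
    k = Q.shape[0]
    jitter = 0.0
    for _ in range(12):
        try:
            L = np.linalg.cholesky(Q + jitter * np.eye(k))
            break
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10.0, 1e-12 * max(np.abs(Q).max(), 1.0))
    else:
        L = np.sqrt(max(np.trace(Q) / k, 1e-12)) * np.eye(k)
    return L[np.tril_indices(k)]


def _unflat_chol(v: np.ndarray, k: int) -> np.ndarray:
    L = np.zeros((k, k))
    L[np.tril_indices(k)] = v
    return L @ L.T


def _start_from_discrete(rows: _Rows, k: int) -> ContinuousParams:
    from .discrete import _fit_ar_arrays, _fit_hazard_arrays

    try:
        u, R, Sigma = _fit_ar_arrays(rows.y1, rows.y2)
        mu0, b_d, Q, theta = _fit_hazard_arrays(
            rows.y1, rows.t1, rows.t2 - rows.t1, rows.death.astype(float))
        d = DiscreteParams(u=u, R=R, Sigma=Sigma, mu0=mu0, b=b_d, Q=Q, theta=theta)
        c = discrete_to_continuous(d, step=1.0)
        w = np.linalg.eigvalsh(c.Q)
        if w.min() <= 0:
            c.Q = c.Q + (1e-12 + abs(w.min())) * np.eye(k)
        if c.mu0 <= 0:
            c.mu0 = 1e-8
        return c
    except Exception:
        y = rows.y1
        dt = rows.t2 - rows.t1
        rate = max(rows.death.sum() / dt.sum(), 1e-6)
        var = np.maximum(y.var(axis=0), 1e-6)
        return ContinuousParams(
            a=-0.1 * np.eye(k), f1=y.mean(axis=0), b=np.sqrt(var) * 0.3,
            mu0=0.5 * rate, f=y.mean(axis=0),
            Q=np.diag(0.5 * rate / (k * var)), theta=0.0)


def _fit_engine(rows: _Rows, y_first: np.ndarray, k: int,
                start: ContinuousParams, slope_names: list,
                fit_theta: bool, h_max: float, maxfev: int | None,
                on_fail: str) -> SPMFit:
    if not rows.death.any():
        raise EstimationError("no events observed; mu0 is not identifiable")
    n_a = k * k
    n_q = k * (k + 1) // 2
    slope_names = list(slope_names)
    # sloped coefficients are searched as (value at t_ref, slope) with t_ref
    # the mean observation age: decorrelates intercept and slope, which keeps
    # the simplex out of the long diagonal valley of the raw parameterization
    t_ref = float(np.round(rows.t1.mean())) if slope_names else 0.0

    def _centered(name, base):
        return base + start.slope(name) * t_ref if name in slope_names else base

    x0 = np.concatenate([
        _centered("a", start.a).ravel(), _centered("f1", start.f1), start.b,
        _chol_flat(_centered("Q", start.Q)), _centered("f", start.f),
        [math.log(max(start.mu0, 1e-12))],
        [start.slope(nm) for nm in slope_names],
        [start.theta] if fit_theta else [],
    ])

    def unpack(x) -> ContinuousParams:
        i = 0
        a = x[i:i + n_a].reshape(k, k).copy(); i += n_a
        f1 = x[i:i + k].copy(); i += k
        b = np.abs(x[i:i + k]); i += k
        Q = _unflat_chol(x[i:i + n_q], k); i += n_q
        f = x[i:i + k].copy(); i += k
        mu0 = math.exp(min(x[i], 50.0)); i += 1
        slopes = {}
        for nm in slope_names:
            slopes[nm] = x[i]; i += 1
        theta = x[i] if fit_theta else start.theta
        for nm, s in slopes.items():
            shift = s * t_ref
            if nm == "a":
                a = a - shift
            elif nm == "f1":
                f1 = f1 - shift
            elif nm == "Q":
                Q = Q - shift
            elif nm == "f":
                f = f - shift
        return ContinuousParams(a=a, f1=f1, b=b, mu0=mu0, f=f, Q=Q,
                                theta=theta, slopes=slopes)

    def negloglik(x):
        try:
            p = unpack(x)
        except (ValueError, OverflowError):
            return 1e300
        ll = _rows_loglik(p, rows, h_max)
        return -ll if np.isfinite(ll) else 1e300

    if maxfev is None:
        maxfev = 5000 * len(x0)
    x, res = nelder_mead(negloglik, x0, maxfev=maxfev)
    fitted = unpack(x)
    if not fitted.is_mean_reverting():
        warnings.warn("fitted feedback matrix a is not mean-reverting "
                      "(some eigenvalue has nonnegative real part)", stacklevel=3)
    law = _initial_law(y_first)
    ll = -res.fun
    if law is not None:
        ll += sum(_gauss_logpdf(y, law[0], law[1]) for y in y_first)
    fit = SPMFit(params=fitted, loglik=float(ll), success=bool(res.success),
                 message=str(res.message), nfev=int(res.nfev),
                 simplex_spread=res.simplex_spread, initial_law=law,
                 n_rows=len(rows.t1), n_events=int(rows.death.sum()))
    if not fit.success and on_fail == "raise":
        raise ConvergenceError(
            f"continuous-time fit did not converge: {res.message}",
            last_iterate=fit)
    return fit


def fit_continuous(data, *, use_exp_theta: bool = False,
                   start="from_discrete", h_max: float = 0.05,
                   maxfev: int | None = None, on_fail: str = "raise") -> SPMFit:
    """Maximum-likelihood fit of the constant-coefficient model.

    ``start`` is a :class:`ContinuousParams` or ``"from_discrete"`` (default),
    in which case starting values come from the discrete-time fit converted
    to the continuous parameterization.  With ``use_exp_theta`` the hazard
    components ``mu0`` and ``Q`` carry an ``exp(theta·t)`` factor and
    ``theta`` is estimated; otherwise ``theta`` is fixed at 0.
    ``on_fail="warn"`` returns the best iterate instead of raising when the
    simplex search hits its evaluation budget.
    """
    rows, y_first, k, _ = _build_rows(data)
    if isinstance(start, ContinuousParams):
        s = ContinuousParams.from_dict(start.to_dict())
    else:
        s = _start_from_discrete(rows, k)
    if not use_exp_theta:
        s.theta = 0.0
    return _fit_engine(rows, y_first, k, s, [], use_exp_theta, h_max,
                       maxfev, on_fail)


def fit_time_dependent(data, formulas: dict, *, start=None,
                       use_exp_theta: bool = False, h_max: float = 0.05,
                       maxfev: int | None = None, on_fail: str = "raise") -> SPMFit:
    """Fit the one-dimensional model with linear-in-time coefficients.

    ``formulas`` maps coefficient names (among ``a, f1, Q, f``) to
    :class:`CoefficientFunction` specs; listed coefficients get a free slope
    (initialized at 0 unless a value is given, with the base initialized
    from the discrete-time fit unless given); unlisted coefficients are held
    constant.  Only ``k = 1`` is supported.
    """
    rows, y_first, k, _ = _build_rows(data)
    if k != 1 and formulas:
        raise UnsupportedConfigurationError(
            "time-dependent coefficients are implemented for one covariate only"
        )
    bad = [nm for nm in formulas if nm not in ("a", "f1", "Q", "f")]
    if bad:
        raise UnsupportedConfigurationError(
            f"no linear time dependence available for coefficient(s) {bad}"
        )
    if isinstance(start, ContinuousParams):
        s = ContinuousParams.from_dict(start.to_dict())
    else:
        s = _start_from_discrete(rows, k)
    s.slopes = {}
    for nm, spec in formulas.items():
        cf = spec if isinstance(spec, CoefficientFunction) else CoefficientFunction(**(spec or {}))
        if cf.base is not None:
            if nm == "a":
                s.a = np.array([[cf.base]])
            else:
                setattr(s, nm, np.atleast_1d(np.asarray(cf.base, float)))
        s.slopes[nm] = cf.slope
    if not use_exp_theta:
        s.theta = 0.0
    return _fit_engine(rows, y_first, k, s, list(formulas), use_exp_theta,
                       h_max, maxfev, on_fail)
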