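"""Discrete-time (fixed-interval) model estimation.

Dynamics ``Y(t+1) = u + R Y(t) + eps`` are estimated by ordinary least
squares jointly across subjects; the hazard parameters ``(mu0, b, Q, theta)``
of ``mu(t, y) = [mu0 + b·y + yᵀQy]·exp(theta·t)`` are estimated by maximum
likelihood of the per-interval death indicators, where the probability of
dying in an interval of length ``dt`` starting at ``(t, y)`` is
``1 − exp(−mu(t, y)·dt)``.

A log-link binomial GLM on ``[1, y, pairwise products of y, t]`` supplies
starting values only (its exponential-of-linear form cannot represent the
bracketed quadratic hazard); the reported estimates maximize the exact
Bernoulli likelihood by Nelder–Mead.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .data import PairedObservations
from .errors import ConvergenceError, EstimationError, RankDeficiencyError
from .optim import nelder_mead
from .params import ContinuousParams, DiscreteParams, discrete_to_continuous

__all__ = [
    "discrete_hazard",
    "fit_autoregression",
    "fit_discrete_hazard",
    "fit_discrete",
]


def discrete_hazard(params: DiscreteParams, y, t):
    """Hazard rate ``[mu0 + b·y + yᵀQy]·exp(theta·t)``.

    ``y`` may be a single k-vector or an (n, k) matrix; ``t`` broadcasts.
    The value may be negative for pathological parameter sets — callers clamp
    at 0 when forming probabilities.
    """
    y = np.asarray(y, dtype=float)
    squeeze = y.ndim == 1
    Y = np.atleast_2d(y)
    if Y.shape[1] != params.k:
        raise ValueError(f"y has dimension {Y.shape[1]}, expected {params.k}")
    bracket = params.mu0 + Y @ params.b + np.einsum("ni,ij,nj->n", Y, params.Q, Y)
    out = bracket * np.exp(params.theta * np.asarray(t, dtype=float))
    return float(out[0]) if squeeze and out.shape == (1,) else out


# ---------------------------------------------------------------------------
# autoregression


def _fit_ar_arrays(y1: np.ndarray, y2: np.ndarray, names=None):
    k = y1.shape[1]
    ok = np.isfinite(y1).all(axis=1) & np.isfinite(y2).all(axis=1)
    y1, y2 = y1[ok], y2[ok]
    n = len(y1)
    if n < k + 2:
        raise EstimationError(
            f"autoregression needs at least {k + 2} complete pairs, got {n}"
        )
    X = np.column_stack([np.ones(n), y1])
    if np.linalg.matrix_rank(X) < k + 1:
        names = names or [f"y{j + 1}" for j in range(k)]
        stds = y1.std(axis=0)
        culprit = names[int(np.argmin(stds))]
        raise RankDeficiencyError(
            f"autoregression design is rank deficient (covariate {culprit!r} "
            "is constant or collinear)"
        )
    beta, *_ = np.linalg.lstsq(X, y2, rcond=None)
    u = beta[0].copy()
    R = beta[1:].T.copy()
    resid = y2 - X @ beta
    dof = max(n - (k + 1), 1)
    Sigma = np.sqrt((resid ** 2).sum(axis=0) / dof)
    return u, R, Sigma


def fit_autoregression(pairs: PairedObservations):
    """OLS of ``y2`` on ``[1, y1]`` jointly across subjects.

    Returns ``(u, R, Sigma)`` with ``Sigma`` the per-covariate residual
    standard deviations.  Rows without a ``y2`` measurement (terminal
    intervals) are ignored.
    """
    return _fit_ar_arrays(pairs.y1, pairs.y2, pairs.covariate_names)


# ---------------------------------------------------------------------------
# hazard MLE


def _quad_columns(Y: np.ndarray):
    """Columns y_i*y_j (i<=j), off-diagonals doubled, so that the column
    coefficients are exactly the entries of the symmetric matrix Q."""
    k = Y.shape[1]
    cols, idx = [], []
    for i in range(k):
        for j in range(i, k):
            c = Y[:, i] * Y[:, j]
            cols.append(c if i == j else 2.0 * c)
            idx.append((i, j))
    return np.column_stack(cols), idx


def _unpack_Q(qvec: np.ndarray, idx, k: int) -> np.ndarray:
    Q = np.zeros((k, k))
    for v, (i, j) in zip(qvec, idx):
        Q[i, j] = Q[j, i] = v
    return Q


def _glm_theta_start(e, Y, quad, t):
    """Log-link event-indicator GLM; only its t coefficient is used."""
    import statsmodels.api as sm

    X = np.column_stack([np.ones(len(e)), Y, quad, t])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for family in (sm.families.Binomial(link=sm.families.links.Log()),
                       sm.families.Poisson()):
            try:
                res = sm.GLM(e, X, family=family).fit(maxiter=100)
                th = float(res.params[-1])
                if np.isfinite(th):
                    return th
            except Exception:
                continue
    return 0.0


def _fit_hazard_arrays(y1, t1, dt, e, *, fix=None, maxfev=None):
    fix = dict(fix or {})
    n, k = y1.shape
    if e.sum() == 0:
        raise EstimationError("no events observed; hazard parameters are not identifiable")
    quad, idx = _quad_columns(y1)
    nq = len(idx)
    X = np.column_stack([np.ones(n), y1, quad])

    # free/fixed pattern over [bracket (1+k+nq), theta]
    p = 1 + k + nq
    fixed_full = np.zeros(p + 1)
    free = np.ones(p + 1, dtype=bool)
    if "mu0" in fix:
        fixed_full[0] = fix["mu0"]
        free[0] = False
    if "b" in fix:
        fixed_full[1:1 + k] = np.broadcast_to(np.asarray(fix["b"], float), (k,))
        free[1:1 + k] = False
    if "Q" in fix:
        Qf = np.asarray(fix["Q"], float)
        Qf = Qf.reshape(k, k) if Qf.size == k * k else np.eye(k) * float(Qf)
        fixed_full[1 + k:1 + k + nq] = [Qf[i, j] for (i, j) in idx]
        free[1 + k:1 + k + nq] = False
    if "theta" in fix:
        fixed_full[-1] = fix["theta"]
        free[-1] = False
    if not free.any():
        raise EstimationError("all hazard parameters are fixed; nothing to estimate")
    free_b = free[:p]
    theta_free = bool(free[-1])

    # the age exponent is centered at the mean observation age: the simplex
    # then searches (bracket at t_bar, theta) instead of the strongly
    # collinear (bracket at t=0, theta)
    t_bar = float(t1.mean())
    tc = t1 - t_bar
    tc_unique, tc_inv = np.unique(tc, return_inverse=True)
    Cfix = X[:, ~free_b] @ fixed_full[:p][~free_b] if (~free_b).any() else 0.0
    Xf = X[:, free_b]

    # clamping the per-interval death probability to [1e-12, 1-1e-12] is
    # equivalent to clamping the cumulative hazard lam = mu*dt
    lam_lo, lam_hi = 1e-12, -math.log(1e-12)
    ev = e.astype(bool)
    alive = ~ev

    def negloglik(x_free):
        # x_free = [scaled free bracket coefs (value at t_bar), theta?]
        gamma = x_free[:-1] if theta_free else x_free
        theta = x_free[-1] if theta_free else fixed_full[-1]
        with np.errstate(over="ignore", invalid="ignore"):
            bracket = Xf @ gamma + Cfix * math.exp(
                min(theta * t_bar, 500.0))
            growth = np.exp(theta * tc_unique)[tc_inv]
            lam = np.clip(bracket * growth * dt, lam_lo, lam_hi)
            # survivors contribute log(1-p) = -lam exactly; deaths log p
            ll = -lam[alive].sum() + np.log(-np.expm1(-lam[ev])).sum()
        return -ll if np.isfinite(ll) else 1e300

    # deterministic multi-start: the GLM theta estimate and theta = 0
    if "theta" in fix:
        theta_starts = [float(fix["theta"])]
    else:
        sub = slice(None) if n <= 50_000 else slice(0, None, n // 50_000 + 1)
        th_glm = _glm_theta_start(e[sub], y1[sub], quad[sub], t1[sub])
        theta_starts = [th_glm if -2.0 < th_glm < 2.0 else 0.0]
        if abs(theta_starts[0]) > 1e-8:
            theta_starts.append(0.0)

    best = None
    for theta0 in theta_starts:
        z = e * np.exp(-theta0 * tc) / dt - Cfix * math.exp(
            min(theta0 * t_bar, 500.0))
        gamma0, *_ = np.linalg.lstsq(Xf, z, rcond=None)
        if not np.isfinite(gamma0).all():
            gamma0 = np.zeros(Xf.shape[1])
        if free_b[0] and gamma0[0] <= 0:
            gamma0[0] = max(e.mean() / dt.mean(), 1e-8)
        x0 = np.concatenate([gamma0, [theta0]]) if theta_free else gamma0
        x, res = nelder_mead(negloglik, x0, maxfev=maxfev)
        if best is None or res.fun < best[1].fun:
            best = (x, res)
    x, res = best
    theta = float(x[-1]) if theta_free else float(fixed_full[-1])
    beta = fixed_full[:p].copy()
    beta[free_b] = (x[:-1] if theta_free else x) * math.exp(-theta * t_bar)
    if not res.success:
        raise ConvergenceError(
            f"hazard MLE did not converge: {res.message}",
            last_iterate={"mu0": beta[0], "b": beta[1:1 + k],
                          "Q": _unpack_Q(beta[1 + k:], idx, k),
                          "theta": theta},
        )
    mu0 = float(beta[0])
    b = beta[1:1 + k].copy()
    Q = _unpack_Q(beta[1 + k:], idx, k)
    # validate nonnegativity of the fitted hazard over the observed data range
    bracket = mu0 + y1 @ b + np.einsum("ni,ij,nj->n", y1, Q, y1)
    if bracket.min() < 0:
        warnings.warn(
            "fitted hazard is negative for some observed covariate values; "
            "interpret with care",
            stacklevel=2,
        )
    return mu0, b, Q, theta


def fit_discrete_hazard(pairs: PairedObservations, dt: float | None = None,
                        fix: dict | None = None, maxfev: int | None = None):
    """Exact Bernoulli MLE of the per-interval hazard parameters.

    Parameters may be fixed via ``fix`` (keys among ``mu0, b, Q, theta``),
    e.g. ``fix={"theta": 0.0}``.  ``dt`` overrides the per-row interval
    lengths (defaults to ``t2 − t1``).  Returns ``(mu0, b, Q, theta)``.
    """
    ok = np.isfinite(pairs.y1).all(axis=1)
    y1 = pairs.y1[ok]
    t1 = pairs.t1[ok]
    e = pairs.case[ok].astype(float)
    if dt is None:
        dts = pairs.interval_lengths()[ok]
    else:
        dts = np.full(len(y1), float(dt))
    return _fit_hazard_arrays(y1, t1, dts, e, fix=fix, maxfev=maxfev)


def fit_discrete(pairs: PairedObservations, fix: dict | None = None,
                 maxfev: int | None = None):
    """Full discrete-time fit: autoregression + hazard MLE.

    Returns ``(DiscreteParams, ContinuousParams)`` — the fitted discrete set
    and its exact continuous-time equivalent.  Requires (approximately) unit
    observation intervals, since the coefficient conversion is defined only
    for a 1-year step.
    """
    u, R, Sigma = fit_autoregression(pairs)
    mu0, b, Q, theta = fit_discrete_hazard(pairs, fix=fix, maxfev=maxfev)
    d = DiscreteParams(u=u, R=R, Sigma=Sigma, mu0=mu0, b=b, Q=Q, theta=theta)
    dt = float(np.median(pairs.interval_lengths())) if len(pairs) else 1.0
    c = discrete_to_continuous(d, step=round(dt, 9))
    return d, c
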