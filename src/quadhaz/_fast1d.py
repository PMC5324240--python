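"""Optional numba-compiled kernel for the one-dimensional row likelihood.

Same RK4 recursion as the numpy path in :mod:`quadhaz.continuous`; the two
implementations agree to floating-point noise and the numpy path remains the
reference (and the fallback when numba is unavailable).
"""

import numpy as np

try:
    from numba import njit

    AVAILABLE = True
except Exception:  # pragma: no cover - numba is normally present
    AVAILABLE = False

    def njit(*a, **k):  # type: ignore
        def wrap(fn):
            return fn
        return wrap

_LOG2PI = 1.8378770664093453


@njit(cache=True)
def _rhs(t, m, g, a, f1, b2, Q, f, mu0, theta, sa, sf1, sQ, sf):
    a_t = a + sa * t
    f1_t = f1 + sf1 * t
    Q_t = Q + sQ * t
    f_t = f + sf * t
    mu0_t = mu0
    if theta != 0.0:
        et = np.exp(theta * t)
        Q_t = Q_t * et
        mu0_t = mu0 * et
    d = m - f_t
    gQ = g * Q_t
    dm = a_t * (m - f1_t) - 2.0 * gQ * d
    dg = 2.0 * a_t * g + b2 - 2.0 * gQ * g
    dH = mu0_t + Q_t * d * d + gQ
    return dm, dg, dH


@njit(cache=True)
def loglik_1d(t1, t2, nsteps, hstep, y1, y2, has_y2, death,
              a, f1, b2, Q, f, mu0, theta, sa, sf1, sQ, sf):
    N = t1.shape[0]
    ll = 0.0
    for i in range(N):
        m = y1[i]
        g = 0.0
        H = 0.0
        t = t1[i]
        h = hstep[i]
        h2 = 0.5 * h
        w = h / 6.0
        for _ in range(nsteps[i]):
            k1m, k1g, k1H = _rhs(t, m, g, a, f1, b2, Q, f, mu0, theta, sa, sf1, sQ, sf)
            k2m, k2g, k2H = _rhs(t + h2, m + h2 * k1m, g + h2 * k1g,
                                 a, f1, b2, Q, f, mu0, theta, sa, sf1, sQ, sf)
            k3m, k3g, k3H = _rhs(t + h2, m + h2 * k2m, g + h2 * k2g,
                                 a, f1, b2, Q, f, mu0, theta, sa, sf1, sQ, sf)
            k4m, k4g, k4H = _rhs(t + h, m + h * k3m, g + h * k3g,
                                 a, f1, b2, Q, f, mu0, theta, sa, sf1, sQ, sf)
            m += w * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
            g += w * (k1g + 2.0 * k2g + 2.0 * k3g + k4g)
            H += w * (k1H + 2.0 * k2H + 2.0 * k3H + k4H)
            t += h
        if has_y2[i]:
            if g <= 0.0:
                return -np.inf
            r = y2[i] - m
            ll += -0.5 * (_LOG2PI + np.log(g) + r * r / g)
        if death[i]:
            tt = t2[i]
            Q_t = Q + sQ * tt
            f_t = f + sf * tt
            mu0_t = mu0
            if theta != 0.0:
                et = np.exp(theta * tt)
                Q_t = Q_t * et
                mu0_t = mu0 * et
            d = m - f_t
            mubar = mu0_t + Q_t * d * d + Q_t * g
            if mubar <= 0.0:
                return -np.inf
            ll += np.log(mubar)
        ll -= H
    return ll
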