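"""Scaled Nelder–Mead wrapper shared by the estimators.

Coordinates are divided by ``max(|x0|, 1e-8)`` so the simplex operates on
O(1) quantities regardless of the native parameter scales (hazard curvatures
are ~1e-6 while trajectory means are ~1e2).  The search restarts once from
its own optimum — a cheap guard against premature simplex collapse.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["nelder_mead"]


def nelder_mead(fun, x0, maxfev=None, xatol=1e-6, restarts=1):
    x0 = np.asarray(x0, dtype=float)
    # near-zero coordinates get unit scale so the simplex can still move them
    scale = np.where(np.abs(x0) > 1e-6, np.abs(x0), 1.0)
    f0 = fun(x0)
    fatol = 1e-8 * max(1.0, abs(f0))
    if maxfev is None:
        maxfev = 2000 * len(x0)

    def scaled(z):
        return fun(z * scale)

    z = x0 / scale
    res = None
    for _ in range(restarts + 1):
        res = minimize(scaled, z, method="Nelder-Mead",
                       options={"maxfev": maxfev, "xatol": xatol,
                                "fatol": fatol, "adaptive": len(x0) > 4})
        z = res.x
    x = res.x * scale
    spread = float(np.max(res.final_simplex[1]) - np.min(res.final_simplex[1]))
    res.simplex_spread = spread
    return x, res
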