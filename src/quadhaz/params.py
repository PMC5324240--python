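"""Parameter sets of the stochastic process model and their conversion.

Two equivalent parameterizations are used throughout the package:

* the *discrete-time* set ``{u, R, Sigma, mu0, b, Q, theta}`` of the
  autoregressive model ``Y(t+1) = u + R Y(t) + eps`` with per-interval hazard
  ``mu(t, y) = [mu0 + b·y + yᵀ Q y]·exp(theta·t)``;
* the *continuous-time* set ``{a, f1, b, mu0, f, Q, theta}`` of the
  mean-reverting diffusion ``dY = a(Y − f1)dt + b dW`` with quadratic hazard
  ``mu(t, y) = [mu0 + (y − f)ᵀ Q (y − f)]·exp(theta·t)``.

For unit observation intervals the two sets are algebraically equivalent and
:func:`discrete_to_continuous` / :func:`continuous_to_discrete` map between
them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ConversionError

__all__ = [
    "DiscreteParams",
    "ContinuousParams",
    "discrete_to_continuous",
    "continuous_to_discrete",
]

#: coefficients that may carry a linear time slope in the one-dimensional
#: time-dependent model variant
SLOPE_COEFFICIENTS = ("a", "f1", "Q", "f")


def _vector(x, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.ndim != 1:
        raise ValueError(f"{name} must be a vector, got shape {v.shape}")
    return v


def _matrix(x, k: int, name: str) -> np.ndarray:
    m = np.asarray(x, dtype=float)
    if m.ndim == 0:
        m = m.reshape(1, 1)
    if m.shape != (k, k):
        raise ValueError(f"{name} must be {k}x{k}, got shape {m.shape}")
    return m


def _sym(m: np.ndarray) -> np.ndarray:
    return 0.5 * (m + m.T)


@dataclass
class DiscreteParams:
    """Coefficients of the discrete-time (fixed-interval) model.

    ``u`` is the autoregression intercept (k-vector), ``R`` the k x k
    autoregression matrix, ``Sigma`` the per-covariate residual standard
    deviations, and ``(mu0, b, Q, theta)`` parameterize the per-interval
    hazard ``[mu0 + b·y + yᵀQy]·exp(theta·t)``.  ``Q`` is stored
    symmetrized.
    """

    u: np.ndarray
    R: np.ndarray
    Sigma: np.ndarray
    mu0: float
    b: np.ndarray
    Q: np.ndarray
    theta: float = 0.0

    def __post_init__(self):
        self.u = _vector(self.u, "u")
        k = self.u.shape[0]
        self.R = _matrix(self.R, k, "R")
        self.Sigma = _vector(self.Sigma, "Sigma")
        self.b = _vector(self.b, "b")
        self.Q = _sym(_matrix(self.Q, k, "Q"))
        if self.Sigma.shape[0] != k or self.b.shape[0] != k:
            raise ValueError("inconsistent dimensions in DiscreteParams")
        self.mu0 = float(self.mu0)
        self.theta = float(self.theta)

    @property
    def k(self) -> int:
        return self.u.shape[0]

    def to_dict(self) -> dict:
        return {
            "u": self.u.tolist(),
            "R": self.R.tolist(),
            "Sigma": self.Sigma.tolist(),
            "mu0": self.mu0,
            "b": self.b.tolist(),
            "Q": self.Q.tolist(),
            "theta": self.theta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DiscreteParams":
        return cls(u=d["u"], R=d["R"], Sigma=d["Sigma"], mu0=d["mu0"],
                   b=d["b"], Q=d["Q"], theta=d.get("theta", 0.0))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DiscreteParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ContinuousParams:
    """Coefficients of the continuous-time model.

    ``a`` (k x k) is the negative-feedback / adaptive-capacity matrix, ``f1``
    the long-term (allostatic) mean trajectory, ``b`` the diffusion strengths,
    ``f`` the risk-minimizing physiological norm, ``Q`` the (symmetric)
    hazard curvature and ``mu0`` the baseline hazard at the norm.  ``theta``
    is the Gompertz log-rate: whenever ``theta != 0`` the hazard components
    ``mu0`` and ``Q`` are multiplied by ``exp(theta·t)``.

    ``slopes`` optionally holds linear time slopes for the one-dimensional
    time-dependent variant, e.g. ``{"f1": 0.1}`` means
    ``f1(t) = f1 + 0.1·t``.  Allowed keys: ``a, f1, Q, f``.
    """

    a: np.ndarray
    f1: np.ndarray
    b: np.ndarray
    mu0: float
    f: np.ndarray
    Q: np.ndarray
    theta: float = 0.0
    slopes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.f1 = _vector(self.f1, "f1")
        k = self.f1.shape[0]
        self.a = _matrix(self.a, k, "a")
        self.b = _vector(self.b, "b")
        self.f = _vector(self.f, "f")
        self.Q = _sym(_matrix(self.Q, k, "Q"))
        if self.b.shape[0] != k or self.f.shape[0] != k:
            raise ValueError("inconsistent dimensions in ContinuousParams")
        self.mu0 = float(self.mu0)
        self.theta = float(self.theta)
        bad = set(self.slopes) - set(SLOPE_COEFFICIENTS)
        if bad:
            raise ValueError(f"time slopes not supported for: {sorted(bad)}")
        if self.slopes and k != 1:
            raise ValueError("time-dependent coefficients require k = 1")
        self.slopes = {name: float(v) for name, v in self.slopes.items()}

    @property
    def k(self) -> int:
        return self.f1.shape[0]

    def slope(self, name: str) -> float:
        return self.slopes.get(name, 0.0)

    def coeff_at(self, name: str, t: float):
        """Evaluate coefficient ``name`` at time ``t`` (slopes and, for
        ``mu0``/``Q``, the exp(theta t) factor included)."""
        base = getattr(self, name)
        val = base + self.slope(name) * t if name in SLOPE_COEFFICIENTS else base
        if name in ("mu0", "Q") and self.theta != 0.0:
            val = val * np.exp(self.theta * t)
        return val

    def is_mean_reverting(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.a).real < 0))

    def to_dict(self) -> dict:
        d = {
            "a": self.a.tolist(),
            "f1": self.f1.tolist(),
            "b": self.b.tolist(),
            "mu0": self.mu0,
            "f": self.f.tolist(),
            "Q": self.Q.tolist(),
            "theta": self.theta,
        }
        if self.slopes:
            d["slopes"] = dict(self.slopes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ContinuousParams":
        return cls(a=d["a"], f1=d["f1"], b=d["b"], mu0=d["mu0"], f=d["f"],
                   Q=d["Q"], theta=d.get("theta", 0.0),
                   slopes=d.get("slopes", {}))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ContinuousParams":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _check_step(step: float) -> None:
    if abs(step - 1.0) > 1e-12:
        raise ConversionError(
            "coefficient conversion is defined only for unit (1-year) "
            f"observation intervals; got step={step!r}. Resample the data to "
            "a 1-year grid or fit the continuous-time model directly."
        )


def _check_full_rank(m: np.ndarray, name: str) -> None:
    if np.linalg.matrix_rank(m) < m.shape[0] or np.linalg.cond(m) > 1e12:
        raise ConversionError(f"matrix {name} is singular; conversion requires full rank")


def discrete_to_continuous(d: DiscreteParams, step: float = 1.0) -> ContinuousParams:
    """Map discrete-time coefficients to the continuous-time set.

    The map is ``Q_c = Q_d``, ``a = R − I``, ``b_c = Sigma``,
    ``f1 = −a⁻¹u``, ``f = −½ Q⁻¹ b_d``, ``mu0_c = mu0_d − fᵀQf`` and
    ``theta_c = theta_d``; it is exact when observations are one time unit
    apart, which is why ``step`` must be 1.
    """
    _check_step(step)
    k = d.k
    a = d.R - np.eye(k)
    _check_full_rank(a, "R - I")
    _check_full_rank(d.Q, "Q")
    f1 = -np.linalg.solve(a, d.u)
    f = -0.5 * np.linalg.solve(d.Q, d.b)
    mu0 = d.mu0 - float(f @ d.Q @ f)
    return ContinuousParams(a=a, f1=f1, b=d.Sigma.copy(), mu0=mu0, f=f,
                            Q=d.Q.copy(), theta=d.theta)


def continuous_to_discrete(c: ContinuousParams, step: float = 1.0) -> DiscreteParams:
    """Exact algebraic inverse of :func:`discrete_to_continuous`."""
    _check_step(step)
    if c.slopes:
        raise ConversionError(
            "conversion is defined for constant coefficients only; "
            "this parameter set has time-dependent slopes"
        )
    k = c.k
    R = c.a + np.eye(k)
    u = -c.a @ c.f1
    b_d = -2.0 * (c.Q @ c.f)
    mu0 = c.mu0 + float(c.f @ c.Q @ c.f)
    return DiscreteParams(u=u, R=R, Sigma=c.b.copy(), mu0=mu0, b=b_d,
                          Q=c.Q.copy(), theta=c.theta)
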