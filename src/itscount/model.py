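"""Segmented design and the LL(0,1) count model.

A two-phase interrupted time series (ITS) observes a count ``Y_t`` at times
``t = 1..n``, with an intervention switching on at index ``t0``.  The model is
segmented regression on the logarithm of the conditional mean, with an
observation-driven feedback term on the previous count::

    ln(mu_t) = beta0 + beta1*T_t + beta2*X_t + beta3*D_t + gamma1*ln(Y_{t-1} + 1)

where ``T_t`` is the (possibly log-transformed) study time, ``X_t`` the
post-intervention phase indicator, and ``D_t = (T_t - T_{t0}) * X_t`` the
post-intervention elapsed time.  ``beta2`` is the immediate level change of
the log conditional mean at the intervention; ``beta3`` the change in its
slope; ``gamma1`` the strength of dependence on the last observation.  This
is the log-linear model of order (0, 1) — the log mean depends on the log of
the single previous observation only.

Conditional distributions: Poisson(mu_t), or negative binomial with mean
``mu_t`` and overdispersion ``phi > 0`` giving variance ``mu_t + mu_t**2/phi``
(``phi -> inf`` recovers Poisson).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .errors import (
    EvaluationError,
    ExplosionError,
    InvalidDesignError,
    NonstationaryWarning,
)

__all__ = [
    "SegmentedDesign",
    "RegressionParams",
    "DependenceParams",
    "ModelSpec",
    "CountSeries",
    "build_design",
    "linear_predictor",
    "conditional_mean",
    "log_pmf_poisson",
    "log_pmf_negbin",
    "conditional_variance",
    "log_likelihood",
]

# exp() argument beyond which float64 overflows
_EXP_OVERFLOW = 709.0


@dataclass(frozen=True)
class SegmentedDesign:
    """Covariate structure of a single-arm two-phase ITS design.

    Attributes
    ----------
    n : int
        Number of observation times (even, >= 4).
    transform : str
        ``"log"`` maps raw time t to ln(t) (so T_1 = 0); ``"identity"``
        keeps T_t = t.
    intervention_index : int
        1-based index t0 of the first post-intervention observation.
    T, X, D : ndarray
        Transformed time, phase indicator, and post-intervention elapsed
        time ``(T_t - anchor) * X_t``, each of length n.
    anchor : str
        ``"transformed"`` anchors D at T_{t0} (same scale as T, default);
        ``"raw"`` subtracts the raw index t0 instead.
    """

    n: int
    transform: str
    intervention_index: int
    T: np.ndarray = field(repr=False)
    X: np.ndarray = field(repr=False)
    D: np.ndarray = field(repr=False)
    anchor: str = "transformed"

    @property
    def n_pre(self) -> int:
        return self.intervention_index - 1

    @property
    def n_post(self) -> int:
        return self.n - self.n_pre


def build_design(
    n: int,
    transform: str = "log",
    intervention_index: int | str = "auto",
    anchor: str = "transformed",
) -> SegmentedDesign:
    """Construct the ITS covariate structure for ``n`` observation times.

    ``intervention_index="auto"`` splits the series into equal pre- and
    post-intervention halves: the intervention starts at t0 = n/2 + 1.
    ``D`` is zero at t0, so ``beta2`` alone carries the immediate level
    change there.
    """
    if not isinstance(n, (int, np.integer)) or isinstance(n, bool):
        raise InvalidDesignError(f"n must be an integer, got {n!r}")
    if n < 4 or n % 2 != 0:
        raise InvalidDesignError(f"n must be an even integer >= 4, got {n}")
    if transform not in ("log", "identity"):
        raise InvalidDesignError(f"unknown time transform {transform!r}")
    if anchor not in ("transformed", "raw"):
        raise InvalidDesignError(f"unknown anchor {anchor!r}")

    if intervention_index == "auto":
        t0 = n // 2 + 1
    else:
        t0 = int(intervention_index)
        if not (2 <= t0 <= n):
            raise InvalidDesignError(
                f"intervention_index must lie in [2, {n}], got {t0}"
            )

    t = np.arange(1, n + 1, dtype=float)
    T = np.log(t) if transform == "log" else t
    X = (t >= t0).astype(float)
    ref = T[t0 - 1] if anchor == "transformed" else float(t0)
    D = (T - ref) * X
    return SegmentedDesign(
        n=n, transform=transform, intervention_index=t0, T=T, X=X, D=D, anchor=anchor
    )


@dataclass(frozen=True)
class RegressionParams:
    """Segmented-regression coefficients on the log conditional-mean scale.

    beta0: starting level; beta1: pre-intervention slope per unit transformed
    time; beta2: level change at the intervention; beta3: trend change.
    """

    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0

    def __post_init__(self):
        for name in ("beta0", "beta1", "beta2", "beta3"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3])


@dataclass(frozen=True)
class DependenceParams:
    """Feedback coefficient of the LL(0,1) recursion.

    Only orders p=0, q=1 are supported: the log conditional mean depends on
    ln(Y_{t-1}+1) through ``gamma1``.  For constant linear predictor and
    Poisson response the recursion has a stationary distribution when
    |gamma1| < 1; values outside that range trigger a warning, not an error.
    """

    gamma1: float
    order_p: int = 0
    order_q: int = 1

    def __post_init__(self):
        if self.order_p != 0 or self.order_q != 1:
            raise ValueError(
                f"only the LL(0,1) model is supported, got p={self.order_p}, q={self.order_q}"
            )
        if not math.isfinite(self.gamma1):
            raise ValueError(f"gamma1 must be finite, got {self.gamma1}")
        if abs(self.gamma1) >= 1:
            warnings.warn(
                f"|gamma1| = {abs(self.gamma1)} >= 1: no stationary regime; "
                "simulated series are prone to explosion",
                NonstationaryWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class ModelSpec:
    """Family (poisson or negbin) plus regression/dependence/dispersion parameters."""

    family: str
    reg: RegressionParams
    dep: DependenceParams
    phi: float | None = None

    def __post_init__(self):
        if self.family not in ("poisson", "negbin"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "negbin":
            if self.phi is None or not (self.phi > 0):
                raise ValueError(f"negbin requires phi > 0, got {self.phi}")


@dataclass
class CountSeries:
    """A realized count outcome path with its seed value and design."""

    design: SegmentedDesign
    y: np.ndarray
    y0: int = 0
    mu: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y)
        if self.y.shape != (self.design.n,):
            raise ValueError(
                f"series length {self.y.shape} does not match design n={self.design.n}"
            )
        if np.any(self.y < 0) or not np.all(np.equal(np.mod(self.y, 1), 0)):
            raise ValueError("counts must be nonnegative integers")
        self.y = self.y.astype(np.int64)
        if self.y0 < 0 or int(self.y0) != self.y0:
            raise ValueError(f"y0 must be a nonnegative integer, got {self.y0}")
        self.y0 = int(self.y0)

    @property
    def y_prev(self) -> np.ndarray:
        """Lagged outcome vector (y0, y_1, ..., y_{n-1}) entering the recursion."""
        return np.concatenate(([self.y0], self.y[:-1]))


def linear_predictor(design: SegmentedDesign, reg: RegressionParams, t: int) -> float:
    """eta_t = beta0 + beta1*T_t + beta2*X_t + beta3*D_t at 1-based index t."""
    if not (1 <= t <= design.n):
        raise IndexError(f"t must lie in [1, {design.n}], got {t}")
    i = t - 1
    return float(
        reg.beta0 + reg.beta1 * design.T[i] + reg.beta2 * design.X[i] + reg.beta3 * design.D[i]
    )


def linear_predictor_vector(design: SegmentedDesign, reg: RegressionParams) -> np.ndarray:
    """All n linear predictors at once."""
    return (
        reg.beta0
        + reg.beta1 * design.T
        + reg.beta2 * design.X
        + reg.beta3 * design.D
    )


def conditional_mean(eta_t: float, gamma1: float, y_prev: int) -> float:
    """mu_t = exp(eta_t + gamma1 * ln(y_prev + 1)).

    Raises :class:`ExplosionError` when the exponent exceeds the float64
    range; the simulator treats that as a generation failure.
    """
    if y_prev < 0:
        raise ValueError(f"y_prev must be >= 0, got {y_prev}")
    log_mu = eta_t + gamma1 * math.log1p(y_prev)
    if log_mu > _EXP_OVERFLOW:
        raise ExplosionError(f"conditional mean overflows: ln(mu) = {log_mu:.3g}")
    return math.exp(log_mu)


def log_pmf_poisson(y, mu):
    """Poisson log pmf: -mu + y*ln(mu) - ln Gamma(y+1). Vectorized."""
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("y must be nonnegative integer(s)")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    out = -mu + y * np.log(mu) - gammaln(y + 1.0)
    return out if out.ndim else float(out)


def log_pmf_negbin(y, mu, phi):
    """Negative binomial log pmf in the (mean, overdispersion) parameterization.

    ln Gamma(phi+y) - ln Gamma(y+1) - ln Gamma(phi)
      + phi*ln(phi/(phi+mu)) + y*ln(mu/(phi+mu))

    Mean mu, variance mu + mu**2/phi. Vectorized.
    """
    y = np.asarray(y)
    mu = np.asarray(mu, dtype=float)
    if np.any(y < 0) or not np.all(np.equal(np.mod(y, 1), 0)):
        raise ValueError("y must be nonnegative integer(s)")
    if np.any(mu <= 0):
        raise ValueError("mu must be positive")
    if not (np.ndim(phi) == 0 and phi > 0):
        raise ValueError(f"phi must be a positive scalar, got {phi}")
    out = (
        gammaln(phi + y)
        - gammaln(y + 1.0)
        - gammaln(phi)
        + phi * np.log(phi / (phi + mu))
        + y * np.log(mu / (phi + mu))
    )
    return out if out.ndim else float(out)


def conditional_variance(mu: float, family: str, phi: float | None = None) -> float:
    """Var(Y_t | F_{t-1}): mu for Poisson, mu + mu**2/phi for negbin."""
    if mu <= 0:
        raise ValueError(f"mu must be positive, got {mu}")
    if family == "poisson":
        return float(mu)
    if family == "negbin":
        if phi is None or phi <= 0:
            raise ValueError("negbin conditional variance requires phi > 0")
        return float(mu + mu * mu / phi)
    raise ValueError(f"unknown family {family!r}")


def conditional_means(series: CountSeries, spec: ModelSpec) -> np.ndarray:
    """Realized conditional means mu_t along an observed path.

    Because the feedback term uses the *observed* previous count, the whole
    vector is available in closed form — no sequential recursion is needed
    at evaluation time.
    """
    eta = linear_predictor_vector(series.design, spec.reg)
    log_mu = eta + spec.dep.gamma1 * np.log1p(series.y_prev)
    with np.errstate(over="ignore"):  # overflow surfaces as inf, caught by callers
        return np.exp(log_mu)


def log_likelihood(series: CountSeries, spec: ModelSpec) -> float:
    """Conditional log likelihood of the series under the LL(0,1) model.

    Sums the conditional log density of y_t given mu_t over t = 1..n, where
    mu_t is driven by the observed y_{t-1} (y0 for t = 1).  Conditional on
    Y_0; the initial state is not marginalized.
    """
    mu = conditional_means(series, spec)
    bad = ~np.isfinite(mu) | (mu <= 0)
    if np.any(bad):
        idx = int(np.argmax(bad)) + 1
        raise EvaluationError(
            f"non-finite conditional mean at t={idx}", index=idx
        )
    if spec.family == "poisson":
        return float(np.sum(log_pmf_poisson(series.y, mu)))
    return float(np.sum(log_pmf_negbin(series.y, mu, spec.phi)))
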