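"""Wald chi-square tests for the three ITS hypotheses.

The tests target the intervention-effect coefficients of the segmented
log-mean model: the joint null beta2 = beta3 = 0 (any change, 2 df), the
level-change null beta2 = 0, and the trend-change null beta3 = 0 (1 df
each).  The statistic is W = r' V^{-1} r with r the tested estimates and V
the corresponding block of the observed-information covariance; p-values
come from the upper tail of the chi-square distribution.  Testing is
two-sided through the quadratic form; rejection uses strict inequality
p < alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .errors import ConfigError, NotConvergedError, SingularCovarianceError
from .fit import FitResult

__all__ = [
    "Hypothesis",
    "TestResult",
    "JOINT_CHANGE",
    "LEVEL_CHANGE",
    "TREND_CHANGE",
    "wald_test",
]

_COEFFICIENTS = {
    "joint_change": ("beta2", "beta3"),
    "level_change": ("beta2",),
    "trend_change": ("beta3",),
}


@dataclass(frozen=True)
class Hypothesis:
    kind: str

    def __post_init__(self):
        if self.kind not in _COEFFICIENTS:
            raise ValueError(
                f"unknown hypothesis {self.kind!r}; expected one of {sorted(_COEFFICIENTS)}"
            )

    @property
    def coefficients(self) -> tuple:
        return _COEFFICIENTS[self.kind]

    @property
    def df(self) -> int:
        return len(self.coefficients)


JOINT_CHANGE = Hypothesis("joint_change")
LEVEL_CHANGE = Hypothesis("level_change")
TREND_CHANGE = Hypothesis("trend_change")


def hypothesis_from_string(name: str) -> Hypothesis:
    """Accept kind names and a few CLI-friendly aliases."""
    aliases = {"joint": "joint_change", "level": "level_change", "trend": "trend_change"}
    return Hypothesis(aliases.get(name, name))


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    reject: bool
    alpha: float
    hypothesis: Hypothesis


def wald_test(
    fit: FitResult, hypothesis: Hypothesis, alpha: float = 0.05
) -> TestResult:
    """W = r' V^{-1} r for the hypothesis' coefficient block of the fit.

    Refuses non-converged fits with :class:`NotConvergedError` and singular
    covariance blocks with :class:`SingularCovarianceError`; the power
    engine treats both as accounting events rather than failures.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    if not fit.converged:
        raise NotConvergedError(
            f"Wald test requires a converged fit ({fit.reason or 'not converged'})"
        )
    try:
        idx = [fit.param_names.index(c) for c in hypothesis.coefficients]
    except ValueError as exc:
        raise ConfigError(
            f"tested coefficient is not a free parameter of this fit: {exc}"
        ) from None
    r = np.array([fit.estimates[c] for c in hypothesis.coefficients])
    V = fit.cov[np.ix_(idx, idx)]
    try:
        c, low = cho_factor(V)
        w = float(r @ cho_solve((c, low), r))
    except np.linalg.LinAlgError:
        raise SingularCovarianceError(
            f"covariance block for {hypothesis.coefficients} is not positive definite"
        ) from None
    if not np.isfinite(w) or w < 0:
        raise SingularCovarianceError("Wald statistic is not a finite nonnegative number")
    p = float(chi2.sf(w, hypothesis.df))
    return TestResult(
        statistic=w,
        df=hypothesis.df,
        p_value=p,
        reject=bool(p < alpha),
        alpha=alpha,
        hypothesis=hypothesis,
    )
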