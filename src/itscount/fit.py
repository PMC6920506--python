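"""Conditional maximum-likelihood estimation for the LL(0,1) model.

Because the feedback term uses the observed previous count, the conditional
log likelihood is that of a generalized linear model with log link on the
augmented design matrix ``[1, T, X, D, ln(y_prev + 1)]``.  The likelihood is
smooth in all parameters, so fitting is a quasi-Newton (BFGS) maximization
with closed-form gradients; ``phi`` is optimized on the log scale to keep it
positive, and its covariance entry is mapped back to the natural scale by
the delta method.  The covariance matrix is the inverse of the observed
information (numerical Hessian of the negative log likelihood, central
differences of the analytic gradient).

Non-convergence is data, not an exception: it is reported in the
:class:`FitResult` and the caller (e.g. the power engine) decides its fate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .errors import ConfigError
from .model import CountSeries, linear_predictor_vector

__all__ = ["FitOptions", "FitResult", "initialize_params", "fit_mle"]

BETA_NAMES = ("beta0", "beta1", "beta2", "beta3")
PARAM_NAMES = BETA_NAMES + ("gamma1",)

_CLIP = 500.0  # bound on ln(mu) inside the objective; far outside any optimum
_PHI_FLOOR = 0.1
_N_RESTARTS = 3


@dataclass(frozen=True)
class FitOptions:
    """Optimizer controls.

    fixed_mask holds parameter name -> value pairs excluded from
    optimization; estimate_phi=False (negbin only) requires "phi" in the
    mask.
    """

    max_iter: int = 500
    grad_tol: float = 1e-4
    fixed_mask: dict | None = None
    estimate_phi: bool = True

    def __post_init__(self):
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not self.grad_tol > 0:
            raise ValueError("grad_tol must be positive")


@dataclass
class FitResult:
    """MLE estimates with observed-information covariance and diagnostics."""

    estimates: dict
    param_names: list  # free parameters, in covariance order
    cov: np.ndarray | None
    loglik: float
    converged: bool
    n_iter: int
    grad_norm: float
    family: str
    reason: str = ""
    degenerate_init: bool = False

    def se(self, name: str) -> float:
        """Standard error of a free parameter on the natural scale."""
        i = self.param_names.index(name)
        return float(np.sqrt(self.cov[i, i]))


def _design_matrix(series: CountSeries) -> np.ndarray:
    d = series.design
    return np.column_stack(
        [np.ones(d.n), d.T, d.X, d.D, np.log1p(series.y_prev)]
    )


def initialize_params(series: CountSeries, family: str) -> tuple[dict, bool]:
    """Starting values from a no-feedback least-squares fit of ln(y+1).

    Returns (params, degenerate) where degenerate flags an all-zero series,
    for which the data carry no slope information and the init falls back
    to a small constant mean.
    """
    init = {nm: 0.0 for nm in PARAM_NAMES}
    init["phi"] = 1.0
    if np.all(series.y == 0):
        init["beta0"] = float(np.log(0.01))
        return init, True
    d = series.design
    A = np.column_stack([np.ones(d.n), d.T, d.X, d.D])
    z = np.log1p(series.y.astype(float))
    beta, *_ = np.linalg.lstsq(A, z, rcond=None)
    for nm, b in zip(BETA_NAMES, beta):
        init[nm] = float(b)
    if family == "negbin":
        mu = np.exp(np.clip(A @ beta, -30, 30))
        excess = float(np.sum((series.y - mu) ** 2 - mu))
        if excess > 0:
            init["phi"] = max(float(np.sum(mu**2)) / excess, _PHI_FLOOR)
        else:
            init["phi"] = 100.0  # no overdispersion signal
    return init, False


def _make_objective(Z, y, family, free5_idx, theta_template, phi_free, phi_fixed):
    """Negative conditional log likelihood and its gradient in working coordinates.

    Working vector = free entries of (beta0..beta3, gamma1), then ln(phi)
    if phi is free.
    """
    k = len(free5_idx)
    gammaln_y1 = gammaln(y + 1.0)

    def fun(x):
        theta = theta_template.copy()
        theta[free5_idx] = x[:k]
        log_mu = np.clip(Z @ theta, -_CLIP, _CLIP)
        mu = np.exp(log_mu)
        if family == "poisson":
            ll = np.sum(-mu + y * log_mu - gammaln_y1)
            score_logmu = y - mu
            grad5 = Z.T @ score_logmu
            g = -grad5[free5_idx]
            return -ll, g
        phi = float(np.exp(np.clip(x[k], -20, 20))) if phi_free else phi_fixed
        ll = np.sum(
            gammaln(phi + y)
            - gammaln_y1
            - gammaln(phi)
            + phi * (np.log(phi) - np.log(phi + mu))
            + y * (log_mu - np.log(phi + mu))
        )
        score_logmu = phi * (y - mu) / (phi + mu)
        grad5 = Z.T @ score_logmu
        g = -grad5[free5_idx]
        if phi_free:
            dll_dphi = np.sum(
                digamma(phi + y)
                - digamma(phi)
                + np.log(phi)
                - np.log(phi + mu)
                + 1.0
                - (phi + y) / (phi + mu)
            )
            g = np.append(g, -dll_dphi * phi)  # chain rule for ln(phi)
        return -ll, g

    return fun


def _newton_polish(fun, x, tol, max_steps=8):
    """Newton refinement from the BFGS solution.

    BFGS can stall just above a tight gradient tolerance on long series;
    a few damped Newton steps with the exact (numerically differentiated)
    Hessian drive the gradient to machine-level precision.
    """
    nll, g = fun(x)
    for _ in range(max_steps):
        gnorm = np.max(np.abs(g)) if g.size else 0.0
        if gnorm < tol * 1e-3:
            break
        H = _numerical_hessian(fun, x)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        t = 1.0
        improved = False
        for _ in range(12):
            x_try = x - t * step
            nll_try, g_try = fun(x_try)
            if np.isfinite(nll_try) and (
                nll_try < nll or np.max(np.abs(g_try), initial=0.0) < gnorm
            ):
                x, nll, g = x_try, nll_try, g_try
                improved = True
                break
            t *= 0.5
        if not improved:
            break
    return x, nll, g


def _numerical_hessian(fun, x):
    """Central-difference Jacobian of the analytic gradient, symmetrized."""
    p = x.size
    H = np.empty((p, p))
    for i in range(p):
        h = 1e-5 * (1.0 + abs(x[i]))
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        _, gp = fun(xp)
        _, gm = fun(xm)
        H[i, :] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def fit_mle(
    series: CountSeries, family: str, options: FitOptions | None = None
) -> FitResult:
    """Maximize the conditional log likelihood over the free parameters.

    Restarts from jittered initial values (deterministically) when the
    first attempt does not reach the gradient tolerance.  A singular or
    indefinite observed information marks the fit non-converged with the
    reason recorded; no exception is raised for optimization failure.
    """
    if family not in ("poisson", "negbin"):
        raise ConfigError(f"unknown family {family!r}")
    opts = options or FitOptions()
    fixed = dict(opts.fixed_mask or {})
    if family == "negbin" and not opts.estimate_phi and "phi" not in fixed:
        raise ConfigError("estimate_phi=False requires a fixed value for 'phi'")
    phi_free = family == "negbin" and opts.estimate_phi and "phi" not in fixed
    phi_fixed = float(fixed["phi"]) if (family == "negbin" and "phi" in fixed) else None
    if phi_fixed is not None and not phi_fixed > 0:
        raise ConfigError(f"fixed phi must be positive, got {phi_fixed}")

    Z = _design_matrix(series)
    y = series.y.astype(float)
    init, degenerate = initialize_params(series, family)

    free5_names = [nm for nm in PARAM_NAMES if nm not in fixed]
    free5_idx = np.array([PARAM_NAMES.index(nm) for nm in free5_names], dtype=int)
    theta_template = np.array([float(fixed.get(nm, 0.0)) for nm in PARAM_NAMES])

    x0 = np.array([init[nm] for nm in free5_names], dtype=float)
    if phi_free:
        x0 = np.append(x0, np.log(max(init["phi"], _PHI_FLOOR)))
    free_names = list(free5_names) + (["phi"] if phi_free else [])

    fun = _make_objective(Z, y, family, free5_idx, theta_template, phi_free, phi_fixed)

    jitter_rng = np.random.default_rng(987654321)  # fixed: restarts must be reproducible
    best = None
    n_iter_total = 0
    for attempt in range(1 + _N_RESTARTS):
        x_start = x0 if attempt == 0 else x0 + jitter_rng.normal(
            0.0, 0.1 * (1.0 + np.abs(x0))
        )
        res = minimize(
            fun,
            x_start,
            jac=True,
            method="BFGS",
            options={"gtol": opts.grad_tol, "maxiter": opts.max_iter},
        )
        n_iter_total += int(res.nit)
        x_ref, nll, g = _newton_polish(fun, res.x, opts.grad_tol)
        gnorm = float(np.max(np.abs(g))) if g.size else 0.0
        cand = (gnorm >= opts.grad_tol, nll, gnorm, x_ref)
        if best is None or cand[:2] < best[:2]:
            best = cand
        if gnorm < opts.grad_tol:
            break

    failed, nll_opt, grad_norm, x_opt = best
    converged = not failed
    reason = "" if converged else "gradient tolerance not reached"

    theta = theta_template.copy()
    theta[free5_idx] = x_opt[: len(free5_idx)]
    estimates = {nm: float(v) for nm, v in zip(PARAM_NAMES, theta)}
    if family == "negbin":
        estimates["phi"] = (
            float(np.exp(x_opt[-1])) if phi_free else phi_fixed
        )

    cov = None
    if converged and free_names:
        H = _numerical_hessian(fun, x_opt)
        try:
            cov_work = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_work = None
        if cov_work is None or not np.all(np.isfinite(cov_work)) or np.any(
            np.diag(cov_work) < 0
        ):
            converged = False
            reason = "singular or indefinite observed information"
        else:
            # delta method: working coordinate for phi is ln(phi)
            scale = np.ones(len(free_names))
            if phi_free:
                scale[-1] = estimates["phi"]
            cov = scale[:, None] * cov_work * scale[None, :]
            cov = 0.5 * (cov + cov.T)

    return FitResult(
        estimates=estimates,
        param_names=free_names,
        cov=cov,
        loglik=-float(nll_opt),
        converged=converged,
        n_iter=n_iter_total,
        grad_norm=grad_norm,
        family=family,
        reason=reason,
        degenerate_init=degenerate,
    )
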