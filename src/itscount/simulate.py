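"""Forward simulation of LL(0,1) count series with explosion detection.

Series are generated by the same recursion the likelihood conditions on:
mu_t is computed from the previously *drawn* count, then y_t is drawn from
Poisson(mu_t) or NB(mu_t, phi).  Negative binomial draws use the
gamma-Poisson mixture (rate ~ Gamma(shape=phi, scale=mu/phi)), which has
mean mu and variance mu + mu**2/phi.

With strong positive feedback (|gamma1| near 1) the recursion can run away;
generation stops as soon as mu_t or y_t exceeds the explosion threshold and
the replicate is reported as a :class:`SimFailure` — failed replicates are
counted, never re-drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import CountSeries, ModelSpec, SegmentedDesign, linear_predictor_vector

__all__ = ["SimFailure", "BatchResult", "simulate_series", "simulate_batch"]

DEFAULT_EXPLOSION_THRESHOLD = 1e6

_LOG_OVERFLOW = 700.0


@dataclass(frozen=True)
class SimFailure:
    """A replicate whose generation stopped before reaching length n."""

    fail_index: int
    reason: str  # "threshold_exceeded" | "numeric_overflow"
    threshold: float


@dataclass
class BatchResult:
    """Successes and failure accounting for a batch of simulated replicates."""

    series: list[CountSeries]
    n_requested: int
    n_failed: int
    seeds: list[tuple[int, int]]  # (base_seed, replicate index) per replicate

    def __post_init__(self):
        if len(self.series) + self.n_failed != self.n_requested:
            raise ValueError("batch accounting violated: successes + failures != requested")


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_series(
    design: SegmentedDesign,
    spec: ModelSpec,
    y0: int = 0,
    seed=None,
    explosion_threshold: float = DEFAULT_EXPLOSION_THRESHOLD,
) -> CountSeries | SimFailure:
    """Draw one series of length design.n, or report where generation failed.

    ``seed`` may be an int, a ``numpy.random.SeedSequence``, or a Generator;
    identical (seed, spec, design, y0) reproduce the series bit for bit.
    """
    if not explosion_threshold > 0:
        raise ValueError(f"explosion_threshold must be positive, got {explosion_threshold}")
    rng = _resolve_rng(seed)
    eta = linear_predictor_vector(design, spec.reg)
    gamma1 = spec.dep.gamma1
    log_thresh = np.log(explosion_threshold)

    y = np.empty(design.n, dtype=np.int64)
    mu = np.empty(design.n, dtype=float)
    y_prev = int(y0)
    for i in range(design.n):
        log_mu = eta[i] + gamma1 * np.log1p(y_prev)
        if not np.isfinite(log_mu) or log_mu > _LOG_OVERFLOW:
            return SimFailure(i + 1, "numeric_overflow", explosion_threshold)
        if log_mu > log_thresh:
            return SimFailure(i + 1, "threshold_exceeded", explosion_threshold)
        m = float(np.exp(log_mu))
        if spec.family == "poisson":
            y_t = int(rng.poisson(m))
        else:
            lam = rng.gamma(shape=spec.phi, scale=m / spec.phi)
            if not np.isfinite(lam):
                return SimFailure(i + 1, "numeric_overflow", explosion_threshold)
            if lam > explosion_threshold * 10:
                return SimFailure(i + 1, "threshold_exceeded", explosion_threshold)
            y_t = int(rng.poisson(lam))
        if y_t > explosion_threshold:
            return SimFailure(i + 1, "threshold_exceeded", explosion_threshold)
        y[i] = y_t
        mu[i] = m
        y_prev = y_t
    return CountSeries(design=design, y=y, y0=int(y0), mu=mu)


def replicate_seed(base_seed: int, r: int) -> np.random.SeedSequence:
    """Deterministic child seed for replicate r of a batch."""
    return np.random.SeedSequence(entropy=base_seed, spawn_key=(r,))


def simulate_batch(
    R: int,
    design: SegmentedDesign,
    spec: ModelSpec,
    y0: int = 0,
    base_seed: int = 0,
    explosion_threshold: float = DEFAULT_EXPLOSION_THRESHOLD,
) -> BatchResult:
    """Draw R replicates with per-replicate child seeds derived from base_seed.

    Failed replicates are dropped from ``series`` and counted in
    ``n_failed``; they are never replaced, so the batch accounting
    identity len(series) + n_failed == R always holds.
    """
    if R < 1:
        raise ValueError(f"R must be >= 1, got {R}")
    series: list[CountSeries] = []
    seeds: list[tuple[int, int]] = []
    n_failed = 0
    for r in range(R):
        seeds.append((base_seed, r))
        out = simulate_series(
            design,
            spec,
            y0=y0,
            seed=replicate_seed(base_seed, r),
            explosion_threshold=explosion_threshold,
        )
        if isinstance(out, SimFailure):
            n_failed += 1
        else:
            series.append(out)
    return BatchResult(series=series, n_requested=R, n_failed=n_failed, seeds=seeds)
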