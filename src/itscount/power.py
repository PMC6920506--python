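"""Monte Carlo power estimation and sample-size search over scenario grids.

Empirical power of a Wald test is the fraction of simulated replicates in
which the null is rejected at the nominal level.  A scenario fixes the data
generating model (family, segmented coefficients, feedback gamma1,
dispersion phi), the design (n, log-time, equal pre/post split), the
replication count R and the significance level; the engine simulates R
series, fits each by conditional MLE, applies the requested Wald test, and
keeps full accounting of generation failures (exploded recursions) and
non-converged fits.

A cell is reported NA — mirroring the "-" convention of published power
tables for this design — when more than a quarter of the R replicates fail
to generate; convergence failures are handled symmetrically.  By default
power divides rejections by the number of converged fits; the literal
divide-by-R convention is available via ``denominator="requested"``.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, NotConvergedError, SingularCovarianceError
from .fit import FitOptions, fit_mle
from .infer import Hypothesis, hypothesis_from_string, wald_test
from .model import DependenceParams, ModelSpec, RegressionParams, build_design
from .simulate import (
    DEFAULT_EXPLOSION_THRESHOLD,
    SimFailure,
    replicate_seed,
    simulate_series,
)

__all__ = [
    "Scenario",
    "PowerCell",
    "PowerTable",
    "split_total_effect",
    "estimate_power",
    "power_table",
    "sample_size_for_power",
    "DEFAULT_GAMMA1_GRID",
    "DEFAULT_N_GRID",
]

logger = logging.getLogger(__name__)

# the canonical simulation grids: gamma1 from -0.9 to 0.9 in steps of 0.2
# plus the uncorrelated case 0, and the eight even sample sizes
DEFAULT_GAMMA1_GRID = tuple(
    sorted(np.round(np.arange(-0.9, 1.0, 0.2), 1).tolist() + [0.0])
)
DEFAULT_N_GRID = (18, 24, 32, 48, 56, 64, 80, 96)


def split_total_effect(total: float, rule: str, weight: float | None = None):
    """Allocate a total intervention effect beta2 + beta3 to the two coefficients.

    equal -> (total/2, total/2); level_only -> (total, 0);
    trend_only -> (0, total); custom -> (w*total, (1-w)*total).
    """
    if rule == "equal":
        return total / 2.0, total / 2.0
    if rule == "level_only":
        return total, 0.0
    if rule == "trend_only":
        return 0.0, total
    if rule == "custom":
        if weight is None or not (0.0 <= weight <= 1.0):
            raise ConfigError(f"custom split requires weight in [0, 1], got {weight}")
        return weight * total, (1.0 - weight) * total
    raise ConfigError(f"unknown split rule {rule!r}")


@dataclass(frozen=True)
class Scenario:
    """One data-generating condition of the Monte Carlo study.

    The intervention effect may be given explicitly (beta2, beta3) or as a
    total_change = beta2 + beta3 with a split rule.  beta0 and beta1 are
    nuisance parameters of the pre-intervention log mean; defaults 2.0 and
    0.1 with log time give pre-intervention means around 7-12, a plausible
    weekly event-count range.
    """

    family: str = "poisson"
    n: int = 18
    gamma1: float = 0.0
    beta2: float | None = None
    beta3: float | None = None
    total_change: float | None = None
    split_rule: str = "equal"
    split_weight: float | None = None
    beta0: float = 2.0
    beta1: float = 0.1
    phi: float = 2.0
    y0: int = 0
    transform: str = "log"
    anchor: str = "transformed"
    explosion_threshold: float = DEFAULT_EXPLOSION_THRESHOLD
    R: int = 200
    alpha: float = 0.05
    hypothesis: Hypothesis | str = "joint_change"
    base_seed: int = 0
    estimate_phi: bool = True
    denominator: str = "converged"  # or "requested"
    na_threshold: float | None = None  # generation-failure count above which a cell is NA; default R/4

    def __post_init__(self):
        if self.family not in ("poisson", "negbin"):
            raise ConfigError(f"unknown family {self.family!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.R < 1:
            raise ConfigError(f"R must be >= 1, got {self.R}")
        if self.n < 4 or self.n % 2 != 0:
            raise ConfigError(f"n must be an even integer >= 4, got {self.n}")
        if self.denominator not in ("converged", "requested"):
            raise ConfigError(f"unknown denominator {self.denominator!r}")
        if self.transform not in ("log", "identity"):
            raise ConfigError(f"unknown transform {self.transform!r}")
        if self.anchor not in ("transformed", "raw"):
            raise ConfigError(f"unknown anchor {self.anchor!r}")
        if self.total_change is not None and (
            self.beta2 is not None or self.beta3 is not None
        ):
            raise ConfigError("give either total_change or explicit beta2/beta3, not both")
        if self.family == "negbin" and not self.phi > 0:
            raise ConfigError(f"negbin requires phi > 0, got {self.phi}")

    def effect(self) -> tuple:
        """Resolve (beta2, beta3) from whichever parameterization was given."""
        if self.total_change is not None:
            return split_total_effect(self.total_change, self.split_rule, self.split_weight)
        return (self.beta2 or 0.0, self.beta3 or 0.0)

    def resolved_hypothesis(self) -> Hypothesis:
        h = self.hypothesis
        return h if isinstance(h, Hypothesis) else hypothesis_from_string(h)

    def model_spec(self) -> ModelSpec:
        b2, b3 = self.effect()
        return ModelSpec(
            family=self.family,
            reg=RegressionParams(self.beta0, self.beta1, b2, b3),
            dep=DependenceParams(self.gamma1),
            phi=self.phi if self.family == "negbin" else None,
        )


@dataclass(frozen=True)
class PowerCell:
    """Empirical power with full generation/convergence accounting."""

    power: float | None
    n_generated: int
    n_converged: int
    n_rejected: int
    status: str  # "ok" | "NA_generation" | "NA_convergence"

    @property
    def is_na(self) -> bool:
        return self.status != "ok"


@dataclass
class PowerTable:
    """PowerCells over a gamma1 (rows) by n (columns) grid."""

    gamma1_grid: list
    n_grid: list
    cells: list  # cells[i][j] for gamma1_grid[i], n_grid[j]
    scenario: Scenario

    def cell(self, gamma1: float, n: int) -> PowerCell:
        return self.cells[self.gamma1_grid.index(gamma1)][self.n_grid.index(n)]


def _fit_options(scenario: Scenario) -> FitOptions:
    if scenario.family == "negbin" and not scenario.estimate_phi:
        return FitOptions(estimate_phi=False, fixed_mask={"phi": scenario.phi})
    return FitOptions()


def estimate_power(scenario: Scenario) -> PowerCell:
    """Simulate, fit and test R replicates; return the accounted cell.

    Deterministic in scenario.base_seed: replicate r uses the child seed
    (base_seed, r).  Generation failures and non-converged fits are dropped
    from the rejection denominator but fully counted; a converged fit whose
    Wald block is singular counts as a convergence failure.
    """
    design = build_design(scenario.n, scenario.transform, "auto", scenario.anchor)
    spec = scenario.model_spec()
    hyp = scenario.resolved_hypothesis()
    opts = _fit_options(scenario)
    na_thresh = scenario.na_threshold if scenario.na_threshold is not None else scenario.R / 4.0

    n_generated = n_converged = n_rejected = 0
    t_start = time.perf_counter()
    for r in range(scenario.R):
        sim = simulate_series(
            design,
            spec,
            y0=scenario.y0,
            seed=replicate_seed(scenario.base_seed, r),
            explosion_threshold=scenario.explosion_threshold,
        )
        if isinstance(sim, SimFailure):
            continue
        n_generated += 1
        fit = fit_mle(sim, scenario.family, opts)
        if not fit.converged:
            continue
        try:
            res = wald_test(fit, hyp, scenario.alpha)
        except (NotConvergedError, SingularCovarianceError):
            continue
        n_converged += 1
        if res.reject:
            n_rejected += 1

    if scenario.R - n_generated > na_thresh:
        status, power = "NA_generation", None
    elif n_generated - n_converged > na_thresh or n_converged == 0:
        status, power = "NA_convergence", None
    else:
        denom = n_converged if scenario.denominator == "converged" else scenario.R
        status, power = "ok", n_rejected / denom
    logger.info(
        "power cell family=%s n=%d gamma1=%.2f hyp=%s seed=%d: "
        "generated=%d converged=%d rejected=%d status=%s (%.1fs)",
        scenario.family,
        scenario.n,
        scenario.gamma1,
        hyp.kind,
        scenario.base_seed,
        n_generated,
        n_converged,
        n_rejected,
        status,
        time.perf_counter() - t_start,
    )
    return PowerCell(
        power=power,
        n_generated=n_generated,
        n_converged=n_converged,
        n_rejected=n_rejected,
        status=status,
    )


def _cell_seed(base_seed: int, i: int, j: int) -> int:
    """Independent derived seed for grid cell (i, j)."""
    return int(np.random.SeedSequence(base_seed, spawn_key=(i, j)).generate_state(1)[0])


def power_table(
    scenario_template: Scenario,
    gamma1_grid=DEFAULT_GAMMA1_GRID,
    n_grid=DEFAULT_N_GRID,
) -> PowerTable:
    """One estimate_power call per (gamma1, n) cell with independent seeds.

    Rows are ordered by ascending gamma1 and columns by ascending n, the
    layout conventional for published ITS power tables (11 x 8 = 88 cells
    on the default grids).
    """
    gamma1_grid = list(gamma1_grid)
    n_grid = list(n_grid)
    if not gamma1_grid or not n_grid:
        raise ConfigError("grids must be nonempty")
    cells = []
    for i, g1 in enumerate(sorted(gamma1_grid)):
        row = []
        for j, n in enumerate(sorted(n_grid)):
            sc = replace(
                scenario_template,
                gamma1=g1,
                n=int(n),
                base_seed=_cell_seed(scenario_template.base_seed, i, j),
            )
            row.append(estimate_power(sc))
        cells.append(row)
    return PowerTable(
        gamma1_grid=sorted(gamma1_grid),
        n_grid=sorted(int(n) for n in n_grid),
        cells=cells,
        scenario=scenario_template,
    )


def sample_size_for_power(
    scenario_template: Scenario,
    target_power: float,
    n_candidates,
) -> int | None:
    """Smallest candidate n whose estimated power reaches the target.

    Candidates are evaluated in ascending order with independent derived
    seeds; NA cells never qualify.  Returns None when no candidate reaches
    the target.
    """
    cands = list(n_candidates)
    if not cands:
        raise ConfigError("n_candidates must be nonempty")
    if cands != sorted(cands):
        raise ConfigError("n_candidates must be sorted ascending")
    if any(n % 2 != 0 for n in cands):
        raise ConfigError("all candidate n must be even")
    if not (0.0 < target_power < 1.0):
        raise ConfigError(f"target_power must lie in (0, 1), got {target_power}")
    for k, n in enumerate(cands):
        sc = replace(
            scenario_template,
            n=int(n),
            base_seed=_cell_seed(scenario_template.base_seed, 0, k),
        )
        cell = estimate_power(sc)
        if cell.status == "ok" and cell.power >= target_power:
            return int(n)
    return None
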