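"""Shared fixtures and independent oracles for the test suite.

The expensive Monte Carlo computations (null-calibration at n=96 and the
parameter-recovery grid at n=2000) are session-scoped so that module-level
property tests and the acceptance checks share one run.
"""

import math

import numpy as np
import pytest
from scipy import stats

import itscount as ic
from itscount.simulate import replicate_seed, simulate_series


def bruteforce_loglik(y, y0, design, beta, gamma1, family, phi=None):
    """Independent recursion-and-sum log likelihood, one time point at a time.

    Uses scipy.stats densities (negative binomial in the size/prob dialect,
    size=phi, prob=phi/(phi+mu)) rather than the package's pmf code.
    """
    ll = 0.0
    y_prev = y0
    for i in range(len(y)):
        eta = (
            beta[0]
            + beta[1] * design.T[i]
            + beta[2] * design.X[i]
            + beta[3] * design.D[i]
        )
        mu = math.exp(eta + gamma1 * math.log(y_prev + 1))
        if family == "poisson":
            ll += stats.poisson.logpmf(y[i], mu)
        else:
            ll += stats.nbinom.logpmf(y[i], phi, phi / (phi + mu))
        y_prev = int(y[i])
    return float(ll)


def random_small_series(rng, family):
    """A small random series with moderate random parameters."""
    n = int(rng.choice([4, 6, 8]))
    design = ic.build_design(n, rng.choice(["log", "identity"]))
    beta = rng.uniform(-1, 1, size=4)
    beta[0] = rng.uniform(-0.5, 1.5)
    gamma1 = rng.uniform(-0.8, 0.8)
    phi = float(rng.uniform(0.5, 5.0))
    y = rng.integers(0, 10, size=n)
    y0 = int(rng.integers(0, 5))
    series = ic.CountSeries(design=design, y=y, y0=y0)
    return series, beta, gamma1, phi


NULL_SEED = 0
NULL_R = 1000
NULL_N = 96


@pytest.fixture(scope="session")
def null_calibration():
    """Rejection fractions of all three Wald tests under the global null.

    Poisson LL(0,1), gamma1=0, beta=(2.0, 0.1, 0, 0), n=96, 1000 replicates
    at alpha=0.05.  Returns (rates dict, n_converged).
    """
    design = ic.build_design(NULL_N)
    spec = ic.ModelSpec(
        "poisson",
        ic.RegressionParams(2.0, 0.1, 0.0, 0.0),
        ic.DependenceParams(0.0),
    )
    hyps = [ic.JOINT_CHANGE, ic.LEVEL_CHANGE, ic.TREND_CHANGE]
    rejections = {h.kind: 0 for h in hyps}
    n_converged = 0
    for r in range(NULL_R):
        sim = simulate_series(design, spec, seed=replicate_seed(NULL_SEED, r))
        assert not isinstance(sim, ic.SimFailure)
        fit = ic.fit_mle(sim, "poisson")
        if not fit.converged:
            continue
        n_converged += 1
        for h in hyps:
            if ic.wald_test(fit, h, 0.05).reject:
                rejections[h.kind] += 1
    rates = {k: v / n_converged for k, v in rejections.items()}
    return rates, n_converged


RECOVERY_TRUTH = {
    "beta0": 2.0,
    "beta1": 0.1,
    "beta2": -0.5,
    "beta3": -0.05,
    "phi": 2.0,
}
RECOVERY_N = 2000
RECOVERY_REPS = 50


@pytest.fixture(scope="session")
def recovery_grid():
    """Mean estimates and mean SEs over 50 long-series replicates.

    Keyed by (family, gamma1) for gamma1 in {-0.5, 0, 0.5} and both
    families; truth beta=(2, 0.1, -0.5, -0.05), phi=2 for negbin.
    """
    design = ic.build_design(RECOVERY_N)
    out = {}
    for fam_i, family in enumerate(("poisson", "negbin")):
        for g_i, gamma1 in enumerate((-0.5, 0.0, 0.5)):
            truth = dict(RECOVERY_TRUTH)
            truth["gamma1"] = gamma1
            if family == "poisson":
                truth.pop("phi")
            spec = ic.ModelSpec(
                family,
                ic.RegressionParams(
                    truth["beta0"], truth["beta1"], truth["beta2"], truth["beta3"]
                ),
                ic.DependenceParams(gamma1),
                phi=truth.get("phi"),
            )
            est = {k: [] for k in truth}
            ses = {k: [] for k in truth}
            for r in range(RECOVERY_REPS):
                seed = np.random.SeedSequence(2026, spawn_key=(fam_i, g_i, r))
                sim = simulate_series(design, spec, seed=seed)
                assert not isinstance(sim, ic.SimFailure)
                fit = ic.fit_mle(sim, family)
                assert fit.converged
                for k in truth:
                    est[k].append(fit.estimates[k])
                    ses[k].append(fit.se(k))
            out[(family, gamma1)] = {
                "truth": truth,
                "mean_est": {k: float(np.mean(v)) for k, v in est.items()},
                "mean_se": {k: float(np.mean(v)) for k, v in ses.items()},
            }
    return out


MONO_R = 1000


@pytest.fixture(scope="session")
def monotonicity_ladders():
    """Empirical power along 3-point ladders in n and in |beta2|.

    Poisson level-change test, gamma1=0, R=1000 per point.  Returns
    {"n": [(n, power)...], "effect": [(beta2, power)...], "R": R}.
    """
    from itscount.power import Scenario, estimate_power

    def cell(**kw):
        c = estimate_power(
            Scenario(
                family="poisson",
                gamma1=0.0,
                hypothesis="level_change",
                R=MONO_R,
                base_seed=37,
                **kw,
            )
        )
        assert c.status == "ok"
        return c.power

    return {
        "n": [(n, cell(n=n, beta2=-0.5)) for n in (18, 32, 64)],
        "effect": [(b, cell(n=32, beta2=-b)) for b in (0.25, 0.5, 1.0)],
        "R": MONO_R,
    }
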