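# Methods

## Model

`itscount` models a single-arm, two-phase interrupted time series of counts
Y₁, …, Y_n with an observation-driven log-linear conditional mean:

    ln(μ_t) = η_t + γ₁ ln(Y_{t−1} + 1),        μ_t = E[Y_t | F_{t−1}]
    η_t     = β₀ + β₁ T_t + β₂ X_t + β₃ D_t

with conditional distribution Poisson(μ_t) or negative binomial NB(μ_t, φ)
in the mean/overdispersion parameterization (variance μ_t + μ_t²/φ). This
is the log-linear model of order (0, 1): the log mean feeds back on the log
of the single previous observation only; higher orders, GLARMA-type
residual feedback and parameter-driven (latent-process) models are out of
scope. Because the feedback term involves the *observed* lagged count, the
conditional likelihood is available in closed form — it is exactly a
generalized linear model with log link on the augmented design
[1, T, X, D, ln(y_prev+1)] — and is maximized directly. The likelihood is
conditional on the seed value Y₀; the initial state is not marginalized.

For constant η and Poisson response the recursion has a stationary
distribution when |γ₁| < 1; constructing `DependenceParams` outside that
range warns (`NonstationaryWarning`) but does not error, since exploring
the explosive regime is part of the package's purpose.

## Design variables

Time runs t = 1..n. The default transform is T_t = ln(t) (so T₁ = 0);
log time damps the otherwise super-exponential growth of the feedback
recursion. The phase indicator X_t switches on at the intervention index
t₀, by default n/2 + 1 (equal pre/post split, n even ≥ 4). The
post-intervention elapsed-time term is

    D_t = (T_t − T_{t₀}) · X_t.

Two conventions are conceivable for the anchor subtracted in D_t — the
transformed time T_{t₀} or the raw index t₀. With log time the raw-index
version mixes scales, so the transformed anchor is the default; it keeps
β₃ interpretable as the post-intervention change in slope per unit
transformed time and makes D zero at the first post point, so β₂ alone
carries the immediate level change there. The raw-index variant remains
available (`anchor="raw"`) for sensitivity analysis.

## Estimation

Free parameters are (β₀..β₃, γ₁) plus φ for the negative binomial, any of
which can be held fixed via `FitOptions.fixed_mask`. φ is optimized as
ln(φ) to enforce positivity and mapped back with the delta method.
Starting values come from least squares of ln(y+1) on [1, T, X, D] with
γ₁ = 0 and a method-of-moments φ from squared residuals (floored at 0.1);
an all-zero series falls back to a small-constant-mean init and is
flagged. Optimization is BFGS with closed-form gradients, followed by a
few damped Newton steps using the numerically differentiated Hessian —
BFGS alone can stall just above a tight gradient tolerance on long
series, while the Newton polish drives the gradient to ~1e-7. A fit is
declared converged when the gradient max-norm falls below `grad_tol`
(default 1e-4); otherwise up to three deterministic jittered restarts are
tried. Non-convergence is reported in the `FitResult`, never raised.

The covariance is the inverse observed information — a central-difference
Jacobian of the analytic gradient at the optimum (step 1e-5·(1+|x|),
symmetrized). A singular or indefinite information marks the fit
non-converged with the reason recorded. No sandwich/robust correction is
applied; the Wald construction below uses the classical observed
information.

## Hypothesis tests

The three ITS nulls are β₂ = β₃ = 0 (joint, 2 df), β₂ = 0 (level) and
β₃ = 0 (trend). The statistic is W = r̂ᵀ V̂⁻¹ r̂ with V̂ the corresponding
covariance block (Cholesky solve; a non-positive-definite block raises a
typed error). p-values come from the upper χ² tail; testing is two-sided
through the quadratic form, and rejection uses strict inequality p < α —
at the boundary p = α the null is retained. For 1 df, W equals
(estimate/SE)² exactly.

## Simulation

Series are generated by the same recursion forward in time, drawing y_t
from Poisson(μ_t) or, for the negative binomial, from the gamma–Poisson
mixture (rate ~ Gamma(shape φ, scale μ_t/φ)), which reproduces the
mean/variance pair exactly. Y₀ defaults to 0. Generation fails — returning
a `SimFailure` with the failing index, never an exception — as soon as μ_t
or y_t exceeds the explosion threshold (default 1e6 on both, configurable)
or any intermediate is non-finite. Failed replicates are counted, never
re-drawn. Replicate r of a batch uses the child seed
`SeedSequence(base_seed, spawn_key=(r,))`, so batches are bit-for-bit
reproducible and trivially parallelizable.

A practical note on the explosive regime: with the default threshold the
explosion of a scenario is close to an all-or-none property of (β₀, γ₁, n)
— the late-time quasi-stationary mean either sits above the threshold or
below it, and Poisson noise on the log scale is tiny once counts are
large. Partial failure fractions therefore occur only in narrow parameter
windows (or with thresholds placed inside the count distribution's tail,
which is how the NA-accounting code paths are exercised in the tests).

## Power engine

A `Scenario` fixes the generating model, design, replication count R and
level α. `estimate_power` simulates R series, fits each, applies the
requested Wald test and keeps full accounting: generation failures,
non-converged fits (a converged fit whose tested covariance block is
singular counts as a convergence failure), and rejections. A cell is
reported NA when more than R/4 replicates fail to generate — the
convention used for dashes in published power tables for this design —
and symmetrically (the threshold is configurable via `na_threshold`) when
more than R/4 of the generated replicates fail to converge. Power is
n_rejected/n_converged by default; the literal divide-by-R convention is
available via `denominator="requested"`. `power_table` runs one cell per
(γ₁, n) pair with independent derived seeds; the default grids are
γ₁ ∈ {−0.9, −0.7, …, 0.9} ∪ {0} (11 rows) and
n ∈ {18, 24, 32, 48, 56, 64, 80, 96}. `sample_size_for_power` scans an
ascending candidate list and returns the first n whose (non-NA) estimate
reaches the target.

## Defaults and what they mean

| parameter | default | units / role |
|---|---|---|
| β₀ | 2.0 | starting log mean; with β₁ = 0.1 and log time, pre-intervention means ≈ 7–12 — plausible weekly event counts |
| β₁ | 0.1 | pre-intervention slope per unit ln(t) |
| φ | 2.0 | negbin overdispersion (variance μ + μ²/2) |
| γ₁ | 0.0 | no serial dependence unless the scenario sets it |
| y₀ | 0 | seed count |
| R | 200 | Monte Carlo replicates per cell |
| α | 0.05 | nominal level of every Wald test |
| threshold | 1e6 | explosion bound on μ_t and y_t |
| transform | log | T_t = ln t |
| split | equal | β₂ = β₃ = total/2 when an effect is given as β₂+β₃ |

β₀ and β₁ deserve emphasis: mid-range power values depend materially on
this calibration (power grows with the information content of the counts),
so published mid-table values under *other* unstated calibrations will not
be matched cell-for-cell. Size under the null, recovery on long series,
near-null power ≈ α and fully saturated cells are robust to it. The split
of a total effect β₂+β₃ between the two coefficients also matters for
joint-test power (a level-only allocation is considerably easier to
detect than an equal one at the default design); it is therefore an
explicit, visible scenario field rather than a hidden constant. φ is
*estimated* by default when fitting negative binomial scenarios —
realistic analyst behavior — and can be fixed via `fixed_mask` for
sensitivity comparison.

## What the generator does and does not emulate

The simulator produces exactly the single-arm, two-phase, aggregate-level
count series the model describes: one intervention at a known time, equal
phase lengths, no control arm, no ramp-up period, no seasonality,
covariates limited to the segmented time terms, and no zero inflation
beyond what the conditional distributions imply. Passing tests therefore
demonstrate internal statistical correctness (calibration, recovery,
monotonicity) under the model's own assumptions — not robustness to the
misspecifications real policy data bring (overlapping interventions,
seasonal cycles, reporting artifacts, excess zeros).

## Numerical choices

* ln Γ is always computed via `scipy.special.gammaln`; factorials are never
  formed.
* Inside the optimizer the log mean is clipped to ±500 to keep early
  iterations finite; the bound is far outside any realistic optimum, and
  the final gradient check is performed on the unclipped model.
* Negative binomial draws could alternatively use a direct NB sampler; the
  gamma–Poisson route is used because it is exact for real-valued φ.
* The restart jitter RNG is fixed, so fitting is a pure function of the
  data and options.
* Wald solves use a Cholesky factorization; asymmetry in the stored
  covariance is removed by symmetrization after inversion.

## Known limitations

* **Hauck–Donner behavior.** Very large *negative* level effects empty the
  post-intervention period; the MLE of β₂ diverges, its SE explodes and
  the Wald statistic collapses toward zero, so empirical power *decreases*
  again for extreme negative effects. This is a property of Wald tests
  under separation, visible as declining large-effect cells in published
  grids for this design; likelihood-ratio tests would behave differently
  but are intentionally not a user-facing feature.
* Wald tests run slightly liberal in small samples (empirical size ≈ 0.06
  at n = 96 under the Poisson null, larger for the negative binomial with
  estimated φ at small n); no small-sample correction is applied.
* Standard errors assume a correctly specified family; there is no
  sandwich option.
* LL(p, q) beyond (0, 1), two-arm and three-phase designs, and
  zero-inflated families are out of scope.

## Problem sizes used in the test suite

The suite's Monte Carlo checks use 1000 replicates for null-calibration
and monotonicity ladders, 50 replicates of length 2000 per cell for
parameter recovery, 100 series of length 1000 for dispersion recovery,
and R = 200 for single power cells — sizes chosen so the whole suite
completes in about a minute while keeping Monte Carlo error small
relative to every asserted tolerance.
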