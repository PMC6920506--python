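# itscount

Segmented regression, inference and simulation-based power analysis for
**interrupted time series (ITS) of count outcomes**.

ITS is the workhorse quasi-experimental design for evaluating health-policy
and public-health interventions: an aggregate outcome (weekly recruitments,
monthly injury counts, …) is observed repeatedly before and after a clearly
timed intervention, and the analysis asks whether the intervention shifted
the *level* and/or the *trend* of the outcome. For count outcomes the usual
Gaussian segmented regression does not apply; `itscount` implements the
observation-driven log-linear model of order (0, 1) — **LL(0,1)** — in which
the conditional mean depends on the segmented covariates and on the previous
count:

```
ln(μ_t) = β₀ + β₁ T_t + β₂ X_t + β₃ (T_t − T_{t₀}) X_t + γ₁ ln(Y_{t−1} + 1)
```

* `T_t` — study time, by default ln(t) (log time tempers explosive feedback),
* `X_t` — indicator of the post-intervention phase (t ≥ t₀),
* `β₂` — immediate **level change** of the log conditional mean,
* `β₃` — **trend change** after the intervention,
* `γ₁` — strength of dependence on the last observation
  (|γ₁| < 1 for a stationary regime),

with `Y_t | past ~ Poisson(μ_t)` or negative binomial with mean `μ_t` and
variance `μ_t + μ_t²/φ` (overdispersion `φ > 0`; `φ → ∞` recovers Poisson).

The package provides:

* exact conditional maximum-likelihood fitting (the feedback term uses the
  *observed* lagged count, so the likelihood factorizes and no integration
  is needed), with observed-information standard errors;
* Wald χ² tests of the three ITS hypotheses — joint change (β₂ = β₃ = 0,
  2 df), level change (β₂ = 0) and trend change (β₃ = 0);
* a reproducible forward simulator with explosion detection (runaway
  feedback paths are counted as generation failures, never re-drawn);
* a Monte Carlo **power engine** over γ₁ × n scenario grids with the
  "more than one quarter failed ⇒ cell is NA" accounting rule, and a
  sample-size search for a target power.

## Worked example

```python
import itscount as ic
from itscount.power import Scenario, estimate_power

design = ic.build_design(n=48, transform="log")          # 24 pre + 24 post points
spec = ic.ModelSpec(
    family="poisson",
    reg=ic.RegressionParams(beta0=2.0, beta1=0.1, beta2=-0.5, beta3=-0.05),
    dep=ic.DependenceParams(gamma1=0.3),
)
series = ic.simulate_series(design, spec, y0=0, seed=42)

fit = ic.fit_mle(series, "poisson")
for hyp in (ic.JOINT_CHANGE, ic.LEVEL_CHANGE, ic.TREND_CHANGE):
    t = ic.wald_test(fit, hyp, alpha=0.05)
    print(f"{hyp.kind:13s} W={t.statistic:6.3f} df={t.df} p={t.p_value:.4f}")

cell = estimate_power(Scenario(
    family="poisson", n=48, gamma1=0.3, beta2=-0.5, beta3=0.0,
    hypothesis="level_change", R=200, alpha=0.05, base_seed=1,
))
print(f"power={cell.power:.2f}")
```

prints

```
joint_change  W=18.570 df=2 p=0.0001
level_change  W=13.607 df=1 p=0.0002
trend_change  W= 0.056 df=1 p=0.8132
power=0.97
```

The fitted model recovers the simulated level drop (β̂₂ = −0.54, SE 0.15):
the level and joint tests reject while the trend test does not — the
simulated trend change (−0.05) is far too small to detect at n = 48. The
power cell says that under this scenario a true level change of −0.5 would
be detected 97% of the time with 200 Monte Carlo replicates.

The same workflow is available from the shell:

```
itscount simulate    --config scenario.yaml --out series.csv
itscount fit         --input series.csv --family poisson --out fit.json
itscount test        --fit-json fit.json --hypothesis level_change
itscount power-table --config scenario.yaml --out results/
itscount sample-size --config scenario.yaml --target-power 0.8 --candidates 18,24,32,48
```

`power-table` writes a long-format CSV (full precision, per-cell
generation/convergence accounting) and a wide-format CSV shaped like the
conventional published power tables (γ₁ rows × n columns, two decimals,
`-` for NA cells).

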