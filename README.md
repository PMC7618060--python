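# lowprev

Feasibility calculations for clinical risk-prediction studies of
low-prevalence outcomes.

When the outcome of interest is rare — death by suicide is the motivating
example, with prevalence usually below 1% even in clinical populations —
prediction studies face two compounding obstacles:

1. **Sample size.** Detecting a binary risk factor with relative risk RR,
   carried by a fraction *f* of the population, against a baseline risk
   *r₀* in factor-negative individuals, requires a two-proportion
   comparison of *p₁ = r₀·RR* versus *p₂ = r₀*. At *r₀* = 1% the required
   cohorts run into the thousands for entirely plausible effect sizes,
   and model development multiplies the requirement further (the
   events-per-variable rule of thumb: at least 10 outcome events per
   candidate predictor).

2. **Predictive performance.** For a dichotomised marker with sensitivity
   *S* applied at prevalence *p*, the relative risk it must carry to
   achieve a given positive predictive value is

   RR = (PPV − p·S) / (p·(1 − S)),

   which is bounded below by PPV/p as *S* → 0. At 1% prevalence a PPV of
   50% therefore demands RR ≥ 50 — far beyond effect sizes observed in
   practice. Equivalently in odds form, moving a 1% pre-test probability
   to 10%, 25% or 50% requires a positive likelihood ratio
   LR+ = S/(1 − specificity) of exactly 11, 33 or 99.

The package computes both sides of this trade-off in closed form
(`risk_algebra`, `sample_size`), tabulates the curves (`curves`),
validates every closed form against direct Monte-Carlo simulation of 2×2
cohorts (`cohort_sim`), and bundles the whole argument into a single
feasibility report (`report`, CLI `lowprev`).

## Worked example

```bash
lowprev report -p 1% --rr 2 --baseline-risk 1% -f 0.5 -f 0.1 \
    --events 222 --predictors 2978
```

prints

```
Feasibility report
==================
tool version: 0.1.0

Outcome prevalence: 0.01 (1%)

Likelihood ratio required to reach each post-test probability:
  0.01 (1%) -> 0.1 (10%): LR+ = 11
  0.01 (1%) -> 0.25 (25%): LR+ = 33
  0.01 (1%) -> 0.5 (50%): LR+ = 99

Sample size to detect RR = 2 at baseline risk 0.01 (1%) (alpha 0.05 two-sided, power 0.9, pooled variant):
  f = 0.5: total n = 6,206 (3,103 exposed / 3,103 unexposed; ~93.1 expected events)
  f = 0.1: total n = 15,990 (1,599 exposed / 14,391 unexposed; ~175.9 expected events)

Events-per-variable rule (10 events per predictor): 222 events support at most 22 predictors; 2978 candidates -> INFEASIBLE
```

Reading: even to reach a modest post-test probability of 10% from a 1%
prevalence, a prediction tool must multiply the outcome odds elevenfold;
detecting a doubling of risk needs more than 6,000 subjects when half the
population carries the factor and nearly 16,000 when only 10% do; and a
dataset with 222 events cannot support screening 2,978 candidate
predictors without severe overfitting risk.

The same quantities are available from Python:

```python
from lowprev import required_lr, rr_from_predictive, required_total_n, DesignSpec

required_lr(0.01, 0.10)                      # 11.0
rr_from_predictive(p=0.01, s=0.8, ppv=0.5)   # 246.0
required_total_n(DesignSpec(r0=0.01, rr=2, f=0.5)).n_total  # 6206
```

Other subcommands: `lowprev scenario` completes a consistent 2×2
marker/outcome distribution from either parameterisation; `lowprev
samplesize` also inverts to achieved power, minimum detectable RR, and the
EPV check; `lowprev curves` writes the sample-size-vs-RR and
RR-vs-sensitivity tables as long-format CSV; `lowprev simulate` runs the
Monte-Carlo power and predictive-metric estimators.

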