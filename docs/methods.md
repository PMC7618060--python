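# Methods

## The 2×2 model

Everything in this package reduces to a joint distribution of two binary
variables: marker (or risk-factor) status and outcome status, with cell
probabilities

|            | outcome + | outcome − |
|------------|-----------|-----------|
| marker +   | a         | b         |
| marker −   | c         | d         |

All familiar quantities are functions of the cells: prevalence
*p = a + c*, marker-positive fraction *f = a + b*, sensitivity
*S = a/(a+c)*, specificity *d/(b+d)*, PPV *a/(a+b)*, NPV *d/(c+d)*,
baseline risk *r₀ = c/(c+d)*, relative risk *RR = PPV/r₀*, and
LR+ = *S/(1 − specificity)*. The table is determined by any three
functionally independent quantities; the package exposes the two
parameterisations that matter in practice:

* **predictive side** (*p*, *S*, PPV) — what a model-evaluation paper
  reports; completing the table gives `f = S·p/PPV`,
  `r₀ = p(1−S)/(1−f)`, and the identity
  `RR = (PPV − p·S)/(p·(1−S))`;
* **exposure side** (*r₀*, RR, *f*) — what an aetiological cohort study
  postulates; then `p = f·r₀·RR + (1−f)·r₀`, `PPV = r₀·RR`,
  `S = f·PPV/p`.

`scenario_from_predictive` and `scenario_from_exposure` each re-derive
every field and the `PredictiveScenario` constructor re-checks all
identities (relative tolerance 1e−9, absolute 1e−12 — generous for
O(1)–O(100) ratios of well-conditioned expressions), rejecting any
inconsistent overspecified input with the name of the violated
constraint. The identity only holds for internally consistent tables, so
strictness here is a correctness feature, not pedantry.

Degenerate boundaries are domain errors rather than infinities:
sensitivity 1 (RR unbounded), specificity 1 (LR+ unbounded),
PPV ≤ p·S (marker-positive fraction above 1). Callers wanting limiting
behaviour pass 1 − ε explicitly; nothing propagates non-finite values.

`required_lr` and `post_test_probability` perform the odds-form Bayes
update in exact rational arithmetic (`fractions.Fraction` on the shortest
decimal representation of the inputs), so hand-entered probabilities
behave as the decimals they look like: the 1% → 10%/25%/50% conversions
return exactly 11, 33 and 99 rather than 11.000000000000002.

## Sample size and power

The sizing question compares exposed risk *p₁ = r₀·RR* with unexposed
risk *p₂ = r₀* at allocation ratio *k = (1−f)/f* unexposed per exposed.
The default (`pooled`) formula is the pooled-variance normal
approximation:

n₁ = [ z₁₋α/₂ √((1+1/k)·p̄(1−p̄)) + z₁₋β √(p₁(1−p₁) + p₂(1−p₂)/k) ]² / (p₁−p₂)²,

with p̄ = f·p₁ + (1−f)·p₂. The exposed group is ceiled first, the
unexposed group is `ceil(k·n₁)`, and the total is their sum —
conservative, reproducible integers. Two variants are selectable and
recorded in every result: `unpooled` (both radicals unpooled) and
`pooled_cc` (Fleiss continuity correction `n₁ + (k+1)/(k·|p₁−p₂|)`,
always at least as large as `pooled`). Significance is interpreted as
two-sided α, the epidemiological default. At r₀ = 1%, RR = 2, α = 0.05,
power 0.90 the pooled variant returns 6,206 (f = 0.5) and 15,990
(f = 0.1).

`achieved_power` inverts the same approximation at a continuous f/(1−f)
split and includes both rejection tails, so power degrades to α (not α/2)
as RR → 1; the far tail is below 1e−10 at design-relevant effect sizes.
It agrees with statsmodels' independent `power_proportions_2indep` to
near machine precision (asserted in the test suite; statsmodels is a
cross-check there, never the implementation).

`min_detectable_rr` bisects on `required_total_n(rr).n_total ≤ n_total`
over (1 + 1e−6, 100] to 1e−6 relative tolerance. Bisecting on the sizing
function rather than on raw `achieved_power` makes the guarantee
"the returned effect is detectable within the stated budget" hold exactly
despite integer rounding of group sizes (rounding both groups up can add
two subjects, which a power-based threshold straddles). The cap of 100 —
and the harder cap RR ≤ 1/r₀ — bound the search to scientifically
meaningful effect sizes; beyond them the function raises
`NotAchievableError`. Note that with a cap this generous, very small
cohorts usually still have *some* detectable (if absurd) effect: 100
subjects at 1% baseline risk can detect RR ≈ 21 under the pooled formula.

The events-per-variable rule is plain arithmetic,
`max_predictors = floor(events / 10)` by default, with a feasibility
verdict when a candidate-predictor count is supplied.

## The Monte-Carlo oracle

`cohort_sim` draws cohorts from exactly the sampling model the design
describes: exposure count binomial(n, f) — or fixed at f·n with
`fixed_margins`, the conditional design — then outcome counts binomial
with risks p₁ and p₂. The rejection test mirrors the approximation the
sizing formula uses: the two-sided pooled-variance z-test, equivalent to
the Pearson chi-square without continuity correction, so the simulation
validates the formula actually implemented. Zero-margin replicates
(no events, or an empty group) cannot reject and are counted as
non-rejections, with a logged warning.

Replicate *i* uses an independent generator spawned from
`SeedSequence(seed)`, making runs bit-for-bit reproducible and
replicate-order independent. Ratio metrics (RR, LR+) pool the 2×2 counts
across replicates before forming the ratio — per-replicate ratios are
undefined or wildly skewed when a 1%-prevalence replicate contains a
handful of events — and carry log-scale delta-method standard errors;
proportion metrics use pooled binomial standard errors.

What the simulator emulates — and what it does not: cohorts are simple
random samples with an exactly binary, perfectly measured exposure and
outcome, independence across subjects, and risks constant within exposure
groups. Real cohorts add confounding, measurement error, clustering,
censoring and model-selection effects, all of which push required sample
sizes *up* and achievable performance *down*; agreement of simulation
with the closed forms here therefore validates the algebra, and the
feasibility verdicts remain optimistic bounds for real studies.

One calibration fact worth knowing: the exact power of the pooled
chi-square test at the returned n (6,206 for the headline design) is
about 0.907, slightly above the 0.90 the normal approximation targets —
discreteness and binomial skewness at ~90 expected events make the
formula mildly conservative. The exact type-I error at n = 5,000 under
the null is 0.049. The simulation tests use 20,000 replicates
(MC SE ≈ 0.002 at the target power), which resolves this comfortably
while keeping the full suite under half a minute.

## Curves

The two curve generators evaluate the single-point operations on grids —
RR from 1.5 to 5.0 in steps of 0.1 for the sizing curve, sensitivity from
0.05 to 0.95 in steps of 0.01 for the effect-size curve, both
overridable — and emit long-format `(x, series, y)` tables with a JSON
metadata sidecar. Grid conventions: sensitivity grids live in the open
interval (0, 1), since both endpoints are domain errors. Invalid grid
points are omitted with a logged warning; the test suite re-checks every
emitted row against a fresh single-point call.

## Report and CLI

`run_report` composes the modules for one parameter set and embeds the
full provenance (all inputs, variant, seed, tool version) so that every
number is recomputable from the report alone; re-running from the
embedded provenance reproduces the JSON byte-for-byte. Section-level
validation failures (e.g. RR = 1 in the sizing section) become structured
error entries naming the violated constraint — nothing is silently
dropped. The CLI accepts probabilities as proportions or percentages
("1%"), prints both scales, reads a flat `key = value` config file with
flags taking precedence, and exits 0/2/1 for success / validation error /
internal error.

## Known limitations

* Only dichotomised markers: no continuous scores, ROC analysis or
  calibration metrics; no negative-likelihood-ratio ("rule-out")
  thresholds.
* Sizing covers a single binary factor; multivariable model-development
  sample size is addressed only through the EPV heuristic.
* The normal-approximation power formulas are asymptotic; below ~5
  expected events per cell they should not be trusted, and the simulator
  is the arbiter there.
* No survival/time-to-event or matched designs.
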