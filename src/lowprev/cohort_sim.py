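"""Monte-Carlo cohorts of binary exposure and binary outcome.

This module is the brute-force counterpart to every closed form in
:mod:`lowprev.risk_algebra` and :mod:`lowprev.sample_size`: cohorts are
drawn from the sampling model the design describes (exposure indicator
with probability f; outcome with risk r0 or r0*rr), and the empirical
power, type-I error, sensitivity, specificity, PPV, RR and LR+ are
estimated by replication.

Randomness: a run is identified by a single integer seed; replicate
``i`` uses an independent substream derived deterministically from
``(seed, i)`` via numpy's SeedSequence spawning, so results are
bit-for-bit reproducible and replicate-order independent.

The rejection test mirrors the approximation behind the default sizing
formula: the two-sided pooled-variance z-test (equivalently the Pearson
chi-square without continuity correction).  Replicates with a zero
margin — no events at all, or an empty exposure group — cannot reject and
are counted as non-rejections (logged).  Ratio estimates (RR, LR+) pool
counts across replicates rather than averaging per-replicate ratios,
which are undefined or wildly skewed at 1% prevalence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .risk_algebra import _check
from .sample_size import DesignSpec

__all__ = [
    "CohortCounts",
    "SimResult",
    "simulate_cohort",
    "empirical_power",
    "empirical_predictive",
]

logger = logging.getLogger("lowprev")


@dataclass(frozen=True)
class CohortCounts:
    """A realised 2x2 table: a = exposed with outcome, b = exposed without,
    c = unexposed with outcome, d = unexposed without."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        _check(min(self.a, self.b, self.c, self.d) >= 0,
               "cell counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SimResult:
    """A Monte-Carlo estimate with its uncertainty.

    ``mc_se`` is the Monte-Carlo standard error of ``estimate`` and
    ``ci95`` the corresponding normal-approximation 95% interval
    (log-scale for ratio metrics).
    """

    estimate: float
    mc_se: float
    ci95: tuple[float, float]
    replicates: int
    seed: int
    design: DesignSpec = field(repr=False)
    n_total: int = 0
    metric: str = "power"


def _rngs(seed: int, replicates: int) -> list[np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(replicates)
    return [np.random.default_rng(c) for c in children]


def _draw_counts(design: DesignSpec, n_total: int,
                 rng: np.random.Generator,
                 fixed_margins: bool = False) -> CohortCounts:
    if fixed_margins:
        n_exp = int(round(design.f * n_total))
    else:
        n_exp = int(rng.binomial(n_total, design.f))
    n_unexp = n_total - n_exp
    a = int(rng.binomial(n_exp, design.p1)) if n_exp else 0
    c = int(rng.binomial(n_unexp, design.p2)) if n_unexp else 0
    return CohortCounts(a=a, b=n_exp - a, c=c, d=n_unexp - c)


def simulate_cohort(design: DesignSpec, n_total: int, seed: int,
                    fixed_margins: bool = False) -> CohortCounts:
    """Draw one cohort: exposure count binomial with probability ``f``
    (or fixed at f*n_total when ``fixed_margins``), then outcome counts
    binomial with risks r0*rr (exposed) and r0 (unexposed).
    Deterministic given ``seed``."""
    _check(n_total >= 1, f"n_total must be >= 1; got {n_total!r}")
    return _draw_counts(design, n_total, np.random.default_rng(seed),
                        fixed_margins)


def _pooled_z_reject(a: int, b: int, c: int, d: int, alpha: float) -> bool:
    """Two-sided pooled-variance z-test (Pearson chi-square, no continuity
    correction).  Zero-margin tables cannot reject."""
    n1, n2 = a + b, c + d
    if n1 == 0 or n2 == 0:
        return False
    pbar = (a + c) / (n1 + n2)
    if pbar <= 0 or pbar >= 1:
        return False
    z = ((a / n1 - c / n2)
         / math.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2)))
    return abs(z) >= norm.ppf(1 - alpha / 2)


def empirical_power(design: DesignSpec, n_total: int, replicates: int,
                    seed: int, fixed_margins: bool = False,
                    raw_records: list | None = None) -> SimResult:
    """Fraction of replicate cohorts in which the two-sided pooled
    chi-square test rejects at level ``design.alpha``.  At ``rr = 1`` this
    estimates the type-I error.

    ``mc_se`` is the binomial standard error of the rejection fraction.
    When ``raw_records`` is a list, one dict per replicate (counts and
    rejection flag) is appended to it.
    """
    _check(replicates >= 100,
           f"replicates must be >= 100; got {replicates!r}")
    rejections = 0
    degenerate = 0
    for i, rng in enumerate(_rngs(seed, replicates)):
        counts = _draw_counts(design, n_total, rng, fixed_margins)
        zero_margin = (counts.a + counts.c == 0 or counts.b + counts.d == 0
                       or counts.a + counts.b == 0
                       or counts.c + counts.d == 0)
        reject = (not zero_margin
                  and _pooled_z_reject(counts.a, counts.b, counts.c,
                                       counts.d, design.alpha))
        if zero_margin:
            degenerate += 1
        if reject:
            rejections += 1
        if raw_records is not None:
            raw_records.append({"replicate": i, "a": counts.a, "b": counts.b,
                                "c": counts.c, "d": counts.d,
                                "reject": int(reject)})
    if degenerate:
        logger.warning("%d of %d replicates had a zero margin and were "
                       "counted as non-rejections", degenerate, replicates)
    est = rejections / replicates
    se = math.sqrt(max(est * (1 - est), 1e-12) / replicates)
    ci = (max(est - 1.96 * se, 0.0), min(est + 1.96 * se, 1.0))
    return SimResult(estimate=est, mc_se=se, ci95=ci, replicates=replicates,
                     seed=seed, design=design, n_total=n_total,
                     metric="power")


def _proportion_result(num: int, den: int, metric: str, replicates: int,
                       seed: int, design: DesignSpec,
                       n_total: int) -> SimResult:
    est = num / den
    se = math.sqrt(max(est * (1 - est), 1e-12) / den)
    ci = (max(est - 1.96 * se, 0.0), min(est + 1.96 * se, 1.0))
    return SimResult(estimate=est, mc_se=se, ci95=ci, replicates=replicates,
                     seed=seed, design=design, n_total=n_total, metric=metric)


def _ratio_result(est: float, se_log: float, metric: str, replicates: int,
                  seed: int, design: DesignSpec, n_total: int) -> SimResult:
    ci = (est * math.exp(-1.96 * se_log), est * math.exp(1.96 * se_log))
    return SimResult(estimate=est, mc_se=est * se_log, ci95=ci,
                     replicates=replicates, seed=seed, design=design,
                     n_total=n_total, metric=metric)


def empirical_predictive(design: DesignSpec, n_total: int, replicates: int,
                         seed: int,
                         fixed_margins: bool = False) -> dict[str, SimResult]:
    """Empirical predictive metrics of the exposure indicator used as a
    marker, pooled over replicates: sensitivity, specificity, PPV, RR and
    LR+.  Each agrees with the closed forms of
    :func:`lowprev.risk_algebra.scenario_from_exposure` to within
    Monte-Carlo error.

    Metrics whose pooled denominator is zero (no events, or no
    marker-positives) are reported as absent from the mapping (logged).
    """
    _check(replicates >= 100,
           f"replicates must be >= 100; got {replicates!r}")
    a = b = c = d = 0
    for rng in _rngs(seed, replicates):
        counts = _draw_counts(design, n_total, rng, fixed_margins)
        a += counts.a
        b += counts.b
        c += counts.c
        d += counts.d
    out: dict[str, SimResult] = {}

    def prop(num: int, den: int, metric: str) -> None:
        if den == 0:
            logger.warning("metric %s undefined: zero denominator", metric)
            return
        out[metric] = _proportion_result(num, den, metric, replicates, seed,
                                         design, n_total)

    prop(a, a + c, "sensitivity")
    prop(d, b + d, "specificity")
    prop(a, a + b, "ppv")
    if min(a, c) > 0 and a + b > 0 and c + d > 0:
        rr = (a / (a + b)) / (c / (c + d))
        se_log = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
        out["rr"] = _ratio_result(rr, se_log, "rr", replicates, seed,
                                  design, n_total)
    else:
        logger.warning("metric rr undefined: empty cell in pooled table")
    if min(a, b) > 0 and a + c > 0 and b + d > 0:
        lr = (a / (a + c)) / (b / (b + d))
        se_log = math.sqrt(1 / a - 1 / (a + c) + 1 / b - 1 / (b + d))
        out["lr_pos"] = _ratio_result(lr, se_log, "lr_pos", replicates, seed,
                                      design, n_total)
    else:
        logger.warning("metric lr_pos undefined: empty cell in pooled table")
    return out
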