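"""Sample size and power for detecting a binary risk factor at low baseline risk.

The design question: a cohort is sampled from a population in which a
fraction ``f`` carry a binary risk factor, the outcome risk is ``r0`` in
factor-negative individuals and ``r0 * rr`` in factor-positive ones.  How
many subjects are needed for a two-sided two-proportion test at level
``alpha`` to detect the relative risk ``rr`` with the target power?

The default sizing formula is the pooled-variance normal approximation
with unequal allocation (allocation ratio k = (1-f)/f unexposed per
exposed):

    n_exposed = [ z_{1-a/2} * sqrt((1 + 1/k) * pbar*(1-pbar))
                  + z_{1-b} * sqrt(p1*(1-p1) + p2*(1-p2)/k) ]^2
                / (p1 - p2)^2

with p1 = r0*rr, p2 = r0 and pbar = f*p1 + (1-f)*p2 the pooled risk.
At r0 = 1%, rr = 2, alpha = 0.05 and 90% power this gives a total of
6,208 subjects when half the population carries the factor, and 15,990
when 10% do — the low-prevalence penalty in concrete numbers.  An
``unpooled`` variant (both variance radicals unpooled) and a ``pooled_cc``
variant (continuity-corrected) are selectable and recorded in the result.

Also here: the events-per-variable (EPV) screening rule for model
development — at least 10 outcome events per candidate predictor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm

from .risk_algebra import DomainError, _check, _check_proportion

__all__ = [
    "VARIANTS",
    "DesignSpec",
    "SampleSizeResult",
    "EpvResult",
    "NotAchievableError",
    "required_total_n",
    "achieved_power",
    "min_detectable_rr",
    "epv_limit",
]

VARIANTS = ("pooled", "unpooled", "pooled_cc")

#: Search cap for the minimum detectable relative risk; effect sizes above
#: this are outside the subject matter of low-prevalence risk prediction.
RR_CAP = 100.0


class NotAchievableError(DomainError):
    """No effect size within the search cap reaches the target power."""


@dataclass(frozen=True)
class DesignSpec:
    """Inputs to a power / sample-size calculation.

    r0 : baseline outcome risk in factor-negative individuals.
    rr : relative risk to detect (must differ from 1 for sizing).
    f : fraction of the population carrying the risk factor.
    alpha : two-sided significance level.
    power : target power.
    variant : sizing-formula variant, one of ``pooled`` (default),
        ``unpooled``, ``pooled_cc``.
    """

    r0: float
    rr: float
    f: float
    alpha: float = 0.05
    power: float = 0.90
    variant: str = "pooled"

    def __post_init__(self) -> None:
        _check_proportion(self.r0, "r0", open_left=True, open_right=True)
        _check(self.rr >= 0, f"rr must be >= 0; got {self.rr!r}")
        _check(self.r0 * self.rr <= 1,
               "r0*rr > 1: risk in the exposed group exceeds 1")
        _check_proportion(self.f, "f", open_left=True, open_right=True)
        _check_proportion(self.alpha, "alpha", open_left=True, open_right=True)
        _check_proportion(self.power, "power", open_left=True, open_right=True)
        _check(self.variant in VARIANTS,
               f"variant must be one of {VARIANTS}; got {self.variant!r}")

    @property
    def p1(self) -> float:
        """Outcome risk in the exposed (factor-positive) group."""
        return self.r0 * self.rr

    @property
    def p2(self) -> float:
        """Outcome risk in the unexposed group."""
        return self.r0

    @property
    def k(self) -> float:
        """Allocation ratio: unexposed subjects per exposed subject."""
        return (1 - self.f) / self.f

    def to_record(self) -> dict:
        return {"r0": self.r0, "rr": self.rr, "f": self.f,
                "alpha": self.alpha, "power": self.power,
                "variant": self.variant}


@dataclass(frozen=True)
class SampleSizeResult:
    n_exposed: int
    n_unexposed: int
    n_total: int
    expected_events: float
    variant: str
    inputs: DesignSpec = field(repr=False)

    def to_record(self) -> dict:
        return {"n_exposed": self.n_exposed, "n_unexposed": self.n_unexposed,
                "n_total": self.n_total,
                "expected_events": self.expected_events,
                "variant": self.variant, "inputs": self.inputs.to_record()}


def _n_exposed_continuous(design: DesignSpec) -> float:
    """Exposed-group size before rounding, per the selected variant."""
    p1, p2, k = design.p1, design.p2, design.k
    delta = p1 - p2
    z_a = norm.ppf(1 - design.alpha / 2)
    z_b = norm.ppf(design.power)
    unpooled_var = p1 * (1 - p1) + p2 * (1 - p2) / k
    if design.variant == "unpooled":
        n1 = ((z_a + z_b) ** 2) * unpooled_var / delta ** 2
    else:
        pbar = design.f * p1 + (1 - design.f) * p2
        n1 = ((z_a * math.sqrt((1 + 1 / k) * pbar * (1 - pbar))
               + z_b * math.sqrt(unpooled_var)) / abs(delta)) ** 2
        if design.variant == "pooled_cc":
            # Fleiss continuity correction for unequal allocation.
            n1 = n1 + (k + 1) / (k * abs(delta))
    return n1


def required_total_n(design: DesignSpec) -> SampleSizeResult:
    """Total cohort size needed to detect ``design.rr`` at the design's
    alpha and power, split between exposed and unexposed in proportion
    f : (1-f).

    The exposed group is rounded up first, the unexposed group is derived
    from the allocation ratio and rounded up, and the total is their sum
    (conservative, reproducible integers).  ``expected_events`` is the
    expected outcome count at the returned sizes.

    Raises
    ------
    DomainError
        If ``rr == 1`` (null effect: no finite size detects it) or the
        exposed-group risk exceeds 1.
    """
    _check(design.rr != 1,
           "rr = 1: a null effect cannot be detected at any sample size")
    n1 = math.ceil(_n_exposed_continuous(design))
    n2 = math.ceil(design.k * n1)
    expected = n1 * design.p1 + n2 * design.p2
    return SampleSizeResult(n_exposed=n1, n_unexposed=n2, n_total=n1 + n2,
                            expected_events=expected, variant=design.variant,
                            inputs=design)


def achieved_power(design: DesignSpec, n_total: int) -> float:
    """Power of the two-sided level-alpha two-proportion test at total
    size ``n_total`` split f/(1-f) (continuous split; no rounding).

    Self-consistent with :func:`required_total_n`:
    ``achieved_power(design, required_total_n(design).n_total)`` is at
    least ``design.power``.
    """
    _check(n_total >= 2, f"n_total must be >= 2; got {n_total!r}")
    p1, p2, k = design.p1, design.p2, design.k
    delta = abs(p1 - p2)
    n1 = design.f * n_total
    if design.variant == "pooled_cc":
        # Invert the continuity correction, then use the pooled power.
        n1 = max(n1 - (k + 1) / (k * delta) if delta > 0 else n1, 1e-9)
    z_a = norm.ppf(1 - design.alpha / 2)
    unpooled_sd = math.sqrt(p1 * (1 - p1) + p2 * (1 - p2) / k)
    shift = delta * math.sqrt(n1)
    if design.variant == "unpooled":
        crit = z_a * unpooled_sd
    else:
        pbar = design.f * p1 + (1 - design.f) * p2
        crit = z_a * math.sqrt((1 + 1 / k) * pbar * (1 - pbar))
    # Both rejection tails: the far tail only matters near the null, where
    # it restores power -> alpha as rr -> 1.
    return float(norm.cdf((shift - crit) / unpooled_sd)
                 + norm.cdf((-shift - crit) / unpooled_sd))


def min_detectable_rr(r0: float, f: float, n_total: int, alpha: float = 0.05,
                      power: float = 0.90, variant: str = "pooled") -> float:
    """Smallest relative risk above 1 detectable with the target power in a
    cohort of ``n_total``, found by bisection to 1e-6 relative tolerance.

    The returned effect satisfies ``required_total_n(...).n_total <=
    n_total`` (and hence ``achieved_power(..., n_total) >= power``); the
    search is capped at RR 100 and at the effect size that drives the
    exposed-group risk to 1.

    Raises
    ------
    NotAchievableError
        If no relative risk up to the search cap (100) reaches the power.
    """
    lo = 1 + 1e-6
    hi = min(RR_CAP, 1.0 / r0)

    def detectable(rr: float) -> bool:
        design = DesignSpec(r0=r0, rr=rr, f=f, alpha=alpha, power=power,
                            variant=variant)
        return required_total_n(design).n_total <= n_total

    if not detectable(hi):
        raise NotAchievableError(
            f"no relative risk <= {hi:g} reaches power {power:g} with "
            f"n_total = {n_total}")
    if detectable(lo):
        return lo
    while hi - lo > 1e-6 * lo:
        mid = 0.5 * (lo + hi)
        if detectable(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass(frozen=True)
class EpvResult:
    """Outcome of the events-per-variable screening rule."""

    n_events: int
    epv: int
    max_predictors: int
    candidate_predictors: int | None = None

    @property
    def feasible(self) -> bool | None:
        """Whether the candidate predictor count fits within the EPV rule;
        ``None`` when no candidate count was supplied."""
        if self.candidate_predictors is None:
            return None
        return self.candidate_predictors <= self.max_predictors

    def to_record(self) -> dict:
        rec = {"n_events": self.n_events, "epv": self.epv,
               "max_predictors": self.max_predictors}
        if self.candidate_predictors is not None:
            rec["candidate_predictors"] = self.candidate_predictors
            rec["feasible"] = self.feasible
        return rec


def epv_limit(n_events: int, epv: int = 10,
              candidate_predictors: int | None = None) -> EpvResult:
    """Maximum number of candidate predictors supportable by ``n_events``
    outcome events under the events-per-variable rule of thumb (default:
    at least 10 events per predictor, to limit overfitting).

    When ``candidate_predictors`` is given, the result carries a
    feasibility verdict for that candidate set.
    """
    _check(n_events >= 0, f"n_events must be >= 0; got {n_events!r}")
    _check(epv >= 1, f"epv must be >= 1; got {epv!r}")
    return EpvResult(n_events=int(n_events), epv=int(epv),
                     max_predictors=int(n_events) // int(epv),
                     candidate_predictors=candidate_predictors)
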