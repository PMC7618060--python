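"""Closed-form algebra for a binary marker predicting a binary outcome.

A dichotomised prediction rule applied to a population with outcome
prevalence ``p`` induces a 2x2 joint distribution of marker status and
outcome status.  That distribution is fully determined by three numbers —
for instance prevalence, sensitivity and positive predictive value — and
every other familiar quantity (specificity, NPV, the marker-positive
fraction ``f``, the relative risk comparing marker-positive with
marker-negative individuals, and the positive likelihood ratio) follows by
algebra on the four cell probabilities.

The central identity, which makes the cost of low prevalence explicit, is

    RR = (PPV - p*S) / (p * (1 - S))

so that as sensitivity shrinks the relative risk needed to sustain a given
PPV approaches the floor PPV / p: at 1% prevalence a rule with 50% PPV
requires a relative risk of at least 50 no matter how the marker is built.

All probabilities in this module are proportions in [0, 1].  Constructors
re-derive every derived field from the minimal parameterisation and raise
:class:`DomainError` naming the violated constraint for any inconsistent or
degenerate input; callers wanting limiting behaviour (sensitivity or
specificity of exactly 1) must pass 1 - eps explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from numbers import Real

__all__ = [
    "DomainError",
    "PredictiveScenario",
    "rr_from_predictive",
    "ppv_from_rr",
    "scenario_from_predictive",
    "scenario_from_exposure",
    "lr_positive",
    "required_lr",
    "post_test_probability",
]

#: Relative tolerance for internal consistency checks.  All quantities here
#: are O(1)-O(100) ratios of well-conditioned expressions.
REL_TOL = 1e-9
#: Absolute tolerance floor for consistency checks near zero.
ABS_TOL = 1e-12


class DomainError(ValueError):
    """An input lies outside the domain where the requested quantity exists,
    or an overspecified scenario is internally inconsistent.  The message
    names the violated constraint."""


def _check(cond: bool, constraint: str) -> None:
    if not cond:
        raise DomainError(constraint)


def _check_proportion(value: float, name: str, *, open_left: bool = False,
                      open_right: bool = False) -> None:
    lo_ok = value > 0 if open_left else value >= 0
    hi_ok = value < 1 if open_right else value <= 1
    lo = "(" if open_left else "["
    hi = ")" if open_right else "]"
    _check(lo_ok and hi_ok, f"{name} must be in {lo}0, 1{hi}; got {value!r}")


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= max(REL_TOL * max(abs(a), abs(b)), ABS_TOL)


# ---------------------------------------------------------------------------
# Scenario container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictiveScenario:
    """A fully consistent joint distribution of binary marker x binary outcome.

    Fields
    ------
    p : outcome prevalence.
    sensitivity : P(marker+ | outcome).
    specificity : P(marker- | no outcome).
    ppv : P(outcome | marker+) — the post-test probability after a positive.
    npv : P(no outcome | marker-).
    f : marker-positive fraction of the population.
    rr : relative risk of the outcome, marker-positive vs marker-negative.
    lr_pos : positive likelihood ratio, sensitivity / (1 - specificity).

    Use :func:`scenario_from_predictive` or :func:`scenario_from_exposure`
    to construct one; the constructor itself verifies all consistency
    identities and rejects anything inconsistent.
    """

    p: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f: float
    rr: float
    lr_pos: float

    def __post_init__(self) -> None:
        _check_proportion(self.p, "p", open_left=True, open_right=True)
        _check_proportion(self.sensitivity, "sensitivity")
        _check_proportion(self.specificity, "specificity")
        _check_proportion(self.ppv, "ppv")
        _check_proportion(self.npv, "npv")
        _check_proportion(self.f, "f", open_left=True, open_right=True)
        _check(self.rr >= 0, f"rr must be >= 0; got {self.rr!r}")
        _check(self.lr_pos >= 0, f"lr_pos must be >= 0; got {self.lr_pos!r}")
        _check(_close(self.f, self.sensitivity * self.p / self.ppv)
               if self.ppv > 0 else self.sensitivity * self.p == 0,
               "f = sensitivity * p / ppv")
        _check(_close(self.p,
                      self.f * self.ppv + (1 - self.f) * (1 - self.npv)),
               "p = f*ppv + (1-f)*(1-npv)")
        _check(_close(self.specificity,
                      1 - self.f * (1 - self.ppv) / (1 - self.p)),
               "specificity = 1 - f*(1-ppv)/(1-p)")
        _check(self.specificity < 1,
               "specificity = 1 gives an unbounded positive likelihood ratio")
        _check(_close(self.lr_pos, self.sensitivity / (1 - self.specificity)),
               "lr_pos = sensitivity/(1-specificity)")
        _check(_close(self.ppv / (1 - self.ppv) if self.ppv < 1 else
                      float("inf"),
                      self.lr_pos * self.p / (1 - self.p)),
               "ppv odds = lr_pos * prevalence odds")
        _check(_close(self.rr * self.r0, self.ppv),
               "rr = ppv / r0 with r0 = p*(1-sensitivity)/(1-f)")

    @property
    def r0(self) -> float:
        """Baseline risk: outcome probability among marker-negative
        individuals, p*(1 - sensitivity)/(1 - f)."""
        return self.p * (1 - self.sensitivity) / (1 - self.f)

    def joint_probabilities(self) -> dict[str, float]:
        """The four cell probabilities of the marker x outcome table.

        Keys: ``a`` marker+/outcome+, ``b`` marker+/outcome-,
        ``c`` marker-/outcome+, ``d`` marker-/outcome-.
        """
        a = self.f * self.ppv
        b = self.f * (1 - self.ppv)
        c = self.p - a
        d = 1 - a - b - c
        return {"a": a, "b": b, "c": c, "d": d}

    def to_record(self) -> dict[str, float]:
        """Flat key-value record (for JSON or single-row CSV output)."""
        return {
            "p": self.p,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f": self.f,
            "rr": self.rr,
            "lr_pos": self.lr_pos,
        }


# ---------------------------------------------------------------------------
# The RR-PPV-sensitivity-prevalence identity and its inverse
# ---------------------------------------------------------------------------

def rr_from_predictive(p: float, s: float, ppv: float) -> float:
    """Relative risk implied by prevalence ``p``, sensitivity ``s`` and
    positive predictive value ``ppv``:  RR = (ppv - p*s) / (p*(1 - s)).

    Strictly increasing in ``s`` when ``ppv > p``; as ``s`` tends to 0 the
    value tends to ``ppv / p``, the floor on the effect size any marker
    must carry to reach that PPV at that prevalence.

    Raises
    ------
    DomainError
        If ``s == 1`` (marker captures every event; RR unbounded) or
        ``ppv <= p*s`` (the marker-positive fraction would exceed 1).
    """
    _check_proportion(p, "p", open_left=True, open_right=True)
    _check_proportion(s, "sensitivity")
    _check(s < 1, "sensitivity = 1 makes the relative risk unbounded")
    _check_proportion(ppv, "ppv")
    _check(ppv > p * s,
           "ppv <= p*sensitivity: marker-positive fraction would exceed 1")
    return (ppv - p * s) / (p * (1 - s))


def ppv_from_rr(p: float, s: float, rr: float) -> float:
    """Positive predictive value implied by prevalence, sensitivity and
    relative risk: the exact inverse of :func:`rr_from_predictive`,
    ppv = rr*p*(1 - s) + p*s.

    Raises
    ------
    DomainError
        If the computed PPV exceeds 1 (no consistent scenario exists at
        this prevalence and effect size).
    """
    _check_proportion(p, "p", open_left=True, open_right=True)
    _check_proportion(s, "sensitivity")
    _check(rr >= 0, f"rr must be >= 0; got {rr!r}")
    ppv = rr * p * (1 - s) + p * s
    _check(ppv <= 1, "computed ppv > 1: scenario impossible at this "
                     "prevalence and effect size")
    return ppv


def scenario_from_predictive(p: float, s: float, ppv: float) -> PredictiveScenario:
    """Complete the 2x2 joint distribution from (prevalence, sensitivity,
    PPV): derives f, baseline risk, specificity, NPV, LR+ and RR.

    Requires ``f = s*p/ppv < 1`` in addition to the preconditions of
    :func:`rr_from_predictive`.
    """
    rr = rr_from_predictive(p, s, ppv)  # validates p, s, ppv
    _check(ppv > 0, "ppv must be > 0 to determine the marker-positive "
                    "fraction")
    f = s * p / ppv
    # ppv > p*s guarantees f < 1 already; keep the named check explicit.
    _check(f < 1, "f = sensitivity*p/ppv must be < 1")
    _check(f > 0, "f = sensitivity*p/ppv must be > 0 for a non-degenerate "
                  "scenario (sensitivity = 0 leaves no marker-positives)")
    spec = 1 - f * (1 - ppv) / (1 - p)
    _check(spec >= 0, "specificity < 0: marker-positive non-events exceed "
                      "all non-events")
    r0 = p * (1 - s) / (1 - f)
    npv = 1 - r0
    lr_pos = lr_positive(s, spec)
    return PredictiveScenario(p=p, sensitivity=s, specificity=spec, ppv=ppv,
                              npv=npv, f=f, rr=rr, lr_pos=lr_pos)


def scenario_from_exposure(r0: float, rr: float, f: float) -> PredictiveScenario:
    """Complete the 2x2 joint distribution from the exposure-side
    parameterisation: baseline risk ``r0`` among factor-negatives, relative
    risk ``rr``, and the fraction ``f`` of the population carrying the
    factor.  Then p = f*r0*rr + (1-f)*r0, the PPV is the risk in the
    exposed group r0*rr, and sensitivity is f*ppv/p.

    This is the executable form of the derivation behind
    :func:`rr_from_predictive`: feeding the resulting (p, s, ppv) back
    through it recovers ``rr``.
    """
    _check_proportion(r0, "r0", open_left=True, open_right=True)
    _check(rr >= 0, f"rr must be >= 0; got {rr!r}")
    _check_proportion(f, "f", open_left=True, open_right=True)
    ppv = r0 * rr
    _check(ppv <= 1, "r0*rr > 1: risk in the exposed group exceeds 1")
    p = f * ppv + (1 - f) * r0
    s = f * ppv / p
    _check(s < 1, "sensitivity = 1: all events occur in the exposed group")
    spec = 1 - f * (1 - ppv) / (1 - p)
    _check(spec >= 0, "specificity < 0")
    npv = 1 - r0
    lr_pos = lr_positive(s, spec)
    return PredictiveScenario(p=p, sensitivity=s, specificity=spec, ppv=ppv,
                              npv=npv, f=f, rr=rr, lr_pos=lr_pos)


# ---------------------------------------------------------------------------
# Likelihood ratios and post-test probability
# ---------------------------------------------------------------------------

def lr_positive(s: float, spec: float) -> float:
    """Positive likelihood ratio, sensitivity / (1 - specificity): the
    factor by which a positive result multiplies the pre-test odds."""
    _check_proportion(s, "sensitivity")
    _check_proportion(spec, "specificity", open_right=True)
    return s / (1 - spec)


def _as_fraction(x: Real) -> Fraction:
    # str() of a float is its shortest decimal repr, so Fraction(str(x))
    # treats 0.01 as exactly 1/100 — the reading intended for hand-entered
    # probabilities — rather than as its binary neighbour.
    if isinstance(x, Fraction):
        return x
    if isinstance(x, int):
        return Fraction(x)
    return Fraction(str(x))


def required_lr(pre_p: float, post_p: float) -> float:
    """The positive likelihood ratio a prediction tool must achieve to move
    a pre-test probability to a target post-test probability:
    [post/(1-post)] / [pre/(1-pre)].

    Computed in exact rational arithmetic on the decimal reading of the
    inputs, so e.g. moving 1% to 10%, 25% or 50% yields exactly 11, 33
    and 99.
    """
    for name, v in (("pre_p", pre_p), ("post_p", post_p)):
        _check_proportion(float(v), name, open_left=True, open_right=True)
    pre = _as_fraction(pre_p)
    post = _as_fraction(post_p)
    return float((post / (1 - post)) / (pre / (1 - pre)))


def post_test_probability(pre_p: float, lr: float) -> float:
    """Odds-form Bayes update: the probability reached from ``pre_p`` after
    applying likelihood ratio ``lr``.  Exact inverse of
    :func:`required_lr` for decimal inputs."""
    _check_proportion(float(pre_p), "pre_p", open_left=True, open_right=True)
    _check(lr >= 0, f"lr must be >= 0; got {lr!r}")
    odds = _as_fraction(pre_p) / (1 - _as_fraction(pre_p)) * _as_fraction(lr)
    return float(odds / (1 + odds))
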