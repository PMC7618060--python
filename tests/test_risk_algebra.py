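"""Unit and property tests for the 2x2 predictive algebra.

The independent oracle throughout is the explicit four-cell joint
probability table: every closed form must match quantities read directly
off the cells."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lowprev import (DomainError, lr_positive, post_test_probability,
                     ppv_from_rr, required_lr, rr_from_predictive,
                     scenario_from_exposure, scenario_from_predictive)

REL = 1e-12


def table_from_predictive(p, s, ppv):
    """Oracle: cell probabilities (a, b, c, d) of the marker x outcome
    table implied by prevalence, sensitivity and PPV, by definition of
    each quantity (no use of the identity under test)."""
    a = p * s                # marker+ and outcome+
    f = a / ppv              # P(marker+) so that a / f = ppv
    b = f - a                # marker+ and outcome-
    c = p - a                # marker- and outcome+
    d = 1 - a - b - c
    return a, b, c, d


def metrics_from_table(a, b, c, d):
    """Oracle: read every metric directly off the cells."""
    p = a + c
    return {
        "p": p,
        "sensitivity": a / (a + c),
        "specificity": d / (b + d),
        "ppv": a / (a + b),
        "npv": d / (c + d),
        "f": a + b,
        "rr": (a / (a + b)) / (c / (c + d)),
        "lr_pos": (a / (a + c)) / (b / (b + d)),
    }


class TestRRFromPredictive:
    @pytest.mark.parametrize("p, s, ppv, expected", [
        (0.01, 0.0, 0.50, 50.0),    # sensitivity->0 floor: PPV/p
        (0.01, 0.5, 0.01, 1.0),     # PPV equal to prevalence: null marker
        (0.01, 0.8, 0.50, 246.0),   # via the 2x2 oracle below
        (0.01, 0.8, 0.10, 46.0),
        (0.01, 0.5, 0.10, 19.0),
    ])
    def test_known_values(self, p, s, ppv, expected):
        assert rr_from_predictive(p, s, ppv) == pytest.approx(expected,
                                                              rel=REL)

    @pytest.mark.parametrize("p, s, ppv", [
        (0.01, 0.3, 0.10), (0.01, 0.8, 0.50), (0.05, 0.6, 0.25),
        (0.001, 0.9, 0.02), (0.2, 0.4, 0.35),
    ])
    def test_matches_2x2_enumeration(self, p, s, ppv):
        """P(outcome|marker+)/P(outcome|marker-) computed directly from
        the joint table equals the closed form."""
        cells = table_from_predictive(p, s, ppv)
        direct = metrics_from_table(*cells)["rr"]
        assert rr_from_predictive(p, s, ppv) == pytest.approx(direct,
                                                              rel=REL)

    def test_sensitivity_one_rejected(self):
        with pytest.raises(DomainError, match="sensitivity"):
            rr_from_predictive(0.01, 1.0, 0.5)

    def test_inconsistent_ppv_rejected(self):
        # ppv <= p*s would need a marker-positive fraction above 1
        with pytest.raises(DomainError, match="marker-positive fraction"):
            rr_from_predictive(0.01, 0.9, 0.009)

    def test_monotone_in_sensitivity_and_prevalence(self):
        grid = [i / 100 for i in range(1, 100)]
        values = [rr_from_predictive(0.01, s, 0.5) for s in grid]
        assert all(lo < hi for lo, hi in zip(values, values[1:]))
        pvals = [0.001, 0.002, 0.005, 0.01, 0.02, 0.05]
        by_p = [rr_from_predictive(p, 0.5, 0.5) for p in pvals]
        assert all(lo > hi for lo, hi in zip(by_p, by_p[1:]))

    def test_floor_at_one_percent_prevalence(self):
        """At p = 1%, PPV 50% requires RR > 50 for every sensitivity; the
        floor 50 is approached as sensitivity -> 0."""
        grid = [i / 100 for i in range(1, 100)]
        assert all(rr_from_predictive(0.01, s, 0.5) > 50 for s in grid)
        assert rr_from_predictive(0.01, 1e-9, 0.5) == pytest.approx(50,
                                                                    rel=1e-6)


class TestPpvFromRR:
    @pytest.mark.parametrize("p, s, rr, expected", [
        (0.01, 0.0, 50.0, 0.50),
        (0.01, 0.3, 1.0, 0.01),   # null effect returns prevalence
        (0.2, 0.7, 1.0, 0.2),
        (0.01, 0.8, 246.0, 0.50),
    ])
    def test_known_values(self, p, s, rr, expected):
        assert ppv_from_rr(p, s, rr) == pytest.approx(expected, rel=REL)

    def test_impossible_scenario_rejected(self):
        with pytest.raises(DomainError, match="ppv > 1"):
            ppv_from_rr(0.1, 0.1, 50.0)

    @given(p=st.floats(1e-4, 0.5), s=st.floats(0.0, 0.99),
           rr=st.floats(0.1, 100.0))
    @settings(max_examples=300, deadline=None)
    def test_round_trip_with_rr_from_predictive(self, p, s, rr):
        try:
            ppv = ppv_from_rr(p, s, rr)
        except DomainError:
            return  # scenario impossible at this prevalence/effect size
        if ppv <= p * s or ppv > 1:
            return
        assert rr_from_predictive(p, s, ppv) == pytest.approx(rr, rel=1e-9)


class TestScenarioConstructors:
    def test_from_predictive_completes_table(self):
        sc = scenario_from_predictive(0.01, 0.8, 0.10)
        assert sc.f == pytest.approx(0.08, rel=REL)
        assert sc.rr == pytest.approx(46.0, rel=REL)
        expected = metrics_from_table(*table_from_predictive(0.01, 0.8, 0.10))
        for key, value in expected.items():
            assert getattr(sc, key if key != "p" else "p") == pytest.approx(
                value, rel=1e-9), key

    def test_coin_flip_marker(self):
        sc = scenario_from_predictive(0.5, 0.5, 0.5)
        assert sc.f == pytest.approx(0.5)
        assert sc.rr == pytest.approx(1.0)
        assert sc.specificity == pytest.approx(0.5)

    def test_impossible_predictive_rejected(self):
        with pytest.raises(DomainError):
            scenario_from_predictive(0.01, 0.9, 0.009)

    def test_from_exposure_known_values(self):
        sc = scenario_from_exposure(0.01, 2.0, 0.5)
        assert sc.p == pytest.approx(0.015, rel=REL)
        assert sc.ppv == pytest.approx(0.02, rel=REL)
        assert sc.sensitivity == pytest.approx(2 / 3, rel=REL)
        # round trip through the identity recovers the relative risk
        assert rr_from_predictive(sc.p, sc.sensitivity,
                                  sc.ppv) == pytest.approx(2.0, rel=REL)

    def test_from_exposure_null_effect(self):
        sc = scenario_from_exposure(0.01, 1.0, 0.3)
        assert sc.p == pytest.approx(0.01, rel=REL)
        assert sc.sensitivity == pytest.approx(0.3, rel=REL)
        assert sc.rr == pytest.approx(1.0, rel=REL)

    def test_from_exposure_risk_above_one_rejected(self):
        with pytest.raises(DomainError, match="exceeds 1"):
            scenario_from_exposure(0.6, 2.0, 0.5)

    @given(r0=st.floats(1e-4, 0.3), rr=st.floats(0.1, 50.0),
           f=st.floats(0.01, 0.99))
    @settings(max_examples=300, deadline=None)
    def test_exposure_round_trip_recovers_rr(self, r0, rr, f):
        """Executable form of the identity's derivation: completing the
        table from (r0, rr, f) and reading it back through the closed form
        recovers rr."""
        if r0 * rr > 1:
            return
        try:
            sc = scenario_from_exposure(r0, rr, f)
        except DomainError:
            return
        assert rr_from_predictive(sc.p, sc.sensitivity,
                                  sc.ppv) == pytest.approx(rr, rel=1e-9)
        # and the scenario matches the 2x2 oracle cell-by-cell
        expected = metrics_from_table(**dict(zip("abcd", [
            f * r0 * rr, f * (1 - r0 * rr), (1 - f) * r0,
            (1 - f) * (1 - r0)])))
        for key, value in expected.items():
            assert getattr(sc, key) == pytest.approx(value, rel=1e-9), key

    @given(r0=st.floats(1e-4, 0.3), rr=st.floats(0.1, 50.0),
           f=st.floats(0.01, 0.99))
    @settings(max_examples=300, deadline=None)
    def test_bayes_consistency(self, r0, rr, f):
        """Updating the prevalence by the marker's LR+ lands exactly on
        the PPV."""
        if r0 * rr > 1:
            return
        try:
            sc = scenario_from_exposure(r0, rr, f)
        except DomainError:
            return
        post = post_test_probability(sc.p, lr_positive(sc.sensitivity,
                                                       sc.specificity))
        assert post == pytest.approx(sc.ppv, rel=1e-9)


class TestLikelihoodRatios:
    @pytest.mark.parametrize("s, spec, expected", [
        (0.5, 0.5, 1.0), (0.8, 0.9, 8.0), (0.0, 0.5, 0.0),
    ])
    def test_lr_positive(self, s, spec, expected):
        assert lr_positive(s, spec) == pytest.approx(expected, rel=REL)

    def test_perfect_specificity_rejected(self):
        with pytest.raises(DomainError):
            lr_positive(0.8, 1.0)

    @pytest.mark.parametrize("pre, post, expected", [
        (0.01, 0.10, 11.0), (0.01, 0.25, 33.0), (0.01, 0.50, 99.0),
        (0.3, 0.3, 1.0),
    ])
    def test_required_lr_exact(self, pre, post, expected):
        # exact rational arithmetic: equality, not approx
        assert required_lr(pre, post) == expected

    @pytest.mark.parametrize("pre, lr, expected", [
        (0.01, 11.0, 0.10), (0.01, 99.0, 0.50), (0.37, 1.0, 0.37),
    ])
    def test_post_test_probability_exact(self, pre, lr, expected):
        assert post_test_probability(pre, lr) == expected

    def test_boundary_probabilities_rejected(self):
        for bad in (0.0, 1.0):
            with pytest.raises(DomainError):
                required_lr(bad, 0.5)
            with pytest.raises(DomainError):
                required_lr(0.5, bad)
            with pytest.raises(DomainError):
                post_test_probability(bad, 2.0)

    @given(pre=st.floats(1e-4, 0.999), post=st.floats(1e-4, 0.999))
    @settings(max_examples=300, deadline=None)
    def test_lr_round_trip(self, pre, post):
        lr = required_lr(pre, post)
        assert post_test_probability(pre, lr) == pytest.approx(post,
                                                               rel=1e-12)


class TestScenarioValidation:
    def test_inconsistent_overspecification_rejected(self):
        """Hand-built scenarios with one perturbed field are refused, and
        the error names a violated constraint."""
        from lowprev import PredictiveScenario
        sc = scenario_from_predictive(0.01, 0.8, 0.10)
        good = sc.to_record()
        for key in ("ppv", "f", "specificity", "rr", "lr_pos", "npv"):
            bad = dict(good)
            bad[key] = min(bad[key] * 1.05 + 0.001, 0.999) \
                if key != "rr" else bad[key] * 1.05
            with pytest.raises(DomainError):
                PredictiveScenario(**bad)

    def test_record_round_trip(self):
        from lowprev import PredictiveScenario
        sc = scenario_from_exposure(0.02, 3.0, 0.25)
        again = PredictiveScenario(**sc.to_record())
        assert again == sc

    def test_joint_probabilities_sum_to_one(self):
        sc = scenario_from_predictive(0.01, 0.8, 0.10)
        cells = sc.joint_probabilities()
        assert sum(cells.values()) == pytest.approx(1.0, rel=1e-12)
        assert cells["a"] + cells["c"] == pytest.approx(sc.p, rel=1e-12)
        assert cells["a"] + cells["b"] == pytest.approx(sc.f, rel=1e-12)
        assert math.isclose(cells["a"] / (cells["a"] + cells["b"]), sc.ppv,
                            rel_tol=1e-12)
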