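"""Combined feasibility report for a low-prevalence risk-prediction study.

:func:`run_report` chains the whole argument for one set of design
parameters: what likelihood ratio the tool must achieve to reach each
post-test target from the population prevalence; what relative risk (and
full 2x2 scenario) a marker with given sensitivity and PPV implies; how
large a cohort is needed to detect the postulated risk factor; whether the
planned predictor count survives the events-per-variable rule; and,
optionally, Monte-Carlo confirmation of the sizing formula.

The report is deterministic given its configuration (including the seed
when simulation is enabled) and embeds the full provenance block, so every
number in it can be recomputed from the report alone.  Requested
computations that fail validation are never silently dropped: they appear
as structured ``{"error": ...}`` entries naming the violated constraint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Mapping

from . import __version__
from .cohort_sim import empirical_power
from .risk_algebra import (DomainError, required_lr, scenario_from_exposure,
                           scenario_from_predictive)
from .sample_size import DesignSpec, epv_limit, required_total_n

__all__ = ["FeasibilityReport", "run_report", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict[str, Any] = {
    "p": 0.01,
    "post_test_targets": (0.10, 0.25, 0.50),
    "sensitivity": None,    # with ppv: complete a predictive scenario
    "ppv": None,
    "r0": 0.01,
    "rr": 2.0,
    "f": (0.5, 0.1),        # one sizing result per exposure fraction
    "alpha": 0.05,
    "power": 0.90,
    "variant": "pooled",
    "events": None,         # with predictors: EPV feasibility verdict
    "predictors": None,
    "epv": 10,
    "simulate": False,
    "replicates": 2000,
    "seed": 0,
}


def _fmt_prob(x: float) -> str:
    """Dual-scale probability formatting: proportion and percent."""
    if x < 0.1:
        return f"{x:.3g} ({100 * x:.3g}%)"
    return f"{x:.4g} ({100 * x:.4g}%)"


@dataclass(frozen=True)
class FeasibilityReport:
    scenario: dict
    sizing: dict
    simulation: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        out = {"provenance": self.provenance, "scenario": self.scenario,
               "sizing": self.sizing}
        if self.simulation is not None:
            out["simulation"] = self.simulation
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"

    def to_text(self) -> str:
        lines = ["Feasibility report", "=================="]
        prov = self.provenance
        lines.append(f"tool version: {prov['version']}")
        lines.append("")
        lines.append(f"Outcome prevalence: {_fmt_prob(prov['p'])}")
        lines.append("")
        lines.append("Likelihood ratio required to reach each post-test "
                     "probability:")
        for entry in self.scenario["required_lr"]:
            lines.append(f"  {_fmt_prob(prov['p'])} -> "
                         f"{_fmt_prob(entry['post_test'])}: "
                         f"LR+ = {entry['lr']:g}")
        comp = self.scenario.get("completed")
        if comp is not None:
            if "error" in comp:
                lines.append(f"Scenario completion failed: {comp['error']}")
            else:
                lines.append("")
                lines.append("Implied 2x2 scenario for the supplied marker "
                             f"(sensitivity {_fmt_prob(comp['sensitivity'])},"
                             f" PPV {_fmt_prob(comp['ppv'])}):")
                lines.append(f"  relative risk: {comp['rr']:g}   "
                             f"LR+: {comp['lr_pos']:g}   "
                             f"specificity: {_fmt_prob(comp['specificity'])} "
                             f"  marker-positive fraction: "
                             f"{_fmt_prob(comp['f'])}")
        lines.append("")
        lines.append(f"Sample size to detect RR = {prov['rr']:g} at baseline "
                     f"risk {_fmt_prob(prov['r0'])} "
                     f"(alpha {prov['alpha']:g} two-sided, power "
                     f"{prov['power']:g}, {prov['variant']} variant):")
        for entry in self.sizing["designs"]:
            if "error" in entry:
                lines.append(f"  f = {entry['f']:g}: not computable -- "
                             f"{entry['error']}")
            else:
                lines.append(f"  f = {entry['f']:g}: total n = "
                             f"{entry['n_total']:,} "
                             f"({entry['n_exposed']:,} exposed / "
                             f"{entry['n_unexposed']:,} unexposed; "
                             f"~{entry['expected_events']:.1f} expected "
                             "events)")
        epv = self.sizing.get("epv")
        if epv is not None:
            lines.append("")
            lines.append(f"Events-per-variable rule ({epv['epv']} events per "
                         f"predictor): {epv['n_events']} events support at "
                         f"most {epv['max_predictors']} predictors"
                         + (f"; {epv['candidate_predictors']} candidates -> "
                            + ("feasible" if epv["feasible"]
                               else "INFEASIBLE")
                            if "candidate_predictors" in epv else ""))
        if self.simulation is not None:
            lines.append("")
            lines.append("Monte-Carlo confirmation of the sizing formula "
                         f"({self.simulation['replicates']} replicates, "
                         f"seed {self.simulation['seed']}):")
            for entry in self.simulation["power"]:
                if "error" in entry:
                    lines.append(f"  f = {entry['f']:g}: {entry['error']}")
                else:
                    lines.append(f"  f = {entry['f']:g}, n = "
                                 f"{entry['n_total']:,}: empirical power "
                                 f"{entry['estimate']:.3f} "
                                 f"(MC SE {entry['mc_se']:.4f})")
        return "\n".join(lines) + "\n"


def run_report(config: Mapping[str, Any] | None = None) -> FeasibilityReport:
    """Build a :class:`FeasibilityReport` from a flat configuration mapping
    (missing keys take :data:`DEFAULT_CONFIG` values)."""
    cfg = dict(DEFAULT_CONFIG)
    if config:
        unknown = set(config) - set(DEFAULT_CONFIG)
        if unknown:
            raise DomainError(
                f"unknown configuration keys: {sorted(unknown)}")
        cfg.update(config)

    f_values = cfg["f"]
    if isinstance(f_values, (int, float)):
        f_values = (float(f_values),)
    f_values = tuple(float(v) for v in f_values)
    targets = tuple(float(t) for t in cfg["post_test_targets"])

    provenance = {k: (list(v) if isinstance(v, tuple) else v)
                  for k, v in cfg.items()}
    provenance["f"] = list(f_values)
    provenance["post_test_targets"] = list(targets)
    provenance["version"] = __version__

    # -- scenario section ---------------------------------------------------
    scenario: dict[str, Any] = {"required_lr": []}
    for post in targets:
        scenario["required_lr"].append(
            {"post_test": post, "lr": required_lr(cfg["p"], post)})
    if cfg["sensitivity"] is not None and cfg["ppv"] is not None:
        try:
            sc = scenario_from_predictive(cfg["p"], cfg["sensitivity"],
                                          cfg["ppv"])
            scenario["completed"] = sc.to_record()
        except DomainError as exc:
            scenario["completed"] = {"error": str(exc)}
    else:
        scenario["completed"] = None

    # -- sizing section -----------------------------------------------------
    sizing: dict[str, Any] = {"designs": []}
    for f in f_values:
        entry: dict[str, Any] = {"f": f}
        try:
            design = DesignSpec(r0=cfg["r0"], rr=cfg["rr"], f=f,
                                alpha=cfg["alpha"], power=cfg["power"],
                                variant=cfg["variant"])
            res = required_total_n(design)
            entry.update(n_exposed=res.n_exposed,
                         n_unexposed=res.n_unexposed, n_total=res.n_total,
                         expected_events=res.expected_events)
        except DomainError as exc:
            entry["error"] = str(exc)
        sizing["designs"].append(entry)
    if cfg["events"] is not None:
        sizing["epv"] = epv_limit(int(cfg["events"]), int(cfg["epv"]),
                                  cfg["predictors"]).to_record()
    else:
        sizing["epv"] = None

    # -- simulation section -------------------------------------------------
    simulation = None
    if cfg["simulate"]:
        simulation = {"replicates": int(cfg["replicates"]),
                      "seed": int(cfg["seed"]), "power": []}
        for entry in sizing["designs"]:
            sim_entry: dict[str, Any] = {"f": entry["f"]}
            if "error" in entry:
                sim_entry["error"] = ("sizing not computable: "
                                      + entry["error"])
            else:
                design = DesignSpec(r0=cfg["r0"], rr=cfg["rr"],
                                    f=entry["f"], alpha=cfg["alpha"],
                                    power=cfg["power"],
                                    variant=cfg["variant"])
                res = empirical_power(design, entry["n_total"],
                                      int(cfg["replicates"]),
                                      int(cfg["seed"]))
                sim_entry.update(n_total=entry["n_total"],
                                 estimate=res.estimate, mc_se=res.mc_se,
                                 ci95=list(res.ci95))
            simulation["power"].append(sim_entry)

    return FeasibilityReport(scenario=scenario, sizing=sizing,
                             simulation=simulation, provenance=provenance)
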