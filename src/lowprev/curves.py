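"""Tabular curves: required sample size vs effect size, and effect size vs
sensitivity.

Two long-format tables summarise the feasibility landscape at a given
prevalence:

* :func:`sample_size_curve` — required total cohort size as a function of
  the relative risk to detect, one series per exposure fraction
  (defaults 5%, 10%, 20%, 50%; baseline risk 1%, 90% power, alpha 0.05);
* :func:`relative_risk_curve` — the relative risk a marker must carry as a
  function of its sensitivity, one series per target PPV (defaults 10%,
  20%, 50%; prevalence 1%).

Grid points that violate the underlying domain constraints are skipped
with a logged warning, never emitted as sentinel values; every emitted row
is independently recomputable from the single-point operation it wraps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .risk_algebra import DomainError, rr_from_predictive
from .sample_size import DesignSpec, required_total_n

__all__ = ["CurveTable", "sample_size_curve", "relative_risk_curve"]

logger = logging.getLogger("lowprev")

DEFAULT_RR_GRID = tuple(np.round(np.arange(1.5, 5.0 + 1e-9, 0.1), 10))
DEFAULT_F_VALUES = (0.05, 0.10, 0.20, 0.50)
DEFAULT_S_GRID = tuple(np.round(np.arange(0.05, 0.95 + 1e-9, 0.01), 10))
DEFAULT_PPV_VALUES = (0.10, 0.20, 0.50)


@dataclass(frozen=True)
class CurveTable:
    """Long-format curve data: rows of (x, series, y) plus the fixed
    parameters that generated them."""

    data: pd.DataFrame  # columns: x, series, y
    metadata: dict

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    def write_metadata(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.metadata, indent=2) + "\n")

    def series(self, label: str) -> pd.DataFrame:
        return self.data[self.data["series"] == label]

    def plot(self, path: str | Path, logy: bool = False) -> None:
        """Optional rendering; requires matplotlib."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for label, grp in self.data.groupby("series"):
            ax.plot(grp["x"], grp["y"], label=str(label))
        ax.set_xlabel(self.metadata.get("x_label", "x"))
        ax.set_ylabel(self.metadata.get("y_label", "y"))
        if logy:
            ax.set_yscale("log")
        ax.legend()
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def _timestamp() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def sample_size_curve(rr_grid: Iterable[float] = DEFAULT_RR_GRID,
                      f_values: Sequence[float] = DEFAULT_F_VALUES,
                      r0: float = 0.01, alpha: float = 0.05,
                      power: float = 0.90,
                      variant: str = "pooled") -> CurveTable:
    """Required total cohort size (y) to detect each relative risk in
    ``rr_grid`` (x), one series per exposure fraction in ``f_values``.
    Series labels are ``f=<value>``."""
    rows = []
    for f in f_values:
        for rr in rr_grid:
            try:
                design = DesignSpec(r0=r0, rr=float(rr), f=float(f),
                                    alpha=alpha, power=power, variant=variant)
                n = required_total_n(design).n_total
            except DomainError as exc:
                logger.warning("skipping rr=%g, f=%g: %s", rr, f, exc)
                continue
            rows.append({"x": float(rr), "series": f"f={f:g}", "y": n})
    meta = {"curve": "sample-size", "r0": r0, "alpha": alpha, "power": power,
            "variant": variant, "f_values": list(f_values),
            "rr_grid": [float(v) for v in rr_grid],
            "x_label": "relative risk", "y_label": "required total n",
            "generated": _timestamp()}
    return CurveTable(data=pd.DataFrame(rows), metadata=meta)


def relative_risk_curve(s_grid: Iterable[float] = DEFAULT_S_GRID,
                        ppv_values: Sequence[float] = DEFAULT_PPV_VALUES,
                        p: float = 0.01) -> CurveTable:
    """Relative risk (y) a marker must carry at each sensitivity in
    ``s_grid`` (x) to achieve each PPV in ``ppv_values`` at prevalence
    ``p``.  Series labels are ``ppv=<value>``."""
    rows = []
    for ppv in ppv_values:
        for s in s_grid:
            try:
                rr = rr_from_predictive(p, float(s), float(ppv))
            except DomainError as exc:
                logger.warning("skipping s=%g, ppv=%g: %s", s, ppv, exc)
                continue
            rows.append({"x": float(s), "series": f"ppv={ppv:g}", "y": rr})
    meta = {"curve": "rr-sensitivity", "p": p,
            "ppv_values": list(ppv_values),
            "s_grid": [float(v) for v in s_grid],
            "x_label": "sensitivity", "y_label": "relative risk",
            "generated": _timestamp()}
    return CurveTable(data=pd.DataFrame(rows), metadata=meta)
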