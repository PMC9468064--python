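"""Fermentation yield coefficients, PHA content and volumetric productivities.

Summarizes a batch cultivation by the field's standard endpoint metrics:

* yield coefficients Y_x/basis and Y_PHA/basis (g/g) against the initially
  supplied oil mass, elemental carbon, and elemental nitrogen;
* PHA content, 100·PHA/total biomass (% w/w), and residual (non-polymer)
  biomass, total biomass − PHA (g/L);
* volumetric productivities, concentration / elapsed time (g/L/h).

For blends the oil basis is the *crude-oil-equivalent* feed: the mass of
crude oil that would carry the same total carbon, so that oil-basis yields
of blended and crude-only runs are comparable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "CultivationSummary",
    "MetricsReport",
    "compute_metrics",
    "pha_content",
    "read_cultivation_summaries",
    "metrics_report_json",
]

SUMMARY_COLUMNS = (
    "label", "crude_feed", "saponified_feed", "c0", "n0",
    "total_biomass", "pha", "elapsed_h",
)


@dataclass(frozen=True)
class CultivationSummary:
    """Endpoint state of one batch cultivation."""

    crude_feed: float            # g/L crude oil supplied
    saponified_feed: float       # g/L saponified oil supplied
    c0: float                    # g C/L initially supplied
    n0: float                    # g N/L initially supplied
    total_biomass: float         # g/L at the analyzed endpoint
    pha: float                   # g/L polymer at the analyzed endpoint
    elapsed: float               # h
    crude_equivalent_feed: float | None = None  # oil basis for blend yields
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("crude_feed", "saponified_feed", "c0", "n0",
                     "total_biomass", "pha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.elapsed <= 0:
            raise ValueError("elapsed time must be positive")
        if self.pha > self.total_biomass * (1 + 1e-9):
            raise ValueError("PHA concentration cannot exceed total biomass")

    @property
    def oil_basis(self) -> float:
        """Feed mass used for oil-basis yields (crude equivalent if set)."""
        if self.crude_equivalent_feed is not None:
            return self.crude_equivalent_feed
        return self.crude_feed + self.saponified_feed


def pha_content(pha: float, total_biomass: float) -> float:
    """Intracellular polymer content, 100·PHA/TB (% w/w)."""
    if total_biomass <= 0:
        raise ValueError("total biomass must be positive")
    if pha < 0 or pha > total_biomass * (1 + 1e-9):
        raise ValueError("PHA must lie in [0, total biomass]")
    return 100.0 * pha / total_biomass


@dataclass(frozen=True)
class MetricsReport:
    """Computed endpoint metrics for one cultivation."""

    yields: dict[str, float]             # x_per_oil, x_per_c, x_per_n, pha_per_*
    pha_content: float                   # % w/w
    residual_biomass: float              # g/L
    productivity_biomass: float          # g/L/h
    productivity_pha: float              # g/L/h
    c_to_n: float                        # g/g
    label: str = ""


def compute_metrics(summary: CultivationSummary) -> MetricsReport:
    """All endpoint metrics from one cultivation summary.

    Raises if a requested yield basis (oil, C or N) is zero.
    """
    bases = {"oil": summary.oil_basis, "c": summary.c0, "n": summary.n0}
    for name, value in bases.items():
        if value <= 0:
            raise ValueError(f"zero {name} basis: cannot form a yield coefficient")
    yields = {}
    for name, basis in bases.items():
        yields[f"x_per_{name}"] = summary.total_biomass / basis
        yields[f"pha_per_{name}"] = summary.pha / basis
    return MetricsReport(
        yields=yields,
        pha_content=pha_content(summary.pha, summary.total_biomass),
        residual_biomass=summary.total_biomass - summary.pha,
        productivity_biomass=summary.total_biomass / summary.elapsed,
        productivity_pha=summary.pha / summary.elapsed,
        c_to_n=summary.c0 / summary.n0,
        label=summary.label,
    )


def read_cultivation_summaries(path: str | Path) -> list[CultivationSummary]:
    """Read cultivation summaries from a headered CSV (columns SUMMARY_COLUMNS).

    An optional ``crude_equivalent_feed`` column sets the blend oil basis.
    """
    df = pd.read_csv(path)
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary CSV {path} lacks required columns {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        ceq = row.get("crude_equivalent_feed")
        out.append(CultivationSummary(
            crude_feed=float(row["crude_feed"]),
            saponified_feed=float(row["saponified_feed"]),
            c0=float(row["c0"]),
            n0=float(row["n0"]),
            total_biomass=float(row["total_biomass"]),
            pha=float(row["pha"]),
            elapsed=float(row["elapsed_h"]),
            crude_equivalent_feed=None if ceq is None or pd.isna(ceq) else float(ceq),
            label=str(row["label"]),
        ))
    return out


def metrics_report_json(report: MetricsReport) -> str:
    """JSON with 2-decimal display values alongside full precision."""
    doc = {
        "label": report.label,
        "yields": report.yields,
        "yields_display": {k: round(v, 2) for k, v in report.yields.items()},
        "pha_content_pct": report.pha_content,
        "residual_biomass": report.residual_biomass,
        "productivity_biomass": report.productivity_biomass,
        "productivity_pha": report.productivity_pha,
        "c_to_n": report.c_to_n,
    }
    return json.dumps(doc, indent=2)
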