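"""Specific growth rates from endpoint optical-density measurements.

A shake-flask experiment measures OD600 at inoculation and again at the end
of the cultivation window (24 h in the reference design).  Assuming
exponential growth over the window, the specific growth rate is

    μ = ln(OD_end / OD_start) / (t_end − t_start)

This module computes μ per flask, aggregates replicate flasks per substrate
level under a selectable policy, and reads/writes the delimited flask-record
format shared with the synthetic-data generator.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ODMeasurement",
    "FlaskRecord",
    "FlaskDataset",
    "endpoint_mu",
    "build_dataset",
    "read_flask_records",
    "write_flask_records",
    "FLASK_COLUMNS",
]

FLASK_COLUMNS = (
    "substrate_label", "c0_gC_per_L", "t_start_h", "od_start",
    "t_end_h", "od_end", "replicate_id",
)

REPLICATE_POLICIES = ("mean_od", "mean_mu", "pooled")


@dataclass(frozen=True)
class ODMeasurement:
    """One OD600 reading at a given time (h)."""

    time: float
    od600: float
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.od600 <= 0:
            raise ValueError(f"od600 must be positive, got {self.od600}")
        if self.time < 0:
            raise ValueError(f"time must be non-negative, got {self.time}")


@dataclass(frozen=True)
class FlaskRecord:
    """One flask: carbon level, start/end OD, substrate identity."""

    c0: float                    # g C/L
    od_start: ODMeasurement
    od_end: ODMeasurement
    substrate_label: str = "crude"
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise ValueError("c0 must be non-negative")
        if self.od_end.time <= self.od_start.time:
            raise ValueError("od_end must be measured after od_start")


def endpoint_mu(od_start: ODMeasurement, od_end: ODMeasurement) -> float:
    """Specific growth rate (h⁻¹) from two OD600 readings.

    μ = ln(OD_end/OD_start) / Δt.  Negative if the culture density declined;
    no clamping is applied here (complete-inhibition handling lives in
    :func:`build_dataset` via the detection floor).
    """
    dt = od_end.time - od_start.time
    if dt <= 0:
        raise ValueError("elapsed time must be positive")
    return math.log(od_end.od600 / od_start.od600) / dt


@dataclass(frozen=True)
class FlaskDataset:
    """Aggregated (c0, μ) observations ready for model fitting."""

    c0: np.ndarray               # g C/L, ascending
    mu: np.ndarray               # h⁻¹, aligned with c0
    substrate_label: str = "crude"
    replicate_policy: str = "mean_od"
    records: tuple[FlaskRecord, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "c0", np.asarray(self.c0, dtype=float))
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))
        if self.c0.shape != self.mu.shape:
            raise ValueError("c0 and mu must align")
        if np.any(np.diff(self.c0) < 0):
            raise ValueError("c0 must be sorted ascending")

    @property
    def n_obs(self) -> int:
        return int(self.c0.size)

    def observation_hash(self) -> str:
        """Stable digest of the (c0, μ) observations, for fit provenance."""
        h = hashlib.sha256()
        h.update(np.round(self.c0, 12).tobytes())
        h.update(np.round(self.mu, 12).tobytes())
        return h.hexdigest()[:16]


def _record_mu(rec: FlaskRecord, detection_floor: float | None) -> float:
    if detection_floor is not None and rec.od_end.od600 < detection_floor:
        return 0.0
    return endpoint_mu(rec.od_start, rec.od_end)


def build_dataset(
    records: Sequence[FlaskRecord],
    replicate_policy: str = "mean_od",
    detection_floor: float | None = None,
    allow_mixed_substrates: bool = False,
) -> FlaskDataset:
    """Aggregate flask records into a fitting dataset, sorted by c0.

    Policies
    --------
    mean_od  : average replicate ODs at each c0 level, then one μ per level
    mean_mu  : one μ per flask, averaged per level
    pooled   : every flask contributes its own (c0, μ) pair (no averaging)

    Flasks whose final OD falls below ``detection_floor`` are assigned μ = 0
    (no detectable biomass at complete inhibition).
    """
    if replicate_policy not in REPLICATE_POLICIES:
        raise ValueError(f"replicate_policy must be one of {REPLICATE_POLICIES}")
    if not records:
        raise ValueError("no flask records supplied")

    labels = {r.substrate_label for r in records}
    if len(labels) > 1 and not allow_mixed_substrates:
        raise ValueError(
            f"records mix substrate labels {sorted(labels)}; "
            "pass allow_mixed_substrates=True if intended"
        )
    label = records[0].substrate_label if len(labels) == 1 else "mixed"

    by_level: dict[float, list[FlaskRecord]] = {}
    for rec in records:
        by_level.setdefault(rec.c0, []).append(rec)
    for level, recs in by_level.items():
        ids = [r.replicate_id for r in recs if r.replicate_id]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate replicate ids at c0={level}")

    c0s: list[float] = []
    mus: list[float] = []
    for level in sorted(by_level):
        recs = by_level[level]
        if replicate_policy == "pooled":
            for rec in recs:
                c0s.append(level)
                mus.append(_record_mu(rec, detection_floor))
        elif replicate_policy == "mean_mu":
            c0s.append(level)
            mus.append(float(np.mean([_record_mu(r, detection_floor) for r in recs])))
        else:  # mean_od: average ODs first, then one μ
            od0 = float(np.mean([r.od_start.od600 for r in recs]))
            od1 = float(np.mean([r.od_end.od600 for r in recs]))
            t0 = float(np.mean([r.od_start.time for r in recs]))
            t1 = float(np.mean([r.od_end.time for r in recs]))
            if detection_floor is not None and od1 < detection_floor:
                mu = 0.0
            else:
                mu = endpoint_mu(ODMeasurement(t0, od0), ODMeasurement(t1, od1))
            c0s.append(level)
            mus.append(mu)

    return FlaskDataset(
        c0=np.array(c0s), mu=np.array(mus), substrate_label=label,
        replicate_policy=replicate_policy, records=tuple(records),
    )


def read_flask_records(path: str | Path) -> list[FlaskRecord]:
    """Read flask records from a headered CSV (columns: FLASK_COLUMNS)."""
    df = pd.read_csv(path)
    missing = set(FLASK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"flask CSV {path} lacks required columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        rid = "" if pd.isna(row.replicate_id) else str(row.replicate_id)
        records.append(FlaskRecord(
            c0=float(row.c0_gC_per_L),
            od_start=ODMeasurement(float(row.t_start_h), float(row.od_start), rid),
            od_end=ODMeasurement(float(row.t_end_h), float(row.od_end), rid),
            substrate_label=str(row.substrate_label),
            replicate_id=rid,
        ))
    return records


def write_flask_records(records: Iterable[FlaskRecord], path: str | Path) -> None:
    """Write flask records as a headered CSV readable by read_flask_records."""
    rows = [
        {
            "substrate_label": r.substrate_label,
            "c0_gC_per_L": r.c0,
            "t_start_h": r.od_start.time,
            "od_start": r.od_start.od600,
            "t_end_h": r.od_end.time,
            "od_end": r.od_end.od600,
            "replicate_id": r.replicate_id,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(FLASK_COLUMNS)).to_csv(path, index=False)
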