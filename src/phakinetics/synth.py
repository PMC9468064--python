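"""Synthetic shake-flask datasets with known growth-kinetic truth.

The generator inverts the endpoint growth-rate formula: given a true model
μ(C0), a flask at carbon level c0 ends after t hours at

    OD_end = OD_0 · exp(μ(c0) · t) · exp(σ·Z),   Z ~ N(0, 1)

i.e. lognormal multiplicative noise on the final optical density, which is
how replicate scatter presents in endpoint OD data (reported spreads like
7.4 ± 0.3 are a few percent of the mean).  On the μ scale the noise becomes
additive with mean zero (σ/t per observation), so replicate means of μ
converge to the truth; no lognormal mean-correction is applied.

:func:`shake_flask_design` reproduces the reference experiment: eight oil
levels evenly spaced over 3.72–30.00 g/L, converted to carbon (≈2.9–23.0
g C/L) with the crude-oil carbon fraction for both substrates (the
saponified flasks matched the crude carbon levels), duplicate flasks,
initial OD600 0.24, 24-h endpoint, and the fitted Han-Levenspiel parameters
as truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from .chemistry import COMPOSITION_PRESETS
from .growth import FlaskRecord, ODMeasurement
from .models import (CRUDE_SCG_ESTIMATES, SAPONIFIED_SCG_ESTIMATES,
                     ParameterSet, evaluate)

__all__ = ["GeneratorConfig", "generate_flasks", "shake_flask_design"]

REFERENCE_OIL_RANGE = (3.72, 30.00)   # g oil/L, crude-oil mass scale
REFERENCE_N_LEVELS = 8
REFERENCE_OD_INITIAL = 0.24
REFERENCE_DURATION_H = 24.0
REFERENCE_REPLICATES = 2


@dataclass(frozen=True)
class GeneratorConfig:
    """Design of a synthetic shake-flask experiment."""

    truth: ParameterSet
    c0_grid: tuple[float, ...]            # g C/L
    od_initial: float = REFERENCE_OD_INITIAL
    duration: float = REFERENCE_DURATION_H
    replicates_per_level: int = REFERENCE_REPLICATES
    noise_sigma: float = 0.03             # lognormal SD on final OD
    seed: int = 0
    substrate_label: str = "crude"

    def __post_init__(self) -> None:
        object.__setattr__(self, "c0_grid", tuple(float(c) for c in self.c0_grid))
        if any(c < 0 for c in self.c0_grid):
            raise ValueError("c0 levels must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.replicates_per_level < 1:
            raise ValueError("replicates_per_level must be ≥ 1")
        if self.od_initial <= 0 or self.duration <= 0:
            raise ValueError("od_initial and duration must be positive")

    def to_json(self) -> str:
        return json.dumps({
            "truth": json.loads(self.truth.to_json()),
            "c0_grid": list(self.c0_grid),
            "od_initial": self.od_initial,
            "duration": self.duration,
            "replicates_per_level": self.replicates_per_level,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "substrate_label": self.substrate_label,
        })

    @classmethod
    def from_json(cls, doc: str | dict) -> "GeneratorConfig":
        data = dict(json.loads(doc)) if isinstance(doc, str) else dict(doc)
        data["truth"] = ParameterSet.from_json(data["truth"])
        data["c0_grid"] = tuple(data["c0_grid"])
        return cls(**data)


def generate_flasks(config: GeneratorConfig) -> list[FlaskRecord]:
    """Simulate flask records; deterministic for a given config seed.

    With ``noise_sigma=0`` the endpoint formula applied to each record
    recovers μ(truth, c0) exactly.
    """
    rng = np.random.default_rng(config.seed)
    records: list[FlaskRecord] = []
    for level_idx, c0 in enumerate(config.c0_grid):
        mu = evaluate(config.truth, c0)
        for rep in range(config.replicates_per_level):
            z = rng.standard_normal() if config.noise_sigma > 0 else 0.0
            od_end = config.od_initial * math.exp(mu * config.duration) \
                * math.exp(config.noise_sigma * z)
            rid = f"L{level_idx}R{rep + 1}"
            records.append(FlaskRecord(
                c0=c0,
                od_start=ODMeasurement(0.0, config.od_initial, rid),
                od_end=ODMeasurement(config.duration, od_end, rid),
                substrate_label=config.substrate_label,
                replicate_id=rid,
            ))
    return records


def reference_c0_grid() -> tuple[float, ...]:
    """Eight carbon levels: evenly spaced oil masses 3.72–30.00 g/L converted
    with the crude-oil carbon fraction (spans ≈2.9–23.0 g C/L)."""
    c_frac = COMPOSITION_PRESETS["scg_crude"].c_fraction
    oil = np.linspace(*REFERENCE_OIL_RANGE, REFERENCE_N_LEVELS)
    return tuple(float(x) for x in oil * c_frac)


def shake_flask_design(
    substrate: str = "crude",
    noise_sigma: float = 0.03,
    seed: int = 0,
    replicates_per_level: int = REFERENCE_REPLICATES,
) -> GeneratorConfig:
    """The reference shake-flask design for one substrate.

    Truth is the fitted Han-Levenspiel parameter set for the chosen oil.
    The saponified design shares the crude carbon grid, whose two highest
    levels exceed the saponified critical concentration (19.11 g C/L) and so
    yield zero-growth flasks.
    """
    if substrate == "crude":
        truth = CRUDE_SCG_ESTIMATES["han_levenspiel"]
    elif substrate == "saponified":
        truth = SAPONIFIED_SCG_ESTIMATES["han_levenspiel"]
    else:
        raise ValueError("substrate must be 'crude' or 'saponified'")
    return GeneratorConfig(
        truth=truth,
        c0_grid=reference_c0_grid(),
        noise_sigma=noise_sigma,
        seed=seed,
        replicates_per_level=replicates_per_level,
        substrate_label=substrate,
    )
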