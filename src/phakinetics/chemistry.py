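"""Saponification and substrate-loading stoichiometry.

Conversions between oil mass, elemental carbon, potassium and nitrogen
loadings, based on measured elemental compositions; extent-of-saponification
and KOH-demand arithmetic from saponification values; and carbon-split
design of crude/saponified oil blends.

Saponification value (SV): mg of KOH required to fully saponify 1 g of oil.
Extent of saponification (%): 100 · SV_sample / SV_oil.

Built-in composition presets ``scg_crude`` and ``scg_saponified`` carry the
measured elemental fractions of crude and saponified spent-coffee-ground
oil (C 76.74 % vs 58.11 % w/w; the saponified product carries 12.92 % w/w
potassium from the KOH counter-ion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

__all__ = [
    "OilComposition",
    "SaponificationAssay",
    "BlendSpec",
    "COMPOSITION_PRESETS",
    "get_composition",
    "extent_of_saponification",
    "minimum_koh_molarity",
    "carbon_loading",
    "substrate_for_carbon",
    "potassium_loading",
    "substrate_for_potassium",
    "nitrogen_from_ammonium_chloride",
    "design_blend",
    "MOLAR_MASS",
]

# g/mol, 4-5 significant figures
MOLAR_MASS = {"KOH": 56.11, "K": 39.098, "N": 14.007, "NH4Cl": 53.491}

_FRACTION_SUM_TOL = 0.02


@dataclass(frozen=True)
class OilComposition:
    """Elemental mass fractions (g/g) and saponification value of an oil."""

    c_fraction: float
    h_fraction: float = 0.0
    o_fraction: float = 0.0
    k_fraction: float = 0.0
    sv: float | None = None                    # mg KOH / g oil
    fatty_acid_profile: dict[str, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        fracs = (self.c_fraction, self.h_fraction, self.o_fraction, self.k_fraction)
        for f in fracs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"mass fractions must lie in [0, 1], got {f}")
        if sum(fracs) > 1.0 + _FRACTION_SUM_TOL:
            raise ValueError(f"elemental fractions sum to {sum(fracs):.4f} > 1")
        if self.sv is not None and self.sv < 0:
            raise ValueError("saponification value must be non-negative")

    @classmethod
    def from_config(cls, doc: str | dict, name: str = "") -> "OilComposition":
        data = dict(json.loads(doc)) if isinstance(doc, str) else dict(doc)
        return cls(
            c_fraction=float(data["c_fraction"]),
            h_fraction=float(data.get("h_fraction", 0.0)),
            o_fraction=float(data.get("o_fraction", 0.0)),
            k_fraction=float(data.get("k_fraction", 0.0)),
            sv=None if data.get("sv") is None else float(data["sv"]),
            fatty_acid_profile=dict(data.get("fatty_acids", {})),
            name=name or str(data.get("name", "")),
        )


#: Measured compositions of the crude and saponified spent-coffee-ground oils
#: (elemental %, w/w → fractions; fatty-acid profile %, w/w; SV mg KOH/g).
COMPOSITION_PRESETS: dict[str, OilComposition] = {
    "scg_crude": OilComposition(
        c_fraction=0.7674, h_fraction=0.1166, o_fraction=0.1161, k_fraction=0.0,
        sv=175.7,
        fatty_acid_profile={
            "palmitic": 31.4, "stearic": 6.6, "oleic": 17.1, "linoleic": 39.6,
            "alpha_linolenic": 2.5, "arachidic": 0.6, "behenic": 0.5, "other": 1.7,
        },
        name="scg_crude",
    ),
    "scg_saponified": OilComposition(
        c_fraction=0.5811, h_fraction=0.0925, o_fraction=0.1966, k_fraction=0.1292,
        sv=175.7,
        fatty_acid_profile={
            "palmitic": 30.9, "stearic": 6.6, "oleic": 17.1, "linoleic": 38.2,
            "alpha_linolenic": 2.6, "arachidic": 0.5, "behenic": 0.5, "other": 3.6,
        },
        name="scg_saponified",
    ),
}


def get_composition(name: str) -> OilComposition:
    try:
        return COMPOSITION_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown composition preset '{name}'; "
            f"available: {', '.join(COMPOSITION_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class SaponificationAssay:
    """One saponification run: measured SVs plus reaction conditions."""

    sv_sample: float                 # mg KOH/g
    sv_oil: float                    # mg KOH/g of the untreated oil
    koh_molarity: float | None = None
    temperature: float | None = None  # °C
    time: float | None = None         # min
    oil_loading: float | None = None  # g oil per L reagent solution

    def __post_init__(self) -> None:
        if self.sv_oil < 0 or self.sv_sample < 0:
            raise ValueError("saponification values must be non-negative")
        if self.sv_oil > 0 and self.sv_sample > self.sv_oil * 1.05:
            raise ValueError("sv_sample exceeds sv_oil beyond measurement tolerance")


def extent_of_saponification(assay: SaponificationAssay) -> float:
    """Percent conversion: 100 · SV_sample / SV_oil."""
    if assay.sv_oil <= 0:
        raise ValueError("sv_oil must be positive")
    return 100.0 * assay.sv_sample / assay.sv_oil


def minimum_koh_molarity(sv_oil: float, oil_loading: float) -> float:
    """Lowest KOH concentration (mol/L) that fully saponifies the oil.

    An oil of saponification value ``sv_oil`` (mg KOH per g oil) loaded at
    ``oil_loading`` g oil per litre of reagent demands
    sv_oil·oil_loading mg KOH per litre, i.e. sv_oil·oil_loading/(1000·56.11)
    mol/L.  At the reference loading of 100 g/L (1 g oil per 10 mL reagent)
    and SV = 175.7 this is 0.313 mol/L.
    """
    if sv_oil < 0 or oil_loading < 0:
        raise ValueError("inputs must be non-negative")
    if oil_loading == 0:
        raise ValueError("oil_loading must be positive")
    return sv_oil * oil_loading / (1000.0 * MOLAR_MASS["KOH"])


def carbon_loading(substrate_conc: float, comp: OilComposition) -> float:
    """g C/L supplied by ``substrate_conc`` g/L of the given oil."""
    if substrate_conc < 0:
        raise ValueError("substrate concentration must be non-negative")
    return substrate_conc * comp.c_fraction


def substrate_for_carbon(target_c: float, comp: OilComposition) -> float:
    """g/L of oil needed to supply ``target_c`` g C/L (inverse of carbon_loading)."""
    if comp.c_fraction <= 0:
        raise ValueError("composition has zero carbon fraction")
    if target_c < 0:
        raise ValueError("target carbon must be non-negative")
    return target_c / comp.c_fraction


def potassium_loading(substrate_conc: float, comp: OilComposition) -> float:
    """g K/L introduced by ``substrate_conc`` g/L of the given (saponified) oil."""
    if substrate_conc < 0:
        raise ValueError("substrate concentration must be non-negative")
    return substrate_conc * comp.k_fraction


def substrate_for_potassium(target_k: float, comp: OilComposition) -> float:
    """g/L of oil that introduces ``target_k`` g K/L (inverse of potassium_loading)."""
    if comp.k_fraction <= 0:
        raise ValueError("composition has zero potassium fraction")
    if target_k < 0:
        raise ValueError("target potassium must be non-negative")
    return target_k / comp.k_fraction


def nitrogen_from_ammonium_chloride(conc: float) -> float:
    """g N/L supplied by ``conc`` g/L NH4Cl (mass-fraction 14.007/53.491)."""
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    return conc * MOLAR_MASS["N"] / MOLAR_MASS["NH4Cl"]


@dataclass(frozen=True)
class BlendSpec:
    """A crude/saponified blend defined by total carbon and the crude C share."""

    total_c0: float                      # g C/L
    crude_c_share: float                 # fraction of carbon from crude oil
    crude_composition: OilComposition = COMPOSITION_PRESETS["scg_crude"]
    saponified_composition: OilComposition = COMPOSITION_PRESETS["scg_saponified"]

    def __post_init__(self) -> None:
        if not 0.0 <= self.crude_c_share <= 1.0:
            raise ValueError("crude_c_share must lie in [0, 1]")
        if self.total_c0 < 0:
            raise ValueError("total_c0 must be non-negative")


def design_blend(spec: BlendSpec, n0: float | None = None) -> dict[str, float]:
    """Oil masses realizing a carbon-split blend, plus the C/N ratio if N is given.

    Returns ``{"crude_conc", "saponified_conc", "total_c0"}`` in g/L with
    ``"c_to_n"`` added when ``n0`` (g N/L) is supplied.  The components'
    carbon loadings sum back to ``total_c0`` exactly.
    """
    crude_c = spec.total_c0 * spec.crude_c_share
    sap_c = spec.total_c0 - crude_c
    crude_conc = substrate_for_carbon(crude_c, spec.crude_composition) if crude_c > 0 else 0.0
    sap_conc = substrate_for_carbon(sap_c, spec.saponified_composition) if sap_c > 0 else 0.0
    out = {
        "crude_conc": crude_conc,
        "saponified_conc": sap_conc,
        "total_c0": spec.total_c0,
    }
    if n0 is not None:
        if n0 <= 0:
            raise ValueError("n0 must be positive to form a C/N ratio")
        out["c_to_n"] = spec.total_c0 / n0
    return out
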