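"""Substrate-inhibition growth models μ(C0).

Nine Monod-family models relating the specific growth rate μ (h⁻¹) of a
culture to the initial carbon-substrate concentration C0 (g C/L).  Each
model is registered as a :class:`ModelSpec` carrying its closed form, its
ordered parameter symbols and per-symbol admissible bounds.  The
Han-Levenspiel and Luong models predict a critical concentration Cmax at
which growth ceases entirely; their cutoff factor ``(1 - C0/Cmax)`` is
clamped to zero for C0 ≥ Cmax so that non-integer exponents never see a
negative base.

Parameter symbols
-----------------
mu_max : maximum specific growth rate (h⁻¹)
Ks     : half-saturation constant (g C/L)
Ki     : inhibition constant (g C/L)
Cmax   : critical substrate concentration, zero growth at and above (g C/L)
K      : secondary rate/affinity constant (g C/L)
n, m   : dimensionless exponents (Han-Levenspiel: m > n > 0 indicates
         uncompetitive substrate inhibition)
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "InhibitionCall",
    "MODELS",
    "MODEL_NAMES",
    "get_model",
    "evaluate",
    "find_peak",
    "critical_concentration",
    "classify_inhibition",
    "CRUDE_SCG_ESTIMATES",
    "SAPONIFIED_SCG_ESTIMATES",
]

_POS = (1e-12, np.inf)          # strictly positive parameters
_EXPONENT = (0.0, 50.0)         # n, m capped to avoid overflow pseudo-fits


def _clamped_cutoff(c0: np.ndarray, cmax: float, expo: float) -> np.ndarray:
    """(1 - c0/cmax)**expo with the base clamped at 0 for c0 >= cmax."""
    base = np.clip(1.0 - np.asarray(c0, dtype=float) / cmax, 0.0, None)
    with np.errstate(divide="ignore"):
        return np.power(base, expo)


def _monod(c, p):
    return p["mu_max"] * c / (p["Ks"] + c)


def _andrews(c, p):
    return p["mu_max"] * c / ((p["Ks"] + c) * (1.0 + c / p["Ki"]))


def _aiba(c, p):
    return p["mu_max"] * c / (p["Ks"] + c) * np.exp(-c / p["Ki"])


def _haldane(c, p):
    # standard form Ks + C0 + C0^2/Ki (argmax at sqrt(Ks*Ki))
    return p["mu_max"] * c / (p["Ks"] + c + c * c / p["Ki"])


def _han_levenspiel(c, p):
    c = np.asarray(c, dtype=float)
    num = p["mu_max"] * c * _clamped_cutoff(c, p["Cmax"], p["n"])
    den = c + p["Ks"] * _clamped_cutoff(c, p["Cmax"], p["m"])
    out = np.where(c >= p["Cmax"], 0.0, np.divide(num, den, out=np.zeros_like(num), where=den > 0))
    return out


def _luong(c, p):
    c = np.asarray(c, dtype=float)
    mu = p["mu_max"] * c / (p["Ks"] + c) * _clamped_cutoff(c, p["Cmax"], p["n"])
    return np.where(c >= p["Cmax"], 0.0, mu)


def _moser(c, p):
    c = np.asarray(c, dtype=float)
    n = p["n"]
    with np.errstate(divide="ignore", invalid="ignore"):
        cn = np.power(c, n)
        mu = p["mu_max"] * cn / (p["Ks"] ** n + cn)
    return np.where(c == 0.0, 0.0, mu)


def _webb(c, p):
    return p["mu_max"] * c * (1.0 + c / p["K"]) / (p["Ks"] + c + c * c / p["Ki"])


def _yano(c, p):
    return p["mu_max"] * c / (p["Ks"] + c + (c * c / p["Ki"]) * (1.0 + c / p["K"]))


@dataclass(frozen=True)
class ModelSpec:
    """A named growth model: closed form plus parameter metadata."""

    name: str
    parameter_symbols: tuple[str, ...]
    bounds: dict[str, tuple[float, float]]
    func: Callable[[np.ndarray, dict[str, float]], np.ndarray]
    monotone: bool = False  # strictly non-decreasing in C0 (no interior peak)

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_symbols)

    def validate(self, values: dict[str, float]) -> None:
        missing = set(self.parameter_symbols) - set(values)
        extra = set(values) - set(self.parameter_symbols)
        if missing or extra:
            raise ValueError(
                f"model '{self.name}' expects symbols {self.parameter_symbols}; "
                f"missing={sorted(missing)}, unexpected={sorted(extra)}"
            )
        for sym in self.parameter_symbols:
            v = values[sym]
            lo, hi = self.bounds[sym]
            if not np.isfinite(v) or not (lo <= v <= hi):
                raise ValueError(
                    f"parameter {sym}={v} outside admissible bounds [{lo}, {hi}] "
                    f"for model '{self.name}'"
                )


MODELS: dict[str, ModelSpec] = {
    "monod": ModelSpec("monod", ("mu_max", "Ks"),
                       {"mu_max": _POS, "Ks": _POS}, _monod, monotone=True),
    "andrews": ModelSpec("andrews", ("mu_max", "Ks", "Ki"),
                         {"mu_max": _POS, "Ks": _POS, "Ki": _POS}, _andrews),
    "aiba": ModelSpec("aiba", ("mu_max", "Ks", "Ki"),
                      {"mu_max": _POS, "Ks": _POS, "Ki": _POS}, _aiba),
    "haldane": ModelSpec("haldane", ("mu_max", "Ks", "Ki"),
                         {"mu_max": _POS, "Ks": _POS, "Ki": _POS}, _haldane),
    "han_levenspiel": ModelSpec(
        "han_levenspiel", ("mu_max", "Ks", "Cmax", "n", "m"),
        {"mu_max": _POS, "Ks": _POS, "Cmax": _POS, "n": _EXPONENT, "m": _EXPONENT},
        _han_levenspiel),
    "luong": ModelSpec("luong", ("mu_max", "Ks", "Cmax", "n"),
                       {"mu_max": _POS, "Ks": _POS, "Cmax": _POS, "n": _EXPONENT},
                       _luong),
    "moser": ModelSpec("moser", ("mu_max", "Ks", "n"),
                       {"mu_max": _POS, "Ks": _POS, "n": _EXPONENT}, _moser,
                       monotone=True),
    "webb": ModelSpec("webb", ("mu_max", "Ks", "Ki", "K"),
                      {"mu_max": _POS, "Ks": _POS, "Ki": _POS, "K": _POS}, _webb),
    "yano": ModelSpec("yano", ("mu_max", "Ks", "Ki", "K"),
                      {"mu_max": _POS, "Ks": _POS, "Ki": _POS, "K": _POS}, _yano),
}

MODEL_NAMES: tuple[str, ...] = tuple(MODELS)


def get_model(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model '{name}'; available: {', '.join(MODEL_NAMES)}"
        ) from None


@dataclass(frozen=True)
class ParameterSet:
    """Values for one model's symbols (g C/L for concentrations, h⁻¹ for rates)."""

    model_name: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        get_model(self.model_name).validate(self.values)

    def __getitem__(self, symbol: str) -> float:
        return self.values[symbol]

    def to_json(self) -> str:
        return json.dumps({"model": self.model_name, **self.values})

    @classmethod
    def from_json(cls, doc: str | dict) -> "ParameterSet":
        data = dict(json.loads(doc)) if isinstance(doc, str) else dict(doc)
        try:
            model = data.pop("model")
        except KeyError:
            raise ValueError("parameter document lacks a 'model' key") from None
        return cls(model, {k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class InhibitionCall:
    """Inhibition-type classification from Han-Levenspiel exponents."""

    label: str  # uncompetitive | other | not_applicable
    n: float | None = None
    m: float | None = None


def classify_inhibition(n: float | None, m: float | None) -> InhibitionCall:
    """Classify substrate inhibition from Han-Levenspiel exponents.

    The exponent ordering m > n > 0 indicates uncompetitive inhibition;
    no further taxonomy is asserted for other orderings ("other").  Pass
    ``None`` for models without these exponents.
    """
    if n is None or m is None:
        return InhibitionCall("not_applicable", n, m)
    if not (math.isfinite(n) and math.isfinite(m)):
        raise ValueError("exponents must be finite")
    if n < 0 or m < 0:
        raise ValueError("exponents must be non-negative")
    label = "uncompetitive" if m > n > 0 else "other"
    return InhibitionCall(label, n, m)


def evaluate(params: ParameterSet, c0) -> float | np.ndarray:
    """Specific growth rate μ (h⁻¹) at carbon concentration c0 (g C/L).

    Accepts a scalar or array c0.  For the Han-Levenspiel and Luong models
    μ = 0 for all c0 ≥ Cmax.  Raises for negative c0.
    """
    spec = get_model(params.model_name)
    arr = np.asarray(c0, dtype=float)
    if np.any(arr < 0):
        raise ValueError("c0 must be non-negative")
    mu = spec.func(arr, params.values)
    mu = np.maximum(mu, 0.0)
    return float(mu) if np.isscalar(c0) or arr.ndim == 0 else mu


def critical_concentration(params: ParameterSet) -> float | None:
    """Finite carbon concentration at which growth ceases, if the model has one.

    Returns Cmax for Han-Levenspiel and Luong; ``None`` for the seven models
    whose μ stays positive for all C0 > 0.
    """
    if params.model_name in ("han_levenspiel", "luong"):
        return params["Cmax"]
    return None


def find_peak(
    params: ParameterSet,
    search_upper: float | None = None,
    n_grid: int = 101,
    xatol: float = 1e-6,
) -> tuple[float, float]:
    """Locate the maximizer of μ(C0) on (0, U].

    U defaults to Cmax for models that have one; otherwise ``search_upper``
    is required.  A coarse grid (``n_grid`` points) brackets the optimum —
    the fitted optima here are very flat — and a bounded scalar minimizer
    refines it to ``xatol``.  Returns ``(c0_at_peak, mu_peak)``.
    """
    upper = critical_concentration(params)
    if search_upper is not None:
        upper = search_upper if upper is None else min(upper, search_upper)
    if upper is None:
        raise ValueError(
            f"model '{params.model_name}' has no finite zero-growth concentration; "
            "a search_upper bound is required"
        )
    if upper <= 0:
        raise ValueError("search interval must have positive length")

    grid = np.linspace(upper / n_grid, upper, n_grid)
    mu = evaluate(params, grid)
    if not np.all(np.isfinite(mu)):
        raise FloatingPointError("non-finite growth rate inside search interval")
    i = int(np.argmax(mu))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    if lo == hi:
        return float(grid[i]), float(mu[i])

    res = minimize_scalar(
        lambda c: -evaluate(params, float(c)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": xatol},
    )
    c_star, mu_star = float(res.x), float(-res.fun)
    # keep the grid point if the refiner somehow did worse
    if mu[i] > mu_star:
        return float(grid[i]), float(mu[i])
    return c_star, mu_star


def _pset(model: str, **values: float) -> ParameterSet:
    return ParameterSet(model, values)


#: Fitted parameter estimates for Cupriavidus necator DSM 545 on crude
#: spent-coffee-ground oil (carbon basis, g C/L; 24-h shake-flask endpoint data).
CRUDE_SCG_ESTIMATES: dict[str, ParameterSet] = {
    "monod": _pset("monod", mu_max=0.144, Ks=0.69),
    "aiba": _pset("aiba", mu_max=0.144, Ks=0.61, Ki=731.08),
    "andrews": _pset("andrews", mu_max=0.144, Ks=0.61, Ki=736.03),
    "haldane": _pset("haldane", mu_max=0.144, Ks=0.68, Ki=35.69),
    "han_levenspiel": _pset("han_levenspiel", mu_max=0.145, Ks=2.65,
                            Cmax=28.50, n=0.096, m=8.995),
    "luong": _pset("luong", mu_max=0.141, Ks=0.61, Cmax=23.25, n=2.091),
    "moser": _pset("moser", mu_max=0.144, Ks=0.61, n=0.021),
    "webb": _pset("webb", mu_max=0.144, Ks=3.84, Ki=0.69, K=0.72),
    "yano": _pset("yano", mu_max=0.144, Ks=0.60, Ki=6.43e7, K=1.13e-4),
}

#: Same organism on saponified spent-coffee-ground oil.
SAPONIFIED_SCG_ESTIMATES: dict[str, ParameterSet] = {
    "monod": _pset("monod", mu_max=0.151, Ks=1.06),
    "aiba": _pset("aiba", mu_max=0.151, Ks=1.03, Ki=7530.31),
    "andrews": _pset("andrews", mu_max=0.151, Ks=1.03, Ki=7582.16),
    "haldane": _pset("haldane", mu_max=0.151, Ks=1.06, Ki=88.14),
    "han_levenspiel": _pset("han_levenspiel", mu_max=0.152, Ks=4.89,
                            Cmax=19.11, n=0.058, m=5.456),
    "luong": _pset("luong", mu_max=0.151, Ks=0.99, Cmax=17.14, n=0.003),
    "moser": _pset("moser", mu_max=0.149, Ks=0.58, n=1.385),
    "webb": _pset("webb", mu_max=0.151, Ks=3.84, Ki=1.49, K=1.57),
    "yano": _pset("yano", mu_max=0.151, Ks=0.95, Ki=1.13e7, K=2.19e-3),
}
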