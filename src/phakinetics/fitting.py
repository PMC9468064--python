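"""Nonlinear least-squares estimation and ranking of the growth models.

Each model is fitted to a :class:`~phakinetics.growth.FlaskDataset` by
minimizing the sum of squared μ residuals with bounded trust-region least
squares, started from a deterministic model-specific grid of initial
guesses (the fitted optima are very flat, Han-Levenspiel especially, so a
single start is unreliable).  Fits are scored by

    R²   = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²
    RMSE = √(Σ(yᵢ − ŷᵢ)² / n)

and ranked, by default on R² with RMSE as tiebreaker and fewer parameters
breaking exact ties.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .growth import FlaskDataset
from .models import MODEL_NAMES, ModelSpec, ParameterSet, get_model

__all__ = [
    "FitOptions",
    "FitResult",
    "ModelRanking",
    "r_squared",
    "rmse",
    "fit_model",
    "fit_all",
    "rank_models",
    "fit_report",
]


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 − SSres/SStot.  ≤ 1; can be negative."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size < 2:
        raise ValueError("observed and predicted must align, length ≥ 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("observed values are all identical (zero total sum of squares)")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root-mean-square error √(Σ(yᵢ−ŷᵢ)²/n)."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape or y.size == 0:
        raise ValueError("observed and predicted must align and be non-empty")
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


@dataclass(frozen=True)
class FitOptions:
    """Controls for the multi-start least-squares search."""

    n_starts: int | None = None      # None: the full deterministic start grid
    seed: int = 0                    # for random starts beyond the grid
    max_iterations: int = 1000
    bounds_policy: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_starts is not None and self.n_starts < 1:
            raise ValueError("n_starts must be ≥ 1")


@dataclass(frozen=True)
class FitResult:
    """One fitted model with goodness-of-fit and provenance."""

    params: ParameterSet
    r_squared: float
    rmse: float
    residuals: tuple[tuple[float, float], ...]   # (c0, y − ŷ)
    converged: bool
    n_obs: int
    sse: float
    n_starts_used: int
    data_hash: str

    @property
    def model_name(self) -> str:
        return self.params.model_name

    @property
    def n_parameters(self) -> int:
        return get_model(self.model_name).n_parameters


def _start_grid(spec: ModelSpec, c0: np.ndarray, mu: np.ndarray) -> list[dict[str, float]]:
    """Deterministic initial guesses tailored to the observed data."""
    mu_max0 = 1.05 * max(float(mu.max()), 1e-3)
    half = mu.max() / 2.0
    above = c0[mu >= half]
    ks0 = float(above[0]) if above.size else float(np.median(c0))
    ks0 = max(ks0, 1e-3)
    # Cmax starts hug the largest level that still grew: with zero-growth
    # levels present the true cutoff sits just above it, not above the grid max
    growing = c0[mu > 0]
    cmax_scale = float(growing.max()) if growing.size else float(c0.max())

    per_symbol: dict[str, list[float]] = {}
    for sym in spec.parameter_symbols:
        if sym == "mu_max":
            per_symbol[sym] = [mu_max0]
        elif sym == "Ks":
            per_symbol[sym] = [ks0]
        elif sym == "Cmax":
            per_symbol[sym] = [1.05 * cmax_scale, 1.2 * cmax_scale, 1.5 * cmax_scale]
        elif sym in ("n", "m"):
            per_symbol[sym] = [0.1, 1.0, 5.0]
        elif sym in ("Ki", "K"):
            per_symbol[sym] = [cmax_scale, 10 * cmax_scale, 100 * cmax_scale]
        else:  # pragma: no cover - registry is closed
            per_symbol[sym] = [1.0]

    combos = itertools.product(*(per_symbol[s] for s in spec.parameter_symbols))
    return [dict(zip(spec.parameter_symbols, combo)) for combo in combos]


def _fit_bounds(
    spec: ModelSpec, c0: np.ndarray, mu: np.ndarray,
    overrides: dict[str, tuple[float, float]],
) -> tuple[np.ndarray, np.ndarray]:
    growing = c0[mu > 0]
    cmax_floor = float(growing.max()) * (1 + 1e-6) if growing.size else float(c0.max())
    lo, hi = [], []
    for sym in spec.parameter_symbols:
        if sym in overrides:
            l, h = overrides[sym]
        elif sym == "mu_max":
            l, h = 1e-8, max(10.0 * float(mu.max()), 1.0)
        elif sym == "Ks":
            l, h = 1e-8, 1e4
        elif sym in ("Ki", "K"):
            l, h = 1e-8, 1e9
        elif sym == "Cmax":
            l, h = cmax_floor, 10.0 * float(c0.max())
        else:  # n, m — capped to avoid overflow-driven pseudo-fits
            l, h = (1e-6 if spec.name == "moser" else 0.0), 50.0
        lo.append(l)
        hi.append(h)
    return np.array(lo), np.array(hi)


def fit_model(
    model: str | ModelSpec,
    dataset: FlaskDataset,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit one growth model to the dataset by multi-start least squares.

    Deterministic for a given dataset and options (random starts beyond the
    deterministic grid are drawn from a seeded generator).  Raises if the
    dataset has fewer levels than parameters + 1 or if every start fails.
    """
    spec = model if isinstance(model, ModelSpec) else get_model(model)
    options = options or FitOptions()
    c0, mu = dataset.c0, dataset.mu
    if dataset.n_obs < spec.n_parameters + 1:
        raise ValueError(
            f"dataset too small: {dataset.n_obs} levels for "
            f"{spec.n_parameters}-parameter model '{spec.name}'"
        )

    lo, hi = _fit_bounds(spec, c0, mu, options.bounds_policy)
    starts = _start_grid(spec, c0, mu)
    if options.n_starts is not None:
        if options.n_starts <= len(starts):
            starts = starts[: options.n_starts]
        else:
            rng = np.random.default_rng(options.seed)
            span_lo = np.maximum(lo, 1e-6)
            span_hi = np.minimum(hi, 1e6)
            for _ in range(options.n_starts - len(starts)):
                draw = np.exp(rng.uniform(np.log(span_lo), np.log(span_hi)))
                starts.append(dict(zip(spec.parameter_symbols, draw)))

    def residual(theta: np.ndarray) -> np.ndarray:
        values = dict(zip(spec.parameter_symbols, theta))
        with np.errstate(all="ignore"):
            pred = spec.func(c0, values)
        pred = np.nan_to_num(np.maximum(pred, 0.0), nan=1e6, posinf=1e6)
        return pred - mu

    best = None
    n_used = 0
    for start in starts:
        x0 = np.clip(np.array([start[s] for s in spec.parameter_symbols]), lo, hi)
        try:
            # moderate tolerance for the exploration phase; the polish pass
            # below tightens the incumbent
            sol = least_squares(
                residual, x0, bounds=(lo, hi), method="trf",
                max_nfev=options.max_iterations, xtol=1e-10, ftol=1e-10, gtol=1e-10,
            )
        except Exception:
            continue
        n_used += 1
        sse = float(2.0 * sol.cost)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, sol)
    if best is None:
        raise RuntimeError(f"all {len(starts)} starts failed for model '{spec.name}'")

    # polish pass from the incumbent: the flat optima benefit from a restart
    try:
        sol = least_squares(
            residual, best[1].x, bounds=(lo, hi), method="trf",
            max_nfev=2 * options.max_iterations, xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        sse = float(2.0 * sol.cost)
        if sse < best[0]:
            best = (sse, sol)
    except Exception:
        pass

    sse, sol = best
    values = {s: float(v) for s, v in zip(spec.parameter_symbols, sol.x)}
    params = ParameterSet(spec.name, values)
    with np.errstate(all="ignore"):
        pred = np.maximum(spec.func(c0, values), 0.0)
    resid = mu - pred
    return FitResult(
        params=params,
        r_squared=r_squared(mu, pred),
        rmse=rmse(mu, pred),
        residuals=tuple(zip(c0.tolist(), resid.tolist())),
        converged=bool(sol.success),
        n_obs=dataset.n_obs,
        sse=sse,
        n_starts_used=n_used,
        data_hash=dataset.observation_hash(),
    )


def fit_all(
    dataset: FlaskDataset,
    models: Iterable[str] = MODEL_NAMES,
    options: FitOptions | None = None,
) -> dict[str, FitResult]:
    """Fit several models to one dataset; returns {model_name: FitResult}."""
    return {name: fit_model(name, dataset, options) for name in models}


RANK_CRITERIA = ("r2_then_rmse", "rmse_then_r2")


@dataclass(frozen=True)
class ModelRanking:
    """Fits ordered best-first under the declared criterion."""

    ranked: tuple[tuple[str, FitResult], ...]
    criterion: str

    @property
    def best(self) -> FitResult:
        return self.ranked[0][1]

    def order(self) -> list[str]:
        return [name for name, _ in self.ranked]


def rank_models(
    fits: Sequence[FitResult] | dict[str, FitResult],
    criterion: str = "r2_then_rmse",
) -> ModelRanking:
    """Rank fits of the same dataset; ties broken by fewer parameters.

    Raises if the fits do not share a dataset (checked via the observation
    hash and n_obs recorded on each fit).
    """
    if criterion not in RANK_CRITERIA:
        raise ValueError(f"criterion must be one of {RANK_CRITERIA}")
    items = list(fits.values()) if isinstance(fits, dict) else list(fits)
    if len(items) < 2:
        raise ValueError("ranking needs at least two fits")
    hashes = {(f.data_hash, f.n_obs) for f in items}
    if len(hashes) > 1:
        raise ValueError("fits come from different datasets and cannot be ranked together")

    def key(f: FitResult):
        if criterion == "r2_then_rmse":
            return (-round(f.r_squared, 12), round(f.rmse, 12), f.n_parameters, f.model_name)
        return (round(f.rmse, 12), -round(f.r_squared, 12), f.n_parameters, f.model_name)

    ordered = sorted(items, key=key)
    return ModelRanking(tuple((f.model_name, f) for f in ordered), criterion)


def fit_report(fits: dict[str, FitResult], ranking: ModelRanking | None = None) -> dict:
    """JSON-ready batch report: full precision plus 3-decimal display values."""
    out: dict = {"models": {}}
    for name, f in fits.items():
        out["models"][name] = {
            "parameters": f.params.values,
            "parameters_display": {k: round(v, 3) for k, v in f.params.values.items()},
            "r_squared": f.r_squared,
            "rmse": f.rmse,
            "converged": f.converged,
            "n_obs": f.n_obs,
        }
    if ranking is not None:
        out["ranking"] = ranking.order()
        out["criterion"] = ranking.criterion
    return out
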