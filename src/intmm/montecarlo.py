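"""Error injection and replicate simulation studies.

The study design mirrors a bench scenario: a constant-time plate is read
once per substrate concentration, the product readings carry bounded random
errors, and each perturbed plate is analysed by every estimator on the same
numbers.  Two error models are provided:

* ``relative_uniform`` -- each reading x becomes x*(1+u), u ~ U(-m, +m);
  the phrase "errors of up to m" implies a hard bound, which excludes a
  Gaussian model.
* ``absolute_uniform_of_lowest`` -- each reading gains e ~ U(-a, +a) where
  a = m times the noiseless reading at the lowest s0, emulating an assay
  whose absolute precision is set near its detection limit.

A "real v" control applies the same perturbations to true initial rates so
the spread attributable to the error model alone can be separated from the
single-time-point bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .core import KineticParameters, initial_rate
from .designs import DesignSpec, SimulatedDataset, simulate_design
from .estimators import (
    FitFailureError,
    FitResult,
    RateEstimate,
    chord_rates,
    fit_hanes_woolf,
    fit_hyperbolic,
    fit_integrated,
)

__all__ = ["ErrorModel", "MonteCarloSummary", "perturb", "perturb_rates",
           "run_study", "study_frame"]

log = logging.getLogger(__name__)

ErrorKind = Literal["relative_uniform", "absolute_uniform_of_lowest", "none"]


@dataclass(frozen=True)
class ErrorModel:
    """Bounded random measurement error.

    ``magnitude`` is the maximum fractional error (relative model) or the
    fraction of the lowest-s0 noiseless reading bounding the absolute model.
    ``target`` selects what the error perturbs: product readings (the
    observable of a single-point assay) or rates (the "real v" control).
    """

    kind: ErrorKind
    magnitude: float = 0.0
    target: Literal["product", "rate"] = "product"

    def __post_init__(self) -> None:
        if self.kind not in ("relative_uniform", "absolute_uniform_of_lowest", "none"):
            raise ValueError(f"unknown error kind {self.kind!r}")
        if self.magnitude < 0:
            raise ValueError("magnitude must be >= 0")

    @property
    def label(self) -> str:
        if self.kind == "none":
            return "none"
        pct = 100 * self.magnitude
        tag = "rel" if self.kind == "relative_uniform" else "abs_lowest"
        return f"{tag}{pct:g}%"


def _perturb_values(values: np.ndarray, model: ErrorModel,
                    rng: np.random.Generator) -> np.ndarray:
    if model.kind == "none" or model.magnitude == 0:
        return values.copy()
    u = rng.uniform(-model.magnitude, model.magnitude, size=len(values))
    if model.kind == "relative_uniform":
        return values * (1.0 + u)
    # absolute errors scaled to the reading at the lowest s0 (index 0:
    # datasets are grid-ordered ascending)
    return values + u * values[0]


def perturb(
    dataset: SimulatedDataset, model: ErrorModel, rng: Union[int, np.random.Generator]
) -> SimulatedDataset:
    """Perturbed copy of a dataset with product readings clipped to (0, s0)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = _perturb_values(dataset.p, model, rng)
    lo = 1e-12 * dataset.s0
    hi = dataset.s0 * (1 - 1e-12)
    clipped = int(np.sum((p < lo) | (p > hi)))
    if clipped:
        log.info("clipped %d perturbed reading(s) back into (0, s0)", clipped)
    return dataset.replace_p(np.clip(p, lo, hi))


def perturb_rates(
    rates: np.ndarray, model: ErrorModel, rng: Union[int, np.random.Generator]
) -> np.ndarray:
    """Perturb an ascending-s0 array of true rates (the 'real v' control)."""
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    v = _perturb_values(np.asarray(rates, dtype=float), model, rng)
    return np.clip(v, 1e-300, None)


@dataclass(frozen=True)
class MonteCarloSummary:
    """Replicate statistics for one (condition, estimator) cell."""

    fraction: Optional[float]  # None for the real-v control
    error_model: ErrorModel
    estimator: str
    n_runs: int
    n_failed: int
    range_V: Tuple[float, float]
    range_Km: Tuple[float, float]
    range_ratio: Tuple[float, float]
    largest_se_pct_V: float
    largest_se_pct_Km: float
    mean_V: float
    sd_V: float
    mean_Km: float
    sd_Km: float

    @property
    def condition(self) -> str:
        f = "real_v" if self.fraction is None else f"f={self.fraction:g}"
        return f"{f}/{self.error_model.label}/{self.estimator}"


_ESTIMATORS = {
    "hanes_woolf": lambda ds: fit_hanes_woolf(chord_rates(ds.measurements)),
    "hyperbolic": lambda ds: fit_hyperbolic(chord_rates(ds.measurements)),
    "integrated": lambda ds: fit_integrated(ds.measurements),
}


def _summarise(fraction, model, name, fits: List[FitResult], n_runs: int) -> MonteCarloSummary:
    V = np.array([f.V_hat for f in fits])
    Km = np.array([f.Km_hat for f in fits])
    ratio = V / Km
    seV = np.array([100 * f.se_V / f.V_hat for f in fits])
    seK = np.array([100 * f.se_Km / f.Km_hat for f in fits])
    return MonteCarloSummary(
        fraction=fraction,
        error_model=model,
        estimator=name,
        n_runs=n_runs,
        n_failed=n_runs - len(fits),
        range_V=(float(V.min()), float(V.max())),
        range_Km=(float(Km.min()), float(Km.max())),
        range_ratio=(float(ratio.min()), float(ratio.max())),
        largest_se_pct_V=float(seV.max()),
        largest_se_pct_Km=float(seK.max()),
        mean_V=float(V.mean()),
        sd_V=float(V.std(ddof=1)) if len(V) > 1 else 0.0,
        mean_Km=float(Km.mean()),
        sd_Km=float(Km.std(ddof=1)) if len(Km) > 1 else 0.0,
    )


def run_study(
    params: KineticParameters,
    fractions: Sequence[float] = (0.10, 0.30, 0.60),
    error_models: Sequence[ErrorModel] = (
        ErrorModel("relative_uniform", 0.05),
        ErrorModel("relative_uniform", 0.10),
        ErrorModel("absolute_uniform_of_lowest", 0.20),
    ),
    estimators: Sequence[str] = ("hanes_woolf", "integrated"),
    s0_grid: Optional[Sequence[float]] = None,
    n_runs: int = 18,
    seed: Optional[int] = None,
    include_real_v: bool = True,
    real_v_time: float = 1e-3,
    strategy: str = "constant_time",
) -> List[MonteCarloSummary]:
    """Replicate study over conversion fractions x error models x estimators.

    Each run perturbs one simulated constant-time plate and hands the same
    perturbed numbers to every estimator, so estimator contrasts are paired.
    The real-v control analyses perturbed true initial rates with the
    rate-based estimators and, for the integrated estimator, a plate sampled
    at a very short shared time (``real_v_time``) where [P]/t is effectively
    the initial rate.  Per-run fit failures are counted and excluded, never
    silently dropped.  Seeding: one root seed spawns one independent
    substream per (condition, run), so adding estimators does not reshuffle
    the noise.
    """
    from .designs import default_grid

    grid = tuple(default_grid() if s0_grid is None else s0_grid)
    root = np.random.SeedSequence(seed)
    conditions: List[Optional[float]] = ([None] if include_real_v else []) + list(fractions)
    summaries: List[MonteCarloSummary] = []
    children = iter(root.spawn(len(conditions) * len(error_models) * n_runs))

    for fraction in conditions:
        for model in error_models:
            fits: dict = {name: [] for name in estimators}
            run_seeds = [next(children) for _ in range(n_runs)]
            for child in run_seeds:
                rng = np.random.default_rng(child)
                if fraction is None:
                    _run_real_v(params, grid, model, rng, estimators, fits,
                                real_v_time, strategy)
                else:
                    spec = DesignSpec(strategy, grid, fraction, params)
                    ds = perturb(simulate_design(spec),
                                 ErrorModel(model.kind, model.magnitude, "product"), rng)
                    for name in estimators:
                        try:
                            fits[name].append(_ESTIMATORS[name](ds))
                        except FitFailureError as exc:
                            log.warning("fit failure (%s, f=%s): %s", name, fraction, exc)
            for name in estimators:
                if fits[name]:
                    summaries.append(_summarise(fraction, model, name, fits[name], n_runs))
    return summaries


def _run_real_v(params, grid, model, rng, estimators, fits, real_v_time, strategy):
    """One run of the real-v control; consumes the same rng across estimators."""
    v_true = initial_rate(params, np.array(grid))
    v_pert = perturb_rates(v_true, ErrorModel(model.kind, model.magnitude, "rate"), rng)
    rates = [RateEstimate(s0=float(s), v_hat=float(v), method="true")
             for s, v in zip(grid, v_pert)]
    for name in estimators:
        try:
            if name == "hanes_woolf":
                fits[name].append(fit_hanes_woolf(rates))
            elif name == "hyperbolic":
                fits[name].append(fit_hyperbolic(rates))
            elif name == "integrated":
                # short-time plate: [P]/t == v to first order
                from .core import Measurement, product_at_time
                p = product_at_time(params, np.array(grid), real_v_time)
                ds = SimulatedDataset(
                    DesignSpec(strategy, tuple(grid), 0.5, params),
                    tuple(Measurement(float(s), real_v_time, float(pi))
                          for s, pi in zip(grid, p)),
                    t_star=real_v_time,
                )
                ds = perturb(ds, ErrorModel(model.kind, model.magnitude, "product"), rng)
                fits[name].append(fit_integrated(ds.measurements))
        except FitFailureError as exc:
            log.warning("fit failure (real v, %s): %s", name, exc)


def study_frame(summaries: Sequence[MonteCarloSummary]) -> pd.DataFrame:
    """Tidy table: one row per condition x estimator, columns mirroring the
    range / largest-SE / mean +- SD replicate summary."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "condition": "real_v" if s.fraction is None else s.fraction,
                "error_model": s.error_model.label,
                "estimator": s.estimator,
                "n_runs": s.n_runs,
                "n_failed": s.n_failed,
                "V_min": s.range_V[0],
                "V_max": s.range_V[1],
                "Km_min": s.range_Km[0],
                "Km_max": s.range_Km[1],
                "ratio_min": s.range_ratio[0],
                "ratio_max": s.range_ratio[1],
                "largest_se_pct_V": s.largest_se_pct_V,
                "largest_se_pct_Km": s.largest_se_pct_Km,
                "mean_V": s.mean_V,
                "sd_V": s.sd_V,
                "mean_Km": s.mean_Km,
                "sd_Km": s.sd_Km,
            }
        )
    return pd.DataFrame(rows)
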