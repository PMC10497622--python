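"""Single-time-point sampling plans and the noiseless datasets they imply.

Two strategies are supported:

* ``constant_conversion`` -- each initial substrate concentration is sampled
  at the time where the same fraction of substrate has been converted, so
  times grow with [S]0.
* ``constant_time`` -- all concentrations are sampled at one shared reaction
  time, chosen so that the lowest [S]0 reaches a target conversion; the
  realised conversion then decreases with increasing [S]0.

The constant-time plan is the experimentally convenient one (one clock for
the whole plate); the bias it induces when [P]/t is mistaken for an initial
rate is quantified in :mod:`intmm.estimators`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (
    ConversionFraction,
    DomainError,
    KineticParameters,
    Measurement,
    product_at_time,
    time_to_product,
)

__all__ = [
    "Strategy",
    "DesignSpec",
    "SimulatedDataset",
    "default_grid",
    "below_km_grid",
    "above_km_grid",
    "grid_by_name",
    "simulate_design",
]

Strategy = Literal["constant_conversion", "constant_time"]


def default_grid(scale: float = 1.0) -> np.ndarray:
    """Seven-point [S]0 grid spanning 0.35-2.45 in units of Km.

    ``scale`` maps the Km-unit grid onto physical concentrations (e.g. a Km
    of 29 uM gives a grid in uM with ``scale=29``).
    """
    return scale * np.arange(1, 8) * 0.35


def below_km_grid(scale: float = 1.0) -> np.ndarray:
    """Five-point grid entirely below Km: 0.07-0.35 in steps of 0.07 Km."""
    return scale * np.arange(1, 6) * 0.07


def above_km_grid(scale: float = 1.0) -> np.ndarray:
    """Six-point grid entirely above Km: 1.4-8.4 in steps of 1.4 Km."""
    return scale * np.arange(1, 7) * 1.4


_GRIDS = {"default": default_grid, "below_km": below_km_grid, "above_km": above_km_grid}


def grid_by_name(name: str, scale: float = 1.0) -> np.ndarray:
    try:
        return _GRIDS[name](scale)
    except KeyError:
        raise KeyError(f"unknown grid {name!r}; choose from {sorted(_GRIDS)}") from None


@dataclass(frozen=True)
class DesignSpec:
    """A single-time-point sampling plan.

    ``target_fraction`` is the substrate conversion imposed at every [S]0
    (constant_conversion) or at the lowest [S]0 only (constant_time).
    """

    strategy: Strategy
    s0_grid: Tuple[float, ...]
    target_fraction: float
    params: KineticParameters

    def __post_init__(self) -> None:
        if self.strategy not in ("constant_conversion", "constant_time"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        grid = tuple(float(s) for s in self.s0_grid)
        if len(grid) == 0:
            raise ValueError("s0_grid must be non-empty")
        if any(s <= 0 for s in grid):
            raise ValueError("s0_grid values must be positive")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("s0_grid must be strictly ascending")
        object.__setattr__(self, "s0_grid", grid)
        f = float(self.target_fraction)
        if not (0 < f < 1):
            raise ValueError(f"target_fraction must be in (0, 1), got {f}")
        object.__setattr__(self, "target_fraction", f)

    def with_params(self, params: KineticParameters) -> "DesignSpec":
        return DesignSpec(self.strategy, self.s0_grid, self.target_fraction, params)


@dataclass(frozen=True)
class SimulatedDataset:
    """Noiseless measurements implied by a design (one per [S]0)."""

    design: DesignSpec
    measurements: Tuple[Measurement, ...]
    t_star: Optional[float] = None  # shared time for constant_time designs

    @property
    def s0(self) -> np.ndarray:
        return np.array([m.s0 for m in self.measurements])

    @property
    def t(self) -> np.ndarray:
        return np.array([m.t for m in self.measurements])

    @property
    def p(self) -> np.ndarray:
        return np.array([m.p for m in self.measurements])

    @property
    def conversions(self) -> np.ndarray:
        return self.p / self.s0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "s0": self.s0,
                "t": self.t,
                "p": self.p,
                "replicate": [m.replicate for m in self.measurements],
            }
        )

    def replace_p(self, p_new: Sequence[float]) -> "SimulatedDataset":
        """Copy with new product readings (used by error injection)."""
        ms = tuple(
            Measurement(m.s0, m.t, float(p), m.replicate)
            for m, p in zip(self.measurements, p_new)
        )
        return SimulatedDataset(self.design, ms, self.t_star)


def simulate_design(spec: DesignSpec) -> SimulatedDataset:
    """Generate the exact dataset a design prescribes.

    constant_conversion: p = f * s0 at each s0, t from the integrated equation.
    constant_time: the shared time t* is the time to reach fraction f at the
    lowest s0; every other p follows from the Lambert-W inversion at t*.
    """
    grid = np.array(spec.s0_grid)
    f = spec.target_fraction
    if spec.strategy == "constant_conversion":
        p = f * grid
        t = time_to_product(spec.params, grid, p)
        ms = tuple(Measurement(float(s), float(ti), float(pi)) for s, ti, pi in zip(grid, t, p))
        return SimulatedDataset(spec, ms, t_star=None)
    # constant_time, anchored at the lowest s0
    s0_min = grid[0]
    t_star = float(time_to_product(spec.params, s0_min, f * s0_min))
    p = np.atleast_1d(product_at_time(spec.params, grid, t_star))
    ms = tuple(Measurement(float(s), t_star, float(pi)) for s, pi in zip(grid, p))
    return SimulatedDataset(spec, ms, t_star=t_star)
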