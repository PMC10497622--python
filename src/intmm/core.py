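"""Exact forward and inverse solutions of the irreversible single-substrate
Henri-Michaelis-Menten (HMM) system.

The model is the classical hyperbola for the initial rate,

    v = V * [S]0 / (Km + [S]0),

together with its integrated form for an irreversible, uninhibited reaction
with [E]0 << [S]0,

    t = [P]/V + (Km/V) * ln([S]0 / ([S]0 - [P])),

which gives the time needed to accumulate product concentration [P] starting
from substrate concentration [S]0.  The inverse problem -- product at a given
time -- has a closed form through the Lambert W function (the Schnell-Mendoza
substrate-depletion solution):

    [S](t) = Km * W((S0/Km) * exp((S0 - V t)/Km)),    [P](t) = S0 - [S](t).

All quantities are carried in arbitrary, self-consistent units; unit strings
on :class:`KineticParameters` are labels only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import wrightomega

__all__ = [
    "DomainError",
    "InvalidParametersError",
    "KineticParameters",
    "Measurement",
    "ConversionFraction",
    "initial_rate",
    "time_to_product",
    "product_at_time",
    "product_at_time_bisect",
    "conversion",
    "round_sig",
]

_REL_TOL = 1e-12  # consistency tolerance for derived parameters


class InvalidParametersError(ValueError):
    """Kinetic parameters violate positivity or internal consistency."""


class DomainError(ValueError):
    """An argument lies outside the physically meaningful domain."""


@dataclass(frozen=True)
class KineticParameters:
    """True or fitted kinetic parameters of an enzyme-substrate pair.

    Parameters
    ----------
    V : float
        Limiting (maximum) rate, ``V = kcat * E0`` (concentration/time).
    Km : float
        Michaelis constant: substrate concentration at which v = V/2.
    E0 : float, optional
        Total enzyme concentration.  When given, ``kcat`` is derived.
    kcat : float, optional
        Turnover number (1/time).  Must equal ``V / E0`` when both are given.
    specificity : float, optional
        Specificity constant ``V / Km`` (1/time); derived when omitted.
    conc_unit, time_unit : str
        Unit labels carried as metadata; no conversion is performed.
    """

    V: float
    Km: float
    E0: Optional[float] = None
    kcat: Optional[float] = None
    specificity: Optional[float] = None
    conc_unit: str = "arb"
    time_unit: str = "arb"

    def __post_init__(self) -> None:
        if not (self.V > 0 and math.isfinite(self.V)):
            raise InvalidParametersError(f"V must be positive and finite, got {self.V}")
        if not (self.Km > 0 and math.isfinite(self.Km)):
            raise InvalidParametersError(f"Km must be positive and finite, got {self.Km}")
        if self.E0 is not None:
            if self.E0 <= 0:
                raise InvalidParametersError(f"E0 must be positive, got {self.E0}")
            derived_kcat = self.V / self.E0
            if self.kcat is None:
                object.__setattr__(self, "kcat", derived_kcat)
            elif abs(self.kcat - derived_kcat) > _REL_TOL * abs(derived_kcat):
                raise InvalidParametersError(
                    f"kcat={self.kcat} inconsistent with V/E0={derived_kcat}"
                )
        elif self.kcat is not None:
            raise InvalidParametersError("kcat given without E0")
        derived_spec = self.V / self.Km
        if self.specificity is None:
            object.__setattr__(self, "specificity", derived_spec)
        elif abs(self.specificity - derived_spec) > _REL_TOL * abs(derived_spec):
            raise InvalidParametersError(
                f"specificity={self.specificity} inconsistent with V/Km={derived_spec}"
            )


@dataclass(frozen=True)
class Measurement:
    """One observation: product concentration ``p`` reached at time ``t``
    starting from initial substrate concentration ``s0``."""

    s0: float
    t: float
    p: float
    replicate: Optional[int] = None

    def __post_init__(self) -> None:
        if not (self.s0 > 0 and math.isfinite(self.s0)):
            raise DomainError(f"s0 must be positive, got {self.s0}")
        if self.t < 0 or not math.isfinite(self.t):
            raise DomainError(f"t must be non-negative, got {self.t}")
        if not (0 <= self.p < self.s0):
            raise DomainError(f"p must satisfy 0 <= p < s0, got p={self.p}, s0={self.s0}")
        if self.t == 0 and self.p != 0:
            raise DomainError("p must be 0 at t = 0")


@dataclass(frozen=True)
class ConversionFraction:
    """Dimensionless fraction of substrate converted, f = p / s0."""

    f: float

    def __post_init__(self) -> None:
        if not (0 <= self.f < 1):
            raise DomainError(f"conversion fraction must be in [0, 1), got {self.f}")

    def __float__(self) -> float:
        return float(self.f)

    @property
    def percent(self) -> float:
        return 100.0 * self.f


def initial_rate(params: KineticParameters, s0):
    """Initial (steady-state) rate v = V*s0/(Km+s0) at substrate concentration s0.

    Accepts a scalar or array ``s0 >= 0``; 0 substrate gives 0 rate.
    """
    s0 = np.asarray(s0, dtype=float)
    if np.any(s0 < 0):
        raise DomainError("s0 must be non-negative")
    v = params.V * s0 / (params.Km + s0)
    return float(v) if v.ndim == 0 else v


def time_to_product(params: KineticParameters, s0, p):
    """Time at which product concentration ``p`` is reached (integrated HMM form).

    t = p/V + (Km/V) * ln(s0 / (s0 - p)); strictly increasing in p, 0 at p = 0.
    """
    s0 = np.asarray(s0, dtype=float)
    p = np.asarray(p, dtype=float)
    if np.any(s0 <= 0):
        raise DomainError("s0 must be positive")
    if np.any(p < 0):
        raise DomainError("p must be non-negative")
    if np.any(p >= s0):
        raise DomainError("p must be below s0: the reaction cannot exceed completion")
    t = p / params.V + (params.Km / params.V) * np.log(s0 / (s0 - p))
    return float(t) if t.ndim == 0 else t


def product_at_time(params: KineticParameters, s0, t):
    """Product concentration at time ``t`` (closed-form Lambert-W inversion).

    Evaluates [S](t) = Km * W((s0/Km) exp((s0 - V t)/Km)) on the principal
    branch and returns p = s0 - [S](t).  The argument of W is always positive,
    so the principal branch is the physical one; the evaluation goes through
    the Wright omega function, W(e^z) = omega(z), which stays stable when
    s0 >> Km or V*t is large and exp() alone would overflow.
    """
    s0 = np.asarray(s0, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(s0 <= 0):
        raise DomainError("s0 must be positive")
    if np.any(t < 0):
        raise DomainError("t must be non-negative")
    z = np.log(s0 / params.Km) + (s0 - params.V * t) / params.Km
    s = params.Km * wrightomega(z).real
    p = np.clip(s0 - s, 0.0, s0)
    return float(p) if p.ndim == 0 else p


def product_at_time_bisect(
    params: KineticParameters, s0: float, t: float, tol: float = 1e-14
) -> float:
    """Invert the integrated equation by bracketing bisection.

    Independent of the Lambert-W route: it only uses the forward map
    :func:`time_to_product`, monotone in p, bisected on [0, s0*(1 - 1e-15)].
    Kept as a slow, transparent oracle for the closed form.
    """
    if t < 0:
        raise DomainError("t must be non-negative")
    if t == 0:
        return 0.0
    lo, hi = 0.0, s0 * (1.0 - 1e-15)
    if time_to_product(params, s0, hi) <= t:
        return hi
    while hi - lo > tol * s0:
        mid = 0.5 * (lo + hi)
        if time_to_product(params, s0, mid) < t:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def conversion(m: Measurement) -> ConversionFraction:
    """Fraction of substrate converted in a measurement, f = p / s0."""
    return ConversionFraction(m.p / m.s0)


def round_sig(x, digits: int = 3):
    """Round to ``digits`` significant figures (scalar or array).

    Used to emulate the hand-tabulation convention of carrying chord rates at
    3 significant digits, which perturbs fitted parameters in the third
    decimal place.
    """

    def _one(v: float) -> float:
        if v == 0 or not math.isfinite(v):
            return v
        return round(v, digits - 1 - int(math.floor(math.log10(abs(v)))))

    if np.ndim(x) == 0:
        return _one(float(x))
    flat = [_one(float(v)) for v in np.ravel(np.asarray(x, dtype=float))]
    return np.array(flat).reshape(np.shape(x))
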