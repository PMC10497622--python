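"""File formats, the synthetic progress-curve fixture, and dead-time
preprocessing of monitored time courses.

Measurement tables are plain CSV with header ``s0,t,p,replicate,label`` and
``#``-prefixed metadata lines carrying unit labels.  Time courses are CSV
with columns ``t,signal`` plus metadata (nominal s0, signal-to-concentration
factor).  No instrument-vendor formats are read.

The fixture generator emulates a chromogenic beta-lactamase assay: nitrocefin
hydrolysis monitored photometrically at a few readings per second, with a
mixing dead time of several seconds between reaction start and the first
usable reading.  Because the first reading then already contains product, the
effective initial substrate concentration is recovered as (final reading -
first reading) once the reaction has run to completion.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import DomainError, KineticParameters, Measurement, product_at_time, time_to_product

__all__ = [
    "IncompleteReactionError",
    "MeasurementTable",
    "TimeCourse",
    "read_measurements",
    "write_measurements",
    "read_time_course",
    "write_time_course",
    "preprocess_time_course",
    "generate_fixture",
    "write_manifest",
]

MEASUREMENT_COLUMNS = ["s0", "t", "p", "replicate", "label"]


class IncompleteReactionError(ValueError):
    """A time course shows no final plateau, so s0 cannot be inferred."""


@dataclass
class MeasurementTable:
    """Rows of (s0, t, p, replicate, label) plus unit metadata."""

    frame: pd.DataFrame
    units: Dict[str, str] = field(default_factory=lambda: {"conc_unit": "arb", "time_unit": "arb"})

    def __post_init__(self) -> None:
        df = self.frame.copy()
        for col in MEASUREMENT_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df = df[MEASUREMENT_COLUMNS]
        # stable dtypes so a write-read cycle is value-identical
        for col in ("s0", "t", "p", "replicate"):
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        df["label"] = df["label"].fillna("").astype(str)
        bad = df[(df.s0 <= 0) | (df.t < 0) | (df.p < 0) | (df.p >= df.s0)]
        if len(bad):
            raise DomainError(
                f"{len(bad)} row(s) violate 0 <= p < s0 and t >= 0; first bad row index: "
                f"{bad.index[0]}"
            )
        self.frame = df

    @classmethod
    def from_measurements(
        cls, measurements: Sequence[Measurement], label: str = "",
        units: Optional[Dict[str, str]] = None,
    ) -> "MeasurementTable":
        df = pd.DataFrame(
            {
                "s0": [m.s0 for m in measurements],
                "t": [m.t for m in measurements],
                "p": [m.p for m in measurements],
                "replicate": [m.replicate for m in measurements],
                "label": label,
            }
        )
        return cls(df, units or {"conc_unit": "arb", "time_unit": "arb"})

    def to_measurements(self) -> List[Measurement]:
        out = []
        for _, row in self.frame.iterrows():
            rep = None if pd.isna(row.replicate) else int(row.replicate)
            out.append(Measurement(float(row.s0), float(row.t), float(row.p), rep))
        return out

    def to_csv(self, path: Union[str, Path]) -> None:
        write_measurements(path, self)

    @classmethod
    def read_csv(cls, path: Union[str, Path]) -> "MeasurementTable":
        return read_measurements(path)


def _read_hash_metadata(path: Path) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
    return meta


def write_measurements(path: Union[str, Path], table: MeasurementTable) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, val in table.units.items():
            fh.write(f"# {key}: {val}\n")
        table.frame.to_csv(fh, index=False)


def read_measurements(path: Union[str, Path]) -> MeasurementTable:
    path = Path(path)
    meta = _read_hash_metadata(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # malformed CSV: surface a parse error with context
        raise DomainError(f"cannot parse measurement CSV {path}: {exc}") from exc
    missing = [c for c in ("s0", "t", "p") if c not in df.columns]
    if missing:
        raise DomainError(f"measurement CSV {path} lacks column(s) {missing}")
    units = {k: v for k, v in meta.items()} or {"conc_unit": "arb", "time_unit": "arb"}
    return MeasurementTable(df, units)


@dataclass
class TimeCourse:
    """A monitored reaction: recorded times (s) and product-proportional signal."""

    s0_nominal: float
    t: np.ndarray
    signal: np.ndarray
    signal_to_conc: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t.shape != self.signal.shape or self.t.ndim != 1:
            raise ValueError("t and signal must be 1-D arrays of equal length")
        if len(self.t) < 3:
            raise ValueError("time course needs at least 3 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")

    @property
    def concentration(self) -> np.ndarray:
        return self.signal * self.signal_to_conc


def write_time_course(path: Union[str, Path], tc: TimeCourse) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# s0_nominal: {tc.s0_nominal!r}\n")
        fh.write(f"# signal_to_conc: {tc.signal_to_conc!r}\n")
        if tc.label:
            fh.write(f"# label: {tc.label}\n")
        pd.DataFrame({"t": tc.t, "signal": tc.signal}).to_csv(fh, index=False)


def read_time_course(path: Union[str, Path]) -> TimeCourse:
    path = Path(path)
    meta = _read_hash_metadata(path)
    df = pd.read_csv(path, comment="#")
    if "t" not in df.columns or "signal" not in df.columns:
        raise DomainError(f"time-course CSV {path} must have columns t,signal")
    return TimeCourse(
        s0_nominal=float(meta.get("s0_nominal", "nan")),
        t=df.t.to_numpy(),
        signal=df.signal.to_numpy(),
        signal_to_conc=float(meta.get("signal_to_conc", 1.0)),
        label=meta.get("label", ""),
    )


def preprocess_time_course(
    tc: TimeCourse,
    target_fraction: Optional[float] = None,
    target_time: Optional[float] = None,
    plateau_tol: float = 0.02,
) -> Measurement:
    """Reduce a monitored time course to one single-point measurement.

    The effective initial substrate concentration at the first usable reading
    is the final reading minus the first (the reaction must have reached a
    plateau); product and time are measured relative to that first reading.
    One point is then selected: the first reading at or past
    ``target_fraction`` of the effective s0, or the reading nearest
    ``target_time`` (seconds after the first reading).

    Raises :class:`IncompleteReactionError` when the final readings still
    trend upward: the last ~10% of points are split in half and the halves'
    means must agree within ``plateau_tol`` of the effective amplitude (a
    trend test rather than a raw spread, so point noise does not mask a
    genuine plateau).
    """
    if (target_fraction is None) == (target_time is None):
        raise ValueError("give exactly one of target_fraction or target_time")
    conc = tc.concentration
    s0_eff = float(conc[-1] - conc[0])
    if s0_eff <= 0:
        raise IncompleteReactionError("no signal increase: nothing was converted")
    tail = conc[-max(4, len(conc) // 10):]
    half = len(tail) // 2
    drift = float(np.mean(tail[half:]) - np.mean(tail[:half]))
    if abs(drift) > plateau_tol * s0_eff:
        raise IncompleteReactionError(
            f"final readings still drift by {drift:.3g} (> {plateau_tol:.0%} of the "
            f"effective s0 {s0_eff:.3g}); the reaction looks incomplete"
        )
    p = conc - conc[0]
    t_rel = tc.t - tc.t[0]
    if target_fraction is not None:
        idx_candidates = np.nonzero((p >= target_fraction * s0_eff) & (t_rel > 0))[0]
        if len(idx_candidates) == 0:
            raise IncompleteReactionError(
                f"curve never reaches {target_fraction:.0%} of the effective s0"
            )
        idx = int(idx_candidates[0])
    else:
        idx = int(np.argmin(np.abs(t_rel - target_time)))
        if t_rel[idx] <= 0:
            idx = 1
    p_sel = float(min(p[idx], s0_eff * (1 - 1e-9)))
    return Measurement(s0=s0_eff, t=float(t_rel[idx]), p=max(p_sel, 0.0))


def generate_fixture(
    params: Optional[KineticParameters] = None,
    s0_list: Sequence[float] = (11.0, 24.0, 37.0, 50.0, 64.0),
    dead_time: float = 7.5,
    readings_per_s: float = 2.0,
    duration: Optional[float] = None,
    noise_sd: float = 0.15,
    seed: Optional[int] = None,
) -> List[TimeCourse]:
    """Synthetic nitrocefin-like progress curves for end-to-end testing.

    Defaults emulate a class C beta-lactamase hydrolysing nitrocefin:
    V = 33 uM/min, Km = 29 uM, substrate 11-64 uM, photometric readings
    2 per second, a mixing dead time of 7.5 s, and additive Gaussian signal
    noise (sd in uM-equivalent units).  Times inside each returned course are
    seconds relative to the first reading; product formed during the dead
    time is present in the first reading, exactly as in a real stopped-start
    assay.  ``duration=None`` extends each recording until 99.9% conversion
    so the plateau needed by :func:`preprocess_time_course` exists.
    """
    if params is None:
        params = KineticParameters(V=33.0, Km=29.0, conc_unit="uM", time_unit="min")
    v_per_s = params.V / 60.0 if params.time_unit == "min" else params.V
    per_s = KineticParameters(V=v_per_s, Km=params.Km, conc_unit=params.conc_unit,
                              time_unit="s")
    rng = np.random.default_rng(seed)
    out = []
    for s0 in s0_list:
        if duration is None:
            t_end = time_to_product(per_s, s0, 0.999 * s0) + 5.0
        else:
            t_end = duration
        n = int(math.floor(t_end * readings_per_s)) + 1
        t_abs = dead_time + np.arange(n) / readings_per_s
        p_true = product_at_time(per_s, s0, t_abs)
        signal = p_true + rng.normal(0.0, noise_sd, size=n)
        out.append(
            TimeCourse(
                s0_nominal=float(s0),
                t=t_abs - dead_time,
                signal=signal,
                signal_to_conc=1.0,
                label=f"s0={s0:g}",
            )
        )
    return out


def write_manifest(path: Union[str, Path], config: dict) -> None:
    """Write a JSON run manifest (config, seed, package version) next to outputs."""
    from . import __version__

    payload = {"package": "intmm", "version": __version__, **config}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
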