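"""File I/O and curve-set containers.

CSV dialects:

* curves: header ``time_s,aif,seg_01,...,seg_16``, one row per frame;
* T1 samples: ``segment,timepoint,r1_blood_per_s,r1_tissue_per_s``;
* cohort tables: snake_case subject-level columns.

All readers validate schema up front and raise
:class:`~cmrquant.exceptions.SchemaError` with line numbers where possible,
so malformed inputs fail before any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import aha
from .exceptions import InvalidParameterError, SchemaError
from .signal_model import TimeSeriesCurve

__all__ = [
    "SegmentalCurveSet",
    "CURVE_COLUMNS",
    "read_curves",
    "write_curves",
    "read_t1_samples",
    "write_t1_samples",
    "read_cohort",
    "resample_to_grid",
]

CURVE_COLUMNS = ["time_s", "aif"] + [f"seg_{s:02d}" for s in aha.SEGMENTS]

T1_COLUMNS = ["segment", "timepoint", "r1_blood_per_s", "r1_tissue_per_s"]


@dataclass
class SegmentalCurveSet:
    """The arterial input plus the 16 AHA segmental curves on one time grid."""

    times: np.ndarray
    aif: np.ndarray
    segments: dict[int, np.ndarray]
    kind: str = "signal"

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.aif = np.asarray(self.aif, dtype=float)
        self.segments = {int(k): np.asarray(v, dtype=float) for k, v in self.segments.items()}
        if sorted(self.segments) != list(aha.SEGMENTS):
            raise SchemaError(
                f"expected segments 1..16, got {sorted(self.segments)}"
            )
        n = self.times.size
        if self.aif.size != n or any(v.size != n for v in self.segments.values()):
            raise SchemaError("all curves must share the time grid length")
        if np.any(np.diff(self.times) <= 0):
            raise SchemaError("time grid must be strictly increasing")

    def aif_curve(self) -> TimeSeriesCurve:
        return TimeSeriesCurve(self.times, self.aif, kind=self.kind, label="aif")

    def segment_curve(self, segment: int) -> TimeSeriesCurve:
        return TimeSeriesCurve(
            self.times, self.segments[segment], kind=self.kind, label=f"seg_{segment:02d}"
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"time_s": self.times, "aif": self.aif}
        for s in aha.SEGMENTS:
            data[f"seg_{s:02d}"] = self.segments[s]
        return pd.DataFrame(data)


def read_curves(path, kind: str = "signal") -> SegmentalCurveSet:
    """Read a segmental curve CSV, validating the dialect strictly."""
    df = pd.read_csv(path)
    missing = [c for c in CURVE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.isna().any().any():
        rows = (df.isna().any(axis=1)).to_numpy().nonzero()[0]
        # +2: one for the header line, one for 1-based file lines
        raise SchemaError(f"{path}: NaN values at file lines {[int(r) + 2 for r in rows[:10]]}")
    t = df["time_s"].to_numpy(dtype=float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if bad.size:
        raise SchemaError(
            f"{path}: time_s not strictly increasing at file line {int(bad[0]) + 3}"
        )
    return SegmentalCurveSet(
        times=t,
        aif=df["aif"].to_numpy(dtype=float),
        segments={s: df[f"seg_{s:02d}"].to_numpy(dtype=float) for s in aha.SEGMENTS},
        kind=kind,
    )


def write_curves(path, curves: SegmentalCurveSet) -> None:
    curves.to_frame().to_csv(path, index=False)


def read_t1_samples(path) -> pd.DataFrame:
    """Read per-segment R1 triplets (pre / 10 min / 20 min)."""
    df = pd.read_csv(path)
    missing = [c for c in T1_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df[["r1_blood_per_s", "r1_tissue_per_s"]].isna().any().any():
        raise SchemaError(f"{path}: NaN R1 values")
    if (df[["r1_blood_per_s", "r1_tissue_per_s"]] <= 0).any().any():
        raise SchemaError(f"{path}: R1 values must be positive")
    return df


def write_t1_samples(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, columns=T1_COLUMNS)


def read_cohort(path, required: tuple[str, ...] = ()) -> pd.DataFrame:
    """Read a subject-level cohort table, checking required columns."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing cohort columns {missing}")
    return df


def resample_to_grid(curve: TimeSeriesCurve, target_times) -> TimeSeriesCurve:
    """Linearly interpolate a curve onto a new grid inside the observed span.

    Extrapolation is refused: the target grid must lie within
    ``[times[0], times[-1]]``.
    """
    target = np.asarray(target_times, dtype=float)
    if target.size == 0:
        raise InvalidParameterError("target grid is empty")
    if target[0] < curve.times[0] - 1e-12 or target[-1] > curve.times[-1] + 1e-12:
        raise InvalidParameterError(
            "target grid requires extrapolation outside the observed time span"
        )
    values = np.interp(target, curve.times, curve.values)
    return TimeSeriesCurve(target, values, kind=curve.kind, label=curve.label)
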