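"""Partition coefficient and extracellular volume from multi-timepoint T1.

With T1 maps acquired pre-contrast and at two post-contrast delays, the
gadolinium partition coefficient of a myocardial segment is the slope of
tissue R1 regressed on blood R1 across the timepoints,

    R1_tissue = intercept + lambda_Gd * R1_blood,

and the extracellular volume fraction follows as

    ECV = (1 - Hct) * lambda_Gd.

Using three timepoints rather than the pre/post pair lowers the variance
of the slope estimate. ECV is carried internally as a fraction and
rendered as percent in reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDesignError, InvalidParameterError

__all__ = [
    "T1Sample",
    "SegmentECV",
    "partition_coefficient",
    "ecv_from_lambda",
    "global_ecv",
    "quantify_segment_ecv",
]

TIMEPOINTS = ("pre", "post10", "post20")


@dataclass(frozen=True)
class T1Sample:
    """One (blood R1, tissue R1) pair for a segment at one timepoint."""

    timepoint: str
    r1_blood: float
    r1_tissue: float
    segment: int = 0

    def __post_init__(self):
        if self.r1_blood <= 0 or self.r1_tissue <= 0:
            raise InvalidParameterError("R1 values must be positive")


@dataclass
class SegmentECV:
    segment: int
    lambda_gd: float
    intercept: float
    ecv: float  # fraction
    hct: float


def partition_coefficient(samples) -> tuple[float, float]:
    """OLS slope and intercept of tissue R1 on blood R1.

    Requires at least two samples with distinct blood R1; all blood R1
    equal is a degenerate design.
    """
    samples = list(samples)
    if len(samples) < 2:
        raise DegenerateDesignError("need at least 2 timepoints for the regression")
    x = np.array([s.r1_blood for s in samples], dtype=float)
    y = np.array([s.r1_tissue for s in samples], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all blood R1 values are equal; slope undefined")
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def ecv_from_lambda(lambda_gd: float, hct: float) -> float:
    """ECV fraction = (1 - Hct) * lambda_Gd."""
    if not 0.0 <= hct < 1.0:
        raise InvalidParameterError(f"hematocrit must be in [0, 1), got {hct}")
    return (1.0 - hct) * lambda_gd


def global_ecv(segment_ecvs) -> float:
    """Unweighted mean ECV over the available segments (fractions in, fraction out)."""
    vals = np.asarray(list(segment_ecvs), dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise InvalidParameterError("no valid segmental ECV values")
    return float(np.mean(vals))


def quantify_segment_ecv(t1_table: pd.DataFrame, hct: float) -> tuple[list[SegmentECV], float, list[str]]:
    """Per-segment lambda/ECV from a T1-sample table plus the global mean.

    The table follows the T1 CSV dialect (``segment, timepoint,
    r1_blood_per_s, r1_tissue_per_s``). Segments whose regression fails are
    skipped with a warning record; the global ECV averages the rest.
    """
    results, warnings = [], []
    for seg, grp in t1_table.groupby("segment"):
        samples = [
            T1Sample(row.timepoint, row.r1_blood_per_s, row.r1_tissue_per_s, int(seg))
            for row in grp.itertuples()
        ]
        try:
            lam, intercept = partition_coefficient(samples)
            ecv = ecv_from_lambda(lam, hct)
        except (DegenerateDesignError, InvalidParameterError) as exc:
            warnings.append(f"segment {seg}: {exc}")
            continue
        results.append(SegmentECV(int(seg), lam, intercept, ecv, hct))
    if not results:
        raise DegenerateDesignError("no segment produced a partition coefficient")
    gecv = global_ecv([r.ecv for r in results])
    return results, gecv, warnings
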