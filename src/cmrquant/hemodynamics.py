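"""Derived hemodynamics: cardiac output, MAP, external work, surrogate MWE.

Surrogate myocardial work efficiency is the external cardiac work --
cardiac output times mean arterial pressure -- normalized to LV mass:

    EW  [mmHg L/min]    = CO * MAP
    MWE [mmHg L/min/g]  = EW / LV mass

It stands in for myocardial external efficiency without requiring
oxygen-consumption imaging. The rate-pressure product index
(SBP x HR / 1e4) tracks cardiac workload and is used both as a covariate
and to normalize resting blood flow per subject.

The unit string for MWE is written mmHg.L.min^-1.g^-1 throughout;
"mmHg L/g/min" seen elsewhere is the same quantity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidParameterError

__all__ = [
    "mean_arterial_pressure",
    "cardiac_output",
    "external_work",
    "mwe",
    "rpp_index",
    "rpp_normalized_mbf",
    "index_by_bsa",
    "derive_hemodynamics",
]


def _require_positive(**kwargs):
    for name, value in kwargs.items():
        arr = np.asarray(value, dtype=float)
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
            raise InvalidParameterError(f"{name} must be positive and finite")


def mean_arterial_pressure(sbp, dbp):
    """MAP = DBP + (SBP - DBP)/3, the one-third pulse-pressure rule."""
    _require_positive(sbp=sbp, dbp=dbp)
    sbp, dbp = np.asarray(sbp, dtype=float), np.asarray(dbp, dtype=float)
    if np.any(sbp < dbp):
        raise InvalidParameterError("systolic pressure below diastolic")
    out = dbp + (sbp - dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def cardiac_output(sv, hr):
    """Cardiac output in L/min from stroke volume (ml) and heart rate (bpm)."""
    _require_positive(sv=sv, hr=hr)
    out = np.asarray(sv, dtype=float) * np.asarray(hr, dtype=float) / 1000.0
    return float(out) if out.ndim == 0 else out


def external_work(co, map_mmhg):
    """External cardiac work (mmHg L/min) = CO x MAP."""
    _require_positive(co=co, map_mmhg=map_mmhg)
    out = np.asarray(co, dtype=float) * np.asarray(map_mmhg, dtype=float)
    return float(out) if out.ndim == 0 else out


def mwe(ew, lv_mass):
    """Surrogate myocardial work efficiency: EW / LV mass (mmHg L/min/g)."""
    _require_positive(lv_mass=lv_mass)
    ew = np.asarray(ew, dtype=float)
    if np.any(ew < 0):
        raise InvalidParameterError("external work must be non-negative")
    out = ew / np.asarray(lv_mass, dtype=float)
    return float(out) if out.ndim == 0 else out


def rpp_index(sbp, hr):
    """Rate-pressure product index: SBP x HR / 1e4 (dimensionless)."""
    _require_positive(sbp=sbp, hr=hr)
    out = np.asarray(sbp, dtype=float) * np.asarray(hr, dtype=float) / 1.0e4
    return float(out) if out.ndim == 0 else out


def rpp_normalized_mbf(mbf, rpp):
    """Per-subject workload-normalized resting MBF: MBF / RPP index."""
    _require_positive(rpp=rpp)
    out = np.asarray(mbf, dtype=float) / np.asarray(rpp, dtype=float)
    return float(out) if out.ndim == 0 else out


def index_by_bsa(value, bsa):
    """Body-size indexing: value / BSA (m^2). Missing BSA is an error, not imputed."""
    bsa_arr = np.asarray(bsa, dtype=float)
    if np.any(~np.isfinite(bsa_arr)) or np.any(bsa_arr <= 0):
        raise InvalidParameterError("bsa must be positive and present")
    out = np.asarray(value, dtype=float) / bsa_arr
    return float(out) if out.ndim == 0 else out


def du_bois_bsa(height_cm, weight_kg):
    """Du Bois BSA (m^2); fallback only when BSA is absent but height/weight present."""
    _require_positive(height_cm=height_cm, weight_kg=weight_kg)
    out = 0.007184 * np.asarray(height_cm, dtype=float) ** 0.725 * np.asarray(
        weight_kg, dtype=float
    ) ** 0.425
    return float(out) if out.ndim == 0 else out


def derive_hemodynamics(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append derived columns to a subject-level cohort table.

    Requires ``sbp, dbp, hr, sv, lv_mass``; appends ``map_mmHg, co_l_min,
    ew, mwe, rpp_index`` and, when ``rest_mbf`` is present,
    ``mbf_rpp_norm``.
    """
    out = cohort.copy()
    out["map_mmHg"] = mean_arterial_pressure(out["sbp"].to_numpy(), out["dbp"].to_numpy())
    out["co_l_min"] = cardiac_output(out["sv"].to_numpy(), out["hr"].to_numpy())
    out["ew"] = external_work(out["co_l_min"].to_numpy(), out["map_mmHg"].to_numpy())
    out["mwe"] = mwe(out["ew"].to_numpy(), out["lv_mass"].to_numpy())
    out["rpp_index"] = rpp_index(out["sbp"].to_numpy(), out["hr"].to_numpy())
    if "rest_mbf" in out.columns:
        out["mbf_rpp_norm"] = rpp_normalized_mbf(
            out["rest_mbf"].to_numpy(), out["rpp_index"].to_numpy()
        )
    return out
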