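"""Synthetic-data generators with known ground truth.

Three generator families make every stage of the pipeline verifiable
without patient data:

* first-pass perfusion curve sets: a gamma-variate arterial input,
  tissue curves as the true-flow-scaled convolution with a known residue
  (exponential or Fermi), passed through the saturation-recovery signal
  model with per-region scale and Gaussian noise at a stated SNR;
* T1-mapping triplets: blood R1 over a contrast-washout schedule and
  tissue R1 on a line with a known partition coefficient;
* structural cohorts: ECV drawn from a truncated normal, resting MBF and
  surrogate MWE generated from known mediation paths, hemodynamic columns
  back-solved so the MWE identity CO*MAP/mass holds row-wise exactly,
  segment-level tables with a base-to-apex gradient in the high-ECV
  tertiles, and an LGE flag with a known logistic dependence on ECV.

Every generator is a pure function of (parameters, seed): identical
inputs give identical outputs. Cohort calibration constants live in
``data/cohort_defaults.yaml``, not in the code.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from . import aha
from .exceptions import GenerationError, InvalidParameterError
from .hemodynamics import mean_arterial_pressure, rpp_index
from .io import SegmentalCurveSet
from .signal_model import (
    SaturationRecoveryParams,
    TimeSeriesCurve,
    signal_from_r1,
)

__all__ = [
    "AifParams",
    "PerfusionTruth",
    "CohortTruth",
    "gen_aif",
    "gen_perfusion_dataset",
    "gen_t1_dataset",
    "gen_mediation_dataset",
    "gen_cohort",
]

_OVERSAMPLE = 10  # fine-grid factor for the forward convolution


# ---------------------------------------------------------------------------
# Perfusion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AifParams:
    """Gamma-variate arterial input in dR1 units.

    The curve is peak * ((t-t0)/(alpha*beta))^alpha * exp(alpha - (t-t0)/beta)
    for t > t0 and zero before; its maximum is ``peak`` at t0 + alpha*beta.
    An optional recirculation bump adds a delayed, scaled copy.
    """

    peak: float = 4.0  # 1/s
    t0: float = 4.0  # s, bolus arrival
    alpha: float = 2.5
    beta: float = 1.5  # s
    recirc_fraction: float = 0.0
    recirc_delay: float = 12.0

    def __post_init__(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise InvalidParameterError("gamma-variate shape parameters must be positive")
        if self.peak < 0:
            raise InvalidParameterError("peak must be non-negative")


def _gamma_variate(t: np.ndarray, p: AifParams) -> np.ndarray:
    out = np.zeros_like(t)
    tau = t - p.t0
    pos = tau > 0
    tp = p.alpha * p.beta
    out[pos] = p.peak * (tau[pos] / tp) ** p.alpha * np.exp(p.alpha - tau[pos] / p.beta)
    return out


def gen_aif(params: AifParams, n_frames: int = 60, dt: float = 0.8) -> TimeSeriesCurve:
    """Deterministic gamma-variate arterial input as a dR1 curve."""
    t = np.arange(n_frames) * dt
    v = _gamma_variate(t, params)
    if params.recirc_fraction > 0:
        shifted = dataclasses.replace(params, t0=params.t0 + params.recirc_delay)
        v = v + params.recirc_fraction * _gamma_variate(t, shifted)
    return TimeSeriesCurve(t, v, kind="delta_r1", label="aif")


def _residue(t: np.ndarray, model: str, f_per_s: float, lambda_p: float, fermi_t0: float, fermi_k: float) -> np.ndarray:
    if model == "exponential":
        # washout time constant = distribution volume / flow
        return np.exp(-t * f_per_s / lambda_p)
    if model == "fermi":
        return (1.0 + np.exp(-fermi_k * fermi_t0)) / (1.0 + np.exp(fermi_k * (t - fermi_t0)))
    raise InvalidParameterError(f"unknown residue model {model!r}")


@dataclass
class PerfusionTruth:
    """Ground truth of one synthetic perfusion dataset."""

    mbf: dict = field(default_factory=lambda: {s: 0.9 for s in aha.SEGMENTS})
    residue_model: str = "exponential"
    aif: AifParams = field(default_factory=AifParams)
    snr: float = np.inf
    seed: int = 0
    lambda_p: float = 0.5  # contrast distribution volume, exponential residue
    fermi_t0: float = 3.0  # s, Fermi shoulder
    fermi_k: float = 1.0  # 1/s, Fermi decay
    delay_frames: int = 0
    density_g_per_ml: float = 1.05
    s0: float = 1000.0

    def __post_init__(self):
        self.mbf = {int(k): float(v) for k, v in self.mbf.items()}
        if any(v < 0 for v in self.mbf.values()):
            raise InvalidParameterError("true MBF must be non-negative")
        if self.snr <= 0:
            raise InvalidParameterError("snr must be positive")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["snr"] = None if np.isinf(self.snr) else self.snr
        return json.dumps(d, indent=2)


def gen_perfusion_dataset(
    truth: PerfusionTruth,
    sr_params: SaturationRecoveryParams = SaturationRecoveryParams(),
    n_frames: int = 60,
    dt: float = 0.8,
    seed: int | None = None,
) -> tuple[SegmentalCurveSet, PerfusionTruth]:
    """Synthesize a segmental first-pass signal dataset with known MBF.

    Tissue dR1 is computed as the continuous convolution of the AIF with
    the flow-scaled residue on a 10x oversampled grid, down-sampled to the
    frame grid, mapped through the saturation-recovery model with
    per-region S0, and degraded with Gaussian noise of standard deviation
    peak-signal/SNR. ``seed`` overrides ``truth.seed``.
    """
    if seed is not None:
        truth = dataclasses.replace(truth, seed=seed)
    rng = np.random.default_rng(truth.seed)
    span = n_frames * dt
    if truth.aif.t0 + 30.0 > span:
        raise GenerationError(
            f"frame grid spans {span:.1f}s but onset+30s needs {truth.aif.t0 + 30:.1f}s"
        )
    n_fine = n_frames * _OVERSAMPLE
    dt_fine = dt / _OVERSAMPLE
    t_fine = np.arange(n_fine) * dt_fine
    aif_fine = _gamma_variate(t_fine, truth.aif)
    if truth.aif.recirc_fraction > 0:
        shifted = dataclasses.replace(truth.aif, t0=truth.aif.t0 + truth.aif.recirc_delay)
        aif_fine = aif_fine + truth.aif.recirc_fraction * _gamma_variate(t_fine, shifted)
    if truth.delay_frames:
        shift = truth.delay_frames * _OVERSAMPLE
        delayed = np.zeros_like(aif_fine)
        delayed[shift:] = aif_fine[:-shift]
    else:
        delayed = aif_fine

    times = np.arange(n_frames) * dt
    r1n_t = sr_params.r1_native_tissue
    r1n_b = sr_params.r1_native_blood
    segments = {}
    for seg in aha.SEGMENTS:
        f_per_s = truth.mbf[seg] * truth.density_g_per_ml / 60.0
        if f_per_s == 0:
            dr1 = np.zeros(n_frames)
        else:
            h = f_per_s * _residue(
                t_fine, truth.residue_model, f_per_s, truth.lambda_p, truth.fermi_t0, truth.fermi_k
            )
            conv = np.convolve(delayed, h)[:n_fine] * dt_fine
            dr1 = conv[:: _OVERSAMPLE]
        segments[seg] = dr1

    def _to_signal(dr1, r1_native):
        r1 = dr1 + r1_native
        if np.max(1.0 - np.exp(-sr_params.ts * r1)) > 0.995:
            raise GenerationError(
                "dR1 too large for the saturation-recovery scale; "
                "increase S0 headroom by shortening ts or lowering the AIF peak"
            )
        sig = signal_from_r1(r1, truth.s0, sr_params)
        if np.isfinite(truth.snr):
            # image SNR convention: noise sd relative to the region's
            # pre-contrast (baseline) signal level
            baseline = float(np.mean(sig[: sr_params.n_baseline]))
            sig = sig + rng.normal(0.0, baseline / truth.snr, size=sig.shape)
        return sig

    aif_signal = _to_signal(aif_fine[:: _OVERSAMPLE], r1n_b)
    seg_signals = {s: _to_signal(v, r1n_t) for s, v in segments.items()}
    curves = SegmentalCurveSet(times, aif_signal, seg_signals, kind="signal")
    return curves, truth


# ---------------------------------------------------------------------------
# T1 / ECV
# ---------------------------------------------------------------------------

# Blood R1 (1/s) at pre-contrast and the 10/20-min post-contrast delays:
# native blood T1 ~1.9 s at 3T, then partial washout of the contrast.
DEFAULT_BLOOD_R1_SCHEDULE = (0.526, 1.75, 1.30)


def gen_t1_dataset(
    true_lambda,
    hct: float = 0.40,
    noise_sd: float = 0.0,
    seed: int | None = None,
    blood_r1_schedule=DEFAULT_BLOOD_R1_SCHEDULE,
    r1_tissue_native: float = 0.8117,  # 1/s, native T1 1232 ms
) -> tuple[pd.DataFrame, dict]:
    """Per-segment R1 triplets generated from a known partition coefficient.

    ``true_lambda`` may be a scalar (applied to all 16 segments) or a
    mapping segment -> lambda. Tissue R1 lies on the line
    intercept + lambda * blood R1 with the intercept chosen so the
    pre-contrast point sits at the native tissue R1; Gaussian noise of sd
    ``noise_sd`` (1/s) is added to the tissue values.
    """
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be non-negative")
    if np.isscalar(true_lambda):
        lam_of = {s: float(true_lambda) for s in aha.SEGMENTS}
    else:
        lam_of = {int(k): float(v) for k, v in dict(true_lambda).items()}
    if any(l <= 0 for l in lam_of.values()):
        raise InvalidParameterError("true lambda must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    timepoints = ("pre", "post10", "post20")
    for seg, lam in sorted(lam_of.items()):
        intercept = r1_tissue_native - lam * blood_r1_schedule[0]
        for tp, rb in zip(timepoints, blood_r1_schedule):
            rt = intercept + lam * rb + rng.normal(0.0, noise_sd)
            rows.append(
                {"segment": seg, "timepoint": tp, "r1_blood_per_s": rb, "r1_tissue_per_s": rt}
            )
    truth = {
        "lambda": lam_of,
        "hct": hct,
        "noise_sd": noise_sd,
        "seed": seed,
        "blood_r1_schedule": tuple(blood_r1_schedule),
    }
    return pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------


def _load_cohort_defaults() -> dict:
    ref = importlib.resources.files("cmrquant").joinpath("data/cohort_defaults.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class CohortTruth:
    """Structural parameters of the synthetic cohort.

    Defaults are loaded from ``data/cohort_defaults.yaml`` and calibrated
    to the printed cohort marginals; they define the study conditions under
    which the inference layer is exercised. Every field can be overridden.
    """

    params: dict = field(default_factory=_load_cohort_defaults)

    def __post_init__(self):
        base = _load_cohort_defaults()
        unknown = set(self.params) - set(base)
        if unknown:
            raise InvalidParameterError(f"unknown cohort parameters: {sorted(unknown)}")
        merged = {**base, **self.params}
        if merged["n_subjects"] < 3:
            raise InvalidParameterError("need at least 3 subjects")
        if merged["mbf_resid_sd"] <= 0 or merged["mwe_resid_sd"] <= 0:
            raise InvalidParameterError("residual sds must be positive")
        self.params = merged

    def __getitem__(self, key):
        return self.params[key]

    def replace(self, **overrides) -> "CohortTruth":
        return CohortTruth({**self.params, **overrides})


def gen_mediation_dataset(
    a: float, b: float, c_prime: float, n: int = 92, seed: int | None = None
) -> pd.DataFrame:
    """Standardized mediation triple (x, m, y) with known path coefficients.

    All three variables have unit population variance; the paths are the
    standardized coefficients. Requires a feasible residual variance for y.
    """
    var_m_resid = 1.0 - a**2
    var_y_resid = 1.0 - (c_prime**2 + b**2 + 2.0 * a * b * c_prime)
    if var_m_resid <= 0 or var_y_resid <= 0:
        raise InvalidParameterError("paths imply non-positive residual variance")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    m = a * x + np.sqrt(var_m_resid) * rng.standard_normal(n)
    y = c_prime * x + b * m + np.sqrt(var_y_resid) * rng.standard_normal(n)
    return pd.DataFrame({"x": x, "m": m, "y": y})


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def gen_cohort(
    truth: CohortTruth | None = None, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate a subject table and a segment table with known structure.

    Subject level: ECV (%) truncated normal; MBF = am + a*ECV + em;
    MWE = ay + c'*ECV + b*MBF + ey; hemodynamic columns are back-solved so
    that CO*MAP/LV mass reproduces the generated MWE exactly row-wise.
    Rows with infeasible MWE or MBF draws have their residuals redrawn
    (count logged in the truth record).

    Segment level: segmental ECV scatters around the subject value; the
    segmental MBF model is b0 + seg_ecv_effect*ECV_seg +
    seg_rpp_effect*(RPP - 0.9) + u_subject + slice increments + noise,
    where the subject random intercept u is the subject's MBF residual em
    (so it is independent of ECV and the segment-level fixed effect is
    estimable without endogeneity). Base-to-apex increments apply in the
    configured ECV tertiles.
    """
    truth = truth or CohortTruth()
    p = truth.params
    rng = np.random.default_rng(seed)
    n = int(p["n_subjects"])

    ecv = _truncated_normal(rng, p["ecv_mean_pct"], p["ecv_sd_pct"], p["ecv_lo_pct"], p["ecv_hi_pct"], n)
    hct = np.clip(rng.normal(p["hct_mean"], p["hct_sd"], n), 0.25, 0.55)

    n_redrawn = 0
    eps_m = rng.normal(0.0, p["mbf_resid_sd"], n)
    mbf = p["mbf_intercept"] + p["path_a_mbf_per_ecv"] * ecv + eps_m
    bad = mbf < p["min_mbf"]
    while np.any(bad):
        n_redrawn += int(bad.sum())
        eps_m[bad] = rng.normal(0.0, p["mbf_resid_sd"], int(bad.sum()))
        mbf = p["mbf_intercept"] + p["path_a_mbf_per_ecv"] * ecv + eps_m
        bad = mbf < p["min_mbf"]

    eps_y = rng.normal(0.0, p["mwe_resid_sd"], n)
    mwe_vals = (
        p["mwe_intercept"] + p["path_c_direct_per_ecv"] * ecv + p["path_b_mwe_per_mbf"] * mbf + eps_y
    )
    bad = mwe_vals < p["min_mwe"]
    while np.any(bad):
        n_redrawn += int(bad.sum())
        eps_y[bad] = rng.normal(0.0, p["mwe_resid_sd"], int(bad.sum()))
        mwe_vals = (
            p["mwe_intercept"]
            + p["path_c_direct_per_ecv"] * ecv
            + p["path_b_mwe_per_mbf"] * mbf
            + eps_y
        )
        bad = mwe_vals < p["min_mwe"]

    hr = np.clip(rng.normal(p["hr_mean"], p["hr_sd"], n), 45, 120)
    dbp = np.clip(rng.normal(p["dbp_mean"], p["dbp_sd"], n), 40, 110)
    pulse = np.clip(rng.normal(p["sbp_mean"] - p["dbp_mean"], 12.0, n), 10, None)
    sbp = dbp + pulse
    bsa = np.clip(rng.normal(p["bsa_mean"], p["bsa_sd"], n), 1.3, 2.6)
    mass_index = np.clip(rng.normal(p["lv_mass_index_mean"], p["lv_mass_index_sd"], n), 30, None)
    lv_mass = mass_index * bsa
    lvef = np.clip(rng.normal(p["lvef_mean"], p["lvef_sd"], n), 20, 78)

    # back-solve hemodynamics so MWE = CO*MAP/mass holds exactly
    map_mmhg = mean_arterial_pressure(sbp, dbp)
    ew = mwe_vals * lv_mass
    co = ew / map_mmhg
    sv = co * 1000.0 / hr
    edv = sv / (lvef / 100.0)
    esv = edv - sv

    lge_p = expit(p["lge_log_or_per_ecv"] * (ecv - p["lge_center_ecv_pct"]))
    lge = rng.random(n) < lge_p

    # NYHA ordinal linked to MWE: lower efficiency -> higher class, with
    # class frequencies pinned to the configured marginals.
    latent = -mwe_vals + rng.normal(0.0, 1.2, n)
    cum = np.cumsum(p["nyha_fractions"])[:-1]
    cuts = np.quantile(latent, cum)
    nyha = 1 + np.searchsorted(cuts, latent, side="left")

    gls = p["gls_mean"] - 0.35 * (lvef - p["lvef_mean"]) + rng.normal(0, p["gls_noise_sd"], n)
    remission = rng.random(n) < p["remission_fraction"]

    subjects = pd.DataFrame(
        {
            "id": [f"S{i + 1:03d}" for i in range(n)],
            "age": np.round(rng.normal(p["age_mean"], p["age_sd"], n)).astype(int),
            "male": rng.random(n) < p["male_fraction"],
            "sbp": sbp,
            "dbp": dbp,
            "hr": hr,
            "edv": edv,
            "esv": esv,
            "sv": sv,
            "lv_mass": lv_mass,
            "bsa": bsa,
            "hct": hct,
            "global_ecv": ecv / 100.0,
            "rest_mbf": mbf,
            "mwe_true": mwe_vals,
            "lvef": lvef,
            "la_volume": rng.normal(p["la_volume_index_mean"], p["la_volume_index_sd"], n) * bsa,
            "gls": gls,
            "nyha": nyha,
            "lge_present": lge.astype(int),
            "nt_probnp": np.exp(rng.normal(p["nt_probnp_log_mean"], p["nt_probnp_log_sd"], n)),
            "troponin_t": np.exp(rng.normal(p["troponin_log_mean"], p["troponin_log_sd"], n)),
            "dflc": np.exp(rng.normal(p["dflc_log_mean"], p["dflc_log_sd"], n)),
            "al_status": np.where(remission, "remission", "recent"),
            "native_t1": rng.normal(p["native_t1_mean_ms"], p["native_t1_sd_ms"], n),
        }
    )

    # subject tertile membership for the base-to-apex gradient
    q1, q2 = np.quantile(ecv, [1 / 3, 2 / 3])
    tertile = np.where(ecv <= q1, "lower", np.where(ecv <= q2, "middle", "upper"))
    rpp = rpp_index(sbp, hr)
    b0_seg = 0.87 - p["seg_ecv_effect"] * p["ecv_mean_pct"]

    seg_rows = []
    for i in range(n):
        grad = tertile[i] in p["gradient_tertiles"]
        for seg in aha.SEGMENTS:
            slc = aha.SLICE_OF_SEGMENT[seg]
            seg_ecv = float(np.clip(ecv[i] + rng.normal(0.0, p["seg_ecv_sd_pct"]), 15.0, 75.0))
            inc = 0.0
            if grad and slc == "mid":
                inc = p["slice_increment_mid"]
            elif grad and slc == "apical":
                inc = p["slice_increment_apical"]
            seg_mbf = (
                b0_seg
                + p["seg_ecv_effect"] * seg_ecv
                + p["seg_rpp_effect"] * (rpp[i] - 0.9)
                + eps_m[i]
                + inc
                + rng.normal(0.0, p["seg_mbf_sd"])
            )
            seg_rows.append(
                {
                    "subject_id": subjects.loc[i, "id"],
                    "segment": seg,
                    "slice": slc,
                    "wall_class": aha.WALL_CLASS_OF_SEGMENT[seg],
                    "ecv_seg_pct": seg_ecv,
                    "mbf": max(seg_mbf, 0.05),
                    "rpp": rpp[i],
                    "ecv_tertile": tertile[i],
                }
            )
    segments = pd.DataFrame(seg_rows)

    truth_record = {
        "seed": int(seed),
        "n_subjects": n,
        "n_residuals_redrawn": n_redrawn,
        "params": {k: (list(v) if isinstance(v, (list, tuple)) else v) for k, v in p.items()},
    }
    return subjects, segments, truth_record
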