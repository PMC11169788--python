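"""Saturation-recovery signal model and signal <-> R1 conversion.

First-pass perfusion imaging uses a saturation-recovery (T1-weighted)
gradient-echo readout. Under an ideal saturation preparation the measured
signal depends on the longitudinal relaxation rate R1 = 1/T1 as

    S(R1) = S0 * (1 - exp(-TS * R1))

where TS is the effective delay between the saturation pulse and the
k-space center and S0 is the fully recovered signal. Flip-angle and
readout corrections of more elaborate sequence models are collapsed into
the single effective TS; this preserves the monotone signal <-> R1 mapping
that the rest of the pipeline relies on.

The unknown scale S0 is calibrated per region from the pre-contrast
(baseline) frames together with the measured native T1, after which each
frame's signal can be inverted to R1 and expressed as the contrast-induced
change dR1(t) = R1(t) - R1_native. Gadolinium concentration is
proportional to dR1, so dR1 curves are the concentration-scale input to
the deconvolution stage.

Units: R1 is carried in 1/s throughout; native T1 inputs are in ms
(the unit in which T1 maps are reported); TS is in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidParameterError, SaturationClippingError

__all__ = [
    "TimeSeriesCurve",
    "SaturationRecoveryParams",
    "signal_from_r1",
    "r1_from_signal",
    "calibrate_s0",
    "delta_r1_curve",
    "r1_native_per_s",
]


def r1_native_per_s(t1_native_ms: float) -> float:
    """Native relaxation rate in 1/s from a native T1 in ms."""
    if t1_native_ms <= 0:
        raise InvalidParameterError(f"native T1 must be positive, got {t1_native_ms}")
    return 1000.0 / float(t1_native_ms)


@dataclass
class TimeSeriesCurve:
    """A sampled curve for one region: raw signal or dR1 versus time.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing.
    values
        Signal (arbitrary units) or dR1 (1/s), same length as ``times``.
    kind
        Either ``"signal"`` or ``"delta_r1"``.
    label
        Optional region label (e.g. ``"aif"`` or an AHA segment number).
    """

    times: np.ndarray
    values: np.ndarray
    kind: str = "signal"
    label: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise InvalidParameterError("curve arrays must be one-dimensional")
        if self.times.size != self.values.size:
            raise InvalidParameterError(
                f"times ({self.times.size}) and values ({self.values.size}) differ in length"
            )
        if self.times.size == 0:
            raise InvalidParameterError("curve must contain at least one sample")
        if np.any(np.diff(self.times) <= 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise InvalidParameterError("curve contains non-finite samples")
        if self.kind not in ("signal", "delta_r1"):
            raise InvalidParameterError(f"unknown curve kind {self.kind!r}")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.times.size


@dataclass(frozen=True)
class SaturationRecoveryParams:
    """Acquisition parameters of the saturation-recovery readout.

    ``ts`` is the effective saturation delay in seconds; ``n_baseline`` the
    number of pre-contrast frames used for S0 calibration; native T1s are
    in ms (tissue and blood differ and each region is calibrated with its
    own native rate).
    """

    ts: float = 0.1
    n_baseline: int = 5
    t1_native_tissue_ms: float = 1232.0
    t1_native_blood_ms: float = 1900.0

    def __post_init__(self):
        if self.ts <= 0:
            raise InvalidParameterError(f"ts must be positive, got {self.ts}")
        if self.n_baseline < 1:
            raise InvalidParameterError("n_baseline must be at least 1")
        if self.t1_native_tissue_ms <= 0 or self.t1_native_blood_ms <= 0:
            raise InvalidParameterError("native T1 values must be positive")

    @property
    def r1_native_tissue(self) -> float:
        return r1_native_per_s(self.t1_native_tissue_ms)

    @property
    def r1_native_blood(self) -> float:
        return r1_native_per_s(self.t1_native_blood_ms)


def signal_from_r1(r1, s0: float, params: SaturationRecoveryParams):
    """Forward saturation-recovery model: S = S0 (1 - exp(-TS R1)).

    Strictly monotone increasing in R1 and bounded above by S0.
    """
    if s0 <= 0:
        raise InvalidParameterError(f"s0 must be positive, got {s0}")
    r1 = np.asarray(r1, dtype=float)
    if np.any(r1 < 0):
        raise InvalidParameterError("r1 must be non-negative")
    out = s0 * (1.0 - np.exp(-params.ts * r1))
    return float(out) if out.ndim == 0 else out


def r1_from_signal(signal, s0: float, params: SaturationRecoveryParams):
    """Invert the saturation-recovery model: R1 = -ln(1 - S/S0)/TS.

    Exact inverse of :func:`signal_from_r1`. Any frame at or above S0 is a
    saturation-clipped sample for which no finite R1 exists;
    :class:`~cmrquant.exceptions.SaturationClippingError` names the first
    such frame. Slightly negative signals (baseline noise) map to negative
    R1 and are tolerated.
    """
    if s0 <= 0:
        raise InvalidParameterError(f"s0 must be positive, got {s0}")
    signal = np.asarray(signal, dtype=float)
    clipped = signal >= s0
    if np.any(clipped):
        idx = int(np.argmax(clipped))
        raise SaturationClippingError(idx, float(np.atleast_1d(signal)[idx]), s0)
    out = -np.log(1.0 - signal / s0) / params.ts
    return float(out) if out.ndim == 0 else out


def calibrate_s0(baseline_values, t1_native_ms: float, ts: float) -> float:
    """Fix the signal scale S0 from pre-contrast frames and the native T1.

    Before contrast arrival R1 equals the native rate, so the baseline
    signal mean must be S0 (1 - exp(-TS R1_native)); solving for S0 gives
    the calibration.
    """
    baseline = np.asarray(baseline_values, dtype=float)
    if baseline.size == 0:
        raise InvalidParameterError("baseline must contain at least one frame")
    if ts <= 0:
        raise InvalidParameterError(f"ts must be positive, got {ts}")
    recovery = 1.0 - np.exp(-ts * r1_native_per_s(t1_native_ms))
    if recovery <= 0 or not np.isfinite(recovery):
        raise InvalidParameterError("degenerate recovery fraction in S0 calibration")
    return float(np.mean(baseline)) / recovery


def delta_r1_curve(
    curve: TimeSeriesCurve,
    s0: float,
    params: SaturationRecoveryParams,
    t1_native_ms: float | None = None,
) -> TimeSeriesCurve:
    """Convert a signal curve to a dR1 curve (R1 minus the native rate).

    ``t1_native_ms`` selects the native rate subtracted per frame; it
    defaults to the tissue native T1 (pass the blood native T1 for the
    arterial input). With S0 calibrated from the same baseline frames, the
    pre-contrast portion of the output averages approximately zero.
    """
    if curve.kind != "signal":
        raise InvalidParameterError("delta_r1_curve expects a signal-kind curve")
    if t1_native_ms is None:
        t1_native_ms = params.t1_native_tissue_ms
    r1 = r1_from_signal(curve.values, s0, params)
    delta = np.asarray(r1) - r1_native_per_s(t1_native_ms)
    return TimeSeriesCurve(curve.times.copy(), delta, kind="delta_r1", label=curve.label)
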