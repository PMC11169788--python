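"""Exception hierarchy shared across the package."""


class CmrQuantError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CmrQuantError, ValueError):
    """A scalar parameter violates its physical or statistical domain."""


class SaturationClippingError(CmrQuantError, ValueError):
    """A signal sample reached or exceeded the fully recovered signal S0.

    The inverse signal->R1 map is undefined there; the offending frame is
    reported so the caller can locate the clipped sample.
    """

    def __init__(self, frame_index: int, signal: float, s0: float):
        self.frame_index = int(frame_index)
        self.signal = float(signal)
        self.s0 = float(s0)
        super().__init__(
            f"signal {signal:.6g} at frame {frame_index} reaches or exceeds "
            f"S0={s0:.6g}; saturation clipping"
        )


class UninformativeInputError(CmrQuantError, ValueError):
    """The arterial input has no detectable upslope; deconvolution is ill-posed."""


class GridMismatchError(CmrQuantError, ValueError):
    """Two curves are not sampled on the same time grid."""


class SchemaError(CmrQuantError, ValueError):
    """An input table violates the expected CSV dialect."""


class DegenerateDesignError(CmrQuantError, ValueError):
    """A regression design has no usable variation (e.g. all blood R1 equal)."""


class SeparationError(CmrQuantError, ValueError):
    """Logistic regression data are completely separated."""


class GenerationError(CmrQuantError, ValueError):
    """A synthetic-data request is physically or numerically infeasible."""
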