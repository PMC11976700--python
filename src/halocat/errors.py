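"""Exception and warning types shared across the pipeline stages."""


class HalocatError(Exception):
    """Base class for all halocat errors."""


class InvalidParameterError(HalocatError, ValueError):
    """A parameter violates its documented constraint."""


class InvalidReadError(HalocatError, ValueError):
    """A raw instrument reading is unusable (e.g. non-positive reference absorbance)."""


class RangeError(HalocatError, ValueError):
    """A derived quantity left the dynamic range of the assay."""


class InsufficientDataError(HalocatError, ValueError):
    """Too few usable observations for the requested estimate."""


class FitFailureError(HalocatError, RuntimeError):
    """Nonlinear fit failed to converge after multi-start."""


class InfeasibleObservationError(HalocatError, ValueError):
    """A (conversion, ee) pair violates resolution mass balance."""


class UndefinedResultError(HalocatError, ValueError):
    """The requested quantity is undefined for this input (e.g. E at zero conversion)."""


class NoTransitionError(HalocatError, ValueError):
    """No unfolding transition detectable in a melt curve."""


class DegenerateResidueError(HalocatError, ValueError):
    """A residue shows zero positional fluctuation; correlations are undefined."""


class DegenerateDesignError(HalocatError, ValueError):
    """Calibration design is degenerate (e.g. all standards at one concentration)."""


class OutOfRangeWarning(UserWarning):
    """A value was clamped back into the assay's dynamic range."""


class ExtrapolationWarning(UserWarning):
    """A quantity was read off a calibration outside its standard range."""


class PoorFitWarning(UserWarning):
    """A calibration or model fit is of questionable quality."""
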