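"""Exception hierarchy for the dorsaflow pipeline."""


class DorsaflowError(Exception):
    """Base class for all pipeline errors."""


class TrackFormatError(DorsaflowError):
    """A trajectory file does not conform to a recognised CSV dialect."""


class TrackDataError(DorsaflowError):
    """Track contents violate an invariant (non-monotone frames, re-attachment, ...)."""


class QCError(DorsaflowError):
    """A track fails a quality-control precondition (too short, zero span, ...)."""


class ConfigurationError(DorsaflowError):
    """Required configuration or metadata is missing or inconsistent."""


class CalibrationError(DorsaflowError):
    """The force-vs-height logistic calibration could not be fitted."""


class FitError(DorsaflowError):
    """A nonlinear model fit failed to converge in all restarts."""


class ConvergenceError(DorsaflowError):
    """Particle advection did not reach terminal velocity within the allotted time."""


class ExtrapolationWarning(UserWarning):
    """A calibration is being evaluated outside its sampled height span."""
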