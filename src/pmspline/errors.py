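"""Exception hierarchy for pmspline."""


class PmsplineError(Exception):
    """Base class for all pmspline errors."""


class ConfigurationError(PmsplineError):
    """Invalid simulation or model configuration."""


class AnnotationError(PmsplineError):
    """Instrument records cannot be joined to the activity logbook."""


class EmptySeriesError(PmsplineError):
    """Cleaning or filtering removed every record of a shift series."""


class CalibrationError(PmsplineError):
    """Calibration fitting or application failed."""


class UnsupportedFractionError(CalibrationError):
    """Calibration requested for a size fraction without a gravimetric standard."""


class ModelConstructionError(PmsplineError):
    """Design matrices and model specification are inconsistent."""


class InitializationError(PmsplineError):
    """MCMC could not be initialized at a finite log-posterior."""


class PredictionError(PmsplineError):
    """Posterior prediction requested for categories absent from the fit."""


class ExtrapolationError(PmsplineError):
    """Spline basis evaluated outside its supported time domain."""


class DegenerateChainError(PmsplineError):
    """MCMC diagnostics undefined (e.g. zero within-chain variance)."""
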