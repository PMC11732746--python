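"""Exception hierarchy for the MSC flux pipeline.

Every error that reflects a problem with the *data* (rather than a bug)
derives from :class:`MSCFluxError`, so callers can catch one base class
at pipeline boundaries.
"""


class MSCFluxError(Exception):
    """Base class for all pipeline errors."""


class MissingMeasurementError(MSCFluxError):
    """A fraction concentration needed by an equation is absent."""


class AmbiguousTrayError(MSCFluxError):
    """Both the direct-tray and syphoned-tray measurements are present
    for one deployment, so the fast-sinking path cannot be chosen."""


class ValidationError(MSCFluxError):
    """A record violates its schema (bad units, negative sd, ...)."""


class UndefinedRatioError(MSCFluxError):
    """A molar ratio has a zero or negative denominator after the
    magnitude rule has been applied."""


class UnfittableProfileError(MSCFluxError):
    """A flux profile has fewer than three positive-flux points, so the
    log-log attenuation fit is undefined."""


class ParameterError(MSCFluxError):
    """A synthetic-data or projection parameterization is infeasible
    (for example a true flux too small to invert through the catcher
    geometry without negative tray concentrations)."""
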