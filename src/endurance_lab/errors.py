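"""Exception hierarchy shared across the pipeline stages."""


class EnduranceLabError(Exception):
    """Base class for all package errors."""


class ValidationError(EnduranceLabError, ValueError):
    """Invalid parameter, protocol, or configuration value."""


class ProtocolError(ValidationError):
    """Stimulation protocol violates its invariants."""


class CalibrationError(EnduranceLabError):
    """A normalization denominator is unusable (e.g. NH4Cl plateau <= baseline)."""


class FitError(EnduranceLabError):
    """Curve fit failed to converge or hit a bound; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EmptySelectionError(EnduranceLabError):
    """Every ROI was rejected by a selection step."""


class RoiError(ValidationError):
    """An ROI is malformed or falls outside the image frame."""
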