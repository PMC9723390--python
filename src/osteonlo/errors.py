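"""Exception hierarchy shared across the pipeline."""


class OsteonloError(Exception):
    """Base class for all package errors."""


class ParameterError(OsteonloError, ValueError):
    """An argument or spec field is outside its valid domain."""


class FormatError(OsteonloError, ValueError):
    """A file on disk does not match the expected storage dialect."""


class EmptyRoiError(OsteonloError, ValueError):
    """A region of interest selects zero (valid) pixels."""


class DegenerateError(OsteonloError, ValueError):
    """A denominator or model term collapses to zero."""


class FitFailureError(OsteonloError, RuntimeError):
    """Least-squares fitting failed to converge; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
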