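"""Package-wide exception hierarchy."""


class MyripbkError(Exception):
    """Base class for all errors raised by myripbk."""


class ConfigurationError(MyripbkError):
    """A parameter file or model assembly is incomplete or inconsistent."""


class DegenerateDataError(MyripbkError):
    """Input data carry no usable kinetic signal (e.g. all-zero rates)."""


class FitFailureError(MyripbkError):
    """Nonlinear fit did not converge after the bounded multi-start schedule."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class IntegrationError(MyripbkError):
    """The ODE solver failed or produced an unphysical state."""


class UndefinedQuantityError(MyripbkError):
    """A requested ratio or coefficient has an undefined (zero) baseline."""
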