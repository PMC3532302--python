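"""Exception types used across the package."""


class DomainError(ValueError):
    """An input lies outside the domain an operation is defined on."""


class IntegrationError(RuntimeError):
    """The ODE integration produced a non-finite state."""


class FitError(RuntimeError):
    """A calibration or curve fit failed to produce a usable result."""
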