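"""Exception hierarchy for stresspcg."""


class StressPCGError(Exception):
    """Base class for all package errors."""


class InvalidInputError(StressPCGError, ValueError):
    """Input violates a structural precondition (shape, finiteness, emptiness)."""


class DomainError(StressPCGError, ValueError):
    """A parameter lies outside its mathematical domain (e.g. alpha <= 0)."""


class DegenerateInputError(StressPCGError, ValueError):
    """Input is structurally valid but degenerate for the requested quantity
    (e.g. an all-zero time-frequency matrix, a constant envelope)."""


class ConfigurationError(StressPCGError, ValueError):
    """A generator or benchmark configuration is internally inconsistent."""
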