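"""Exception types shared across the package."""


class EcnormError(Exception):
    """Base class for all package errors."""


class ValidationError(EcnormError, ValueError):
    """Malformed or inconsistent user input (bad matrix cell, bad design, ...)."""


class EstimationError(EcnormError, RuntimeError):
    """A statistical estimation step could not be carried out."""
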