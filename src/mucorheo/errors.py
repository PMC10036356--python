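"""Exception hierarchy shared across the pipeline."""


class MucorheoError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MucorheoError, ValueError):
    """A data value violates an operation's preconditions."""


class InvalidConfigError(MucorheoError, ValueError):
    """A configuration / reference value is unusable (e.g. zero reference)."""


class InfeasibleMixtureError(MucorheoError):
    """Pooling constraints admit no recipe."""
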