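"""Exception types shared across the package."""


class CortexsigError(Exception):
    """Base class for package errors."""


class ConfigError(CortexsigError, ValueError):
    """A simulation or analysis configuration is invalid.

    The message names the offending field.
    """


class ParseError(CortexsigError, ValueError):
    """A text input could not be parsed; the message carries coordinates."""


class AlignmentError(CortexsigError, ValueError):
    """Expression matrix and metadata (or a detection matrix) do not align."""


class FitError(CortexsigError, RuntimeError):
    """A model fit failed (rank deficiency, separation, non-convergence)."""
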