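"""Exception hierarchy shared across the pipeline.

Every error raised by specswap derives from :class:`SpecswapError`, so callers
(and the CLI) can distinguish pipeline failures from programming errors.
"""


class SpecswapError(Exception):
    """Base class for all specswap errors."""


class InputError(SpecswapError):
    """Malformed or inconsistent user-supplied data."""


class AlignmentError(InputError):
    """Alignment-specific input problem (e.g. ragged sequences)."""


class ConfigurationError(SpecswapError):
    """Invalid parameter or option combination."""


class FitError(SpecswapError):
    """Nonlinear fit failed to converge or produced an unusable result."""
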