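"""Exception hierarchy shared by all modules.

The CLI maps these onto exit codes: :class:`InputError` and
:class:`ParameterError` exit with 2, :class:`InsufficientDataError` with 3.
"""


class ModspecError(Exception):
    """Base class for all package errors."""


class InputError(ModspecError):
    """Malformed or invalid input data (non-finite samples, empty signal,
    mismatched lengths, unreadable file)."""


class ParameterError(ModspecError):
    """Invalid analysis/filter parameters (hop > window, band edges beyond
    Nyquist, degenerate band, non-COLA window/hop pair)."""


class InsufficientDataError(ModspecError):
    """Signal too short for the requested analysis."""
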