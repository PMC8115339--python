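"""Exception hierarchy shared across the pipeline.

``InputError`` maps to CLI exit code 2 (bad or missing input),
``NumericalError`` to exit code 3 (convergence / degeneracy).
"""


class MagstreamError(Exception):
    """Base class for all package errors."""


class InputError(MagstreamError):
    """Raised for malformed, missing or inconsistent input data."""


class NumericalError(MagstreamError):
    """Raised when an iterative or algebraic procedure fails (non-convergence,
    degenerate matrices)."""
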