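"""Exception hierarchy shared across the package.

``DataError`` covers malformed or insufficient input data (CLI exit code 2);
``NumericalError`` covers failures of the numerical machinery such as
ill-conditioned deconvolution kernels (CLI exit code 3).
"""


class EivnprError(Exception):
    """Base class for package errors."""


class DataError(EivnprError):
    """Malformed, missing, or insufficient input data."""


class FormatError(DataError):
    """A file does not conform to the expected tabular dialect."""


class NumericalError(EivnprError):
    """A numerical procedure failed (overflow, no root, degenerate system)."""
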