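"""Exception hierarchy and CLI exit codes.

Exit code convention: 0 success, 1 data error, 2 configuration error.
"""


class SvmHdmrError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class DataError(SvmHdmrError):
    """The input data violate a precondition (bad groups, constant column, ...)."""

    exit_code = 1


class ConfigurationError(SvmHdmrError):
    """The requested settings are invalid (unknown column, bad fold count, ...)."""

    exit_code = 2


class KernelError(DataError):
    """A kernel family is unusable for the given data (e.g. non-positive grand mean)."""
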