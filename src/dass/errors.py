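"""Structured exceptions raised by the package."""


class DassError(Exception):
    """Base class for all package-specific errors."""


class TableReadError(DassError):
    """A tabular input file could not be read or decoded."""


class EmptyTableError(DassError):
    """The input file contains no table at all (not even a header)."""


class ConfigError(DassError):
    """Invalid run configuration: unknown defined approach, bad format, bad map file."""


class EvaluationError(DassError):
    """A performance evaluation was requested that the data cannot support."""
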