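"""Exception hierarchy shared across the package.

``ConfigError`` and ``DataError`` map onto the CLI exit codes 2 and 3.
"""


class TomothickError(Exception):
    """Base class for all package errors."""


class ConfigError(TomothickError):
    """Invalid parameters or configuration (CLI exit code 2)."""


class DataError(TomothickError):
    """Invalid or inconsistent input data (CLI exit code 3)."""


class VolumeParseError(DataError):
    """A volume file could not be parsed as MRC2014."""


class SchemaError(DataError):
    """A tabular file is missing required columns."""


class DegenerateGeometryError(DataError):
    """An instance is too thin/small or otherwise geometrically degenerate."""


class UndefinedStatisticError(DataError):
    """A requested statistic is undefined for the given data (e.g. zero variance)."""
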