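"""Exception hierarchy shared across the pipeline.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericError -> 4.
"""


class Acini3dError(Exception):
    """Base class for all package errors."""


class ConfigError(Acini3dError):
    """Invalid configuration: bad parameter ranges, conflicting input modes."""


class DataError(Acini3dError):
    """Invalid or inconsistent input data."""


class SchemaError(DataError):
    """A required column or sheet is missing from an input table."""


class ParseError(DataError):
    """A value in an input table could not be parsed."""


class DegenerateGeometryError(DataError):
    """An acinus is too small or collapsed for geometric features."""


class GenerationError(Acini3dError):
    """Synthetic-cohort generation failed (e.g. infeasible sphere packing)."""


class NumericError(Acini3dError):
    """A numerical procedure failed in a way that invalidates the analysis."""


class AnalysisError(NumericError):
    """Statistical analysis cannot proceed (e.g. single-class outcome)."""
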