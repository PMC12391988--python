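"""Error categories used across the package and surfaced by the CLI."""

from __future__ import annotations


class GeldiffError(Exception):
    """Base class for all package errors."""

    category = "error"
    exit_code = 1


class ValidationError(GeldiffError, ValueError):
    """A physically invalid or non-finite parameter / data value."""

    category = "validation"
    exit_code = 4


class SchemaError(GeldiffError, ValueError):
    """A malformed input table: wrong header, non-numeric cells,
    duplicate keys, unsorted times, or an empty file."""

    category = "schema"
    exit_code = 3


class FitError(GeldiffError, RuntimeError):
    """A model fit that failed to converge or has no solution."""

    category = "fit"
    exit_code = 5


class OutsideModelRangeError(GeldiffError, ValueError):
    """A requested inversion target that no radius on the model curve
    attains within the search interval."""

    category = "range"
    exit_code = 6
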