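"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class DiffGwasError(Exception):
    """Base class for all package errors."""


class ConfigError(DiffGwasError):
    """Invalid configuration: bad threshold, missing column mapping, bad path."""


class DataError(DiffGwasError):
    """Invalid or unusable input data."""


class EstimationError(DataError):
    """Overlap-correlation estimation is impossible (too few SNPs, zero variance)."""


class DegenerateVarianceError(DataError):
    """Adjusted variance of the effect-size difference is non-positive."""


class StandardizationError(DataError):
    """Z-score vector cannot be standardized (constant or too short)."""
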