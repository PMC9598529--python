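"""Exception hierarchy for composcore."""


class ComposcoreError(Exception):
    """Base class for all composcore errors."""


class CohortFormatError(ComposcoreError):
    """The input file does not have the expected columns/layout."""


class CohortValidationError(ComposcoreError):
    """The input parses but violates a cohort invariant (missing value,
    non-numeric entry, duplicate record, wrong number of condition levels)."""


class DegenerateScaleError(ComposcoreError):
    """A measure has zero or undefined variance on the scaling subset."""


class ConfigError(ComposcoreError):
    """A generator or training configuration is invalid or infeasible."""


class BatteryMismatchError(ComposcoreError):
    """Data columns do not match the battery a model was trained on."""


class DivergenceError(ComposcoreError):
    """Training produced a non-finite loss."""


class PairingError(ComposcoreError):
    """A subject lacks a record under one of the two conditions."""


class InsufficientDataError(ComposcoreError):
    """Too few rows/pairs for the requested computation."""


class DegenerateStatisticError(ComposcoreError):
    """A statistic is undefined on this input (e.g. zero-variance
    paired differences, zero-variance composite)."""
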