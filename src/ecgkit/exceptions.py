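"""Exception hierarchy shared across ecgkit modules."""


class EcgKitError(Exception):
    """Base class for all ecgkit errors."""


class ValidationError(EcgKitError, ValueError):
    """An object violates its declared invariants."""


class FormatError(EcgKitError, ValueError):
    """A file is not in the expected on-disk format."""


class SchemaError(EcgKitError, ValueError):
    """Tabular inputs disagree on identifiers or label columns."""


class ParameterError(EcgKitError, ValueError):
    """A caller-supplied parameter is out of its admissible range."""


class UnsupportedRateError(EcgKitError, ValueError):
    """The sampling rate is too low for the requested spectral analysis."""


class TooShortError(EcgKitError, ValueError):
    """The signal is too short for the requested filter padding."""


class InsufficientCohortError(EcgKitError, ValueError):
    """Too few records to build a cohort reference."""


class ReferenceMismatchError(EcgKitError, ValueError):
    """Record and reference frequency grids cannot be aligned."""


class DegenerateFitError(EcgKitError, ValueError):
    """A fit is refused because the input leaves it underdetermined."""


class DegenerateRecordError(EcgKitError, ValueError):
    """A record is degenerate for the requested statistic (e.g. flat signal)."""


class UndefinedMetricError(EcgKitError, ValueError):
    """A metric is undefined on the given input (e.g. single-class label)."""


class AlignmentError(EcgKitError, ValueError):
    """Paired inputs have mismatched lengths or identifiers."""


class InstabilityError(EcgKitError, RuntimeError):
    """A resampling procedure failed on too large a fraction of draws."""


class InsufficientDataError(EcgKitError, ValueError):
    """Not enough samples per class for the requested procedure."""
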