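"""Exception hierarchy for the DAF-ECoG pipeline."""


class DafEcogError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DafEcogError, ValueError):
    """A configuration field is invalid; the message names the field."""


class GenerationError(DafEcogError):
    """Synthetic-data generation failed (e.g., overlapping trials)."""


class PreprocessingError(DafEcogError):
    """Referencing, epoching, or normalization failed."""


class ParameterError(DafEcogError, ValueError):
    """An analysis parameter is out of range (e.g., notch frequency >= Nyquist)."""


class SelectionError(DafEcogError):
    """Electrode selection cannot be computed (e.g., too few trials)."""


class AssemblyError(DafEcogError):
    """Response-matrix assembly failed (e.g., mismatched time axes)."""


class SensitivityError(DafEcogError):
    """DAF-sensitivity computation cannot proceed (e.g., a single delay condition)."""


class StatTestError(DafEcogError):
    """A pointwise statistical test cannot be formed."""


class WarpingError(DafEcogError):
    """DTW alignment or path transfer failed."""


class NumericalDegeneracyError(DafEcogError):
    """A normalization denominator is non-positive; the message names the electrode."""
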