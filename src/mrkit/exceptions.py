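"""Exception hierarchy.

Everything raised on purpose derives from :class:`MrKitError` so pipeline
code can distinguish analysis failures from programming errors.
"""


class MrKitError(Exception):
    """Base class for all mrkit errors."""


class SumstatsFormatError(MrKitError):
    """A summary-statistics file is structurally unusable (e.g. missing column)."""


class SumstatsValidationError(MrKitError):
    """A summary-statistics row violates a field invariant."""


class HarmonizationError(MrKitError):
    """Exposure and outcome statistics cannot be harmonized."""


class IncompatibleAllelesError(HarmonizationError):
    """Allele pairs disagree even after attempting a strand flip."""


class LdAlignmentError(MrKitError):
    """An LD matrix cannot be aligned to an instrument set."""


class EstimationError(MrKitError):
    """A causal-effect estimator cannot be computed on the given inputs."""


class ConvergenceError(EstimationError):
    """An iterative optimizer failed to converge."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm


class ScaleError(MrKitError):
    """A requested rescaling is invalid for the estimate's units."""


class ConfigError(MrKitError):
    """An analysis plan or study configuration is invalid."""
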