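"""Exception hierarchy.

Everything raised on purpose derives from :class:`FuzzywaveError`, so callers
(and the CLI) can distinguish model/domain failures from genuine bugs.
"""


class FuzzywaveError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FuzzywaveError):
    """A model parameter violates its constraints (e.g. zero spread/dilation)."""


class DegenerateActivationError(FuzzywaveError):
    """No fuzzy rule fires: the summed firing strength underflowed to ~0.

    Indicates the probe point lies far outside the fuzzified input region.
    """


class SchemaError(FuzzywaveError):
    """Tabular input does not match the expected schema."""


class ConfigError(FuzzywaveError):
    """An invalid configuration value."""


class DegenerateDesignError(FuzzywaveError):
    """A regression design with no spread in the predictor."""


class NonPhysicalFitError(FuzzywaveError):
    """A linearized kinetic fit whose coefficients imply non-physical constants."""


class TrainingDivergedError(FuzzywaveError):
    """Gradient descent produced a non-finite loss."""


class SolverError(FuzzywaveError):
    """A root-finding step failed to bracket or converge."""


class ScalingError(FuzzywaveError):
    """Scaling spec cannot be fitted or applied (degenerate column, mismatch)."""
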