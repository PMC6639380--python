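"""Exception hierarchy used across the package."""


class HeterosimError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HeterosimError):
    """A model or domain object violates a structural invariant."""


class FormatError(ValidationError):
    """A model file could not be parsed in the requested dialect."""


class InfeasibleError(HeterosimError):
    """The linear program has no feasible solution."""


class UnboundedError(HeterosimError):
    """The linear program objective is unbounded."""


class ConfigError(HeterosimError):
    """A simulation configuration is invalid."""


class StructuralError(HeterosimError):
    """Two objects that must share structure (e.g. locus sets) do not."""


class StatisticalError(HeterosimError):
    """Not enough data (or variance) to compute a statistic."""


class UndefinedRatioError(HeterosimError):
    """A ratio with a zero denominator was requested."""
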