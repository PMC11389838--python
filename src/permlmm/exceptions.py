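"""Exception hierarchy shared across permlmm modules."""


class PermLmmError(Exception):
    """Base class for all permlmm errors."""


class ParseError(PermLmmError):
    """A file could not be parsed; the message names the offending record."""


class DimensionError(PermLmmError):
    """Inputs have inconsistent shapes or sample counts."""


class AlignmentError(PermLmmError):
    """Sample ids of genotype/phenotype/covariate inputs do not overlap."""


class EmptyGenotypeError(PermLmmError):
    """A filtering step removed every SNP."""


class ConditioningError(PermLmmError):
    """A matrix could not be stabilized within the allowed jitter budget."""


class FitError(PermLmmError):
    """Variance-component estimation failed to find a finite optimum."""
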