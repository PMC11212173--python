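"""Exception types shared across the pipeline stages."""


class McprError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(McprError):
    """Invalid simulation or pipeline configuration."""


class ClassificationError(McprError):
    """A contraceptive method code outside the controlled vocabulary."""


class CodingError(McprError):
    """A raw survey value outside its documented code set."""


class AggregationError(McprError):
    """Community-level aggregation cannot proceed (e.g. no districts)."""


class DegenerateTableError(McprError):
    """A contingency table with a zero expected cell count."""


class FitError(McprError):
    """Model estimation failed (non-convergence, separation, ...)."""
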