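"""Exception types shared across the pipeline."""


class FcgnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(FcgnetError, ValueError):
    """An invalid simulation or pipeline configuration."""


class DegenerateDataError(FcgnetError, ValueError):
    """Data without the variance required by a statistical procedure
    (e.g. constant expression in an ANOVA, zero comparison-group SD)."""


class UndefinedPropertyError(FcgnetError, ValueError):
    """A graph property whose defining formula has a zero denominator
    (e.g. assortativity of a regular graph)."""


class MissingDataError(FcgnetError, ValueError):
    """Required observations absent (missing reference CTs, empty strata)."""
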