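"""Exception hierarchy for the grabld package."""


class GrabldError(Exception):
    """Base class for all grabld errors."""


class ConfigurationError(GrabldError):
    """Invalid option, flag combination, or column mapping."""


class ValidationError(GrabldError):
    """Input data violates a documented invariant."""


class FormatError(GrabldError):
    """A file does not conform to its declared on-disk format."""


class EmptyIntersectionError(GrabldError):
    """No SNPs shared between the genotype panel and the summary table."""


class UndefinedMetricError(GrabldError):
    """A metric is undefined for the given inputs (e.g. AUC with one class)."""
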