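"""Typed error and signal classes shared across the pipeline.

Errors ending in ``Error`` are genuine failures; ``*Signal`` classes mark
expected, recoverable per-gene conditions (a gene with no usable SNPs is
skipped with a reason code, not a crash).
"""


class AdmixTwasError(Exception):
    """Base class for all package errors."""


class FormatError(AdmixTwasError):
    """An input file does not conform to the expected schema."""


class EmptyModelError(AdmixTwasError):
    """A prediction model contains no genes."""


class CovarianceError(AdmixTwasError):
    """An LD reference covariance is inconsistent or invalid."""


class ConfigError(AdmixTwasError):
    """A run or simulation configuration is self-contradictory."""


class GeneSkipSignal(AdmixTwasError):
    """Base for per-gene skip conditions; carries a short reason code."""

    reason = "skipped"

    def __init__(self, gene_id: str, detail: str = ""):
        self.gene_id = gene_id
        self.detail = detail
        super().__init__(f"{gene_id}: {self.reason}" + (f" ({detail})" if detail else ""))


class NoOverlapSignal(GeneSkipSignal):
    """No model SNP could be matched to the GWAS (or the LD reference)."""

    reason = "no-overlap"


class DegenerateVarianceSignal(GeneSkipSignal):
    """Predicted-expression variance is numerically zero."""

    reason = "zero-variance"


class InsufficientDataSignal(AdmixTwasError):
    """Too few observations for the requested statistic (e.g. n < 3 for r)."""
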