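"""Exception hierarchy for the etgwas package."""


class EtgwasError(Exception):
    """Base class for all etgwas-specific errors."""


class ParseError(EtgwasError):
    """A standard-format input (VCF, GFF3, phenotype table) could not be parsed."""


class EmptyInputError(EtgwasError):
    """An input yielded no usable records (e.g. zero biallelic sites)."""


class ConfigError(EtgwasError):
    """Invalid configuration: bad column name, out-of-range parameter, ..."""


class IdMismatchError(EtgwasError):
    """Accession ids in one input are absent from another."""


class DegenerateSnpError(EtgwasError):
    """A SNP is monomorphic (all-ref or all-alt) after pooling; no model fits."""


class InsufficientDataError(EtgwasError):
    """Too few complete observations to compute a statistic (e.g. LD r^2)."""


class NoVariantError(EtgwasError):
    """A gene region contains no variant sites; no haplotype can be built."""
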