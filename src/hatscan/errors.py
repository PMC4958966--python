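"""Exception hierarchy shared across the package."""


class HatscanError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(HatscanError):
    """A sequence contains characters outside its declared alphabet,
    or two sequences with incompatible alphabets were combined."""


class FormatError(HatscanError):
    """A tabular or FASTA input violates its format contract."""


class ConfigurationError(HatscanError):
    """An analysis was configured inconsistently (unknown stage label,
    unmapped taxon, missing anchor, degenerate TE parameters, ...)."""


class ReferenceCdsError(HatscanError):
    """A reference coding sequence is unusable (not a codon multiple,
    or carries an internal stop)."""


class UndefinedRatioError(HatscanError):
    """A ratio was requested against a zero-valued reference."""
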