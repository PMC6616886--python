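"""Exception hierarchy shared across hcrkit."""


class HCRError(Exception):
    """Base class for all hcrkit errors."""


class InputError(HCRError):
    """Invalid or inconsistent user-supplied data."""


class FormatError(HCRError):
    """A file does not conform to its declared format."""


class ConfigurationError(HCRError):
    """Incompatible or invalid parameters."""


class EmptyAssemblyError(InputError):
    """An assembly has no scoreable contigs (e.g. only plasmids)."""


class EmptyProfileError(InputError):
    """A genome yields no valid k-mers at the requested k."""


class GenerationError(HCRError):
    """The synthetic generator cannot satisfy the requested layout."""


class AlignerUnavailableError(HCRError):
    """The configured external aligner executable is not on PATH."""
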