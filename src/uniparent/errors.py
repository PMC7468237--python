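"""Exception hierarchy shared across the package."""


class UniparentError(Exception):
    """Base class for all package-specific errors."""


class FormatError(UniparentError):
    """Malformed input file (unequal record lengths, bad characters, ...)."""


class MetadataError(UniparentError):
    """Inconsistent sample metadata (duplicate ids, missing rows, ...)."""


class DegenerateInputError(UniparentError):
    """Input is syntactically valid but leaves nothing to analyse."""


class ConfigError(UniparentError):
    """Invalid run or scenario configuration."""
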