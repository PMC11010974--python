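"""Exception hierarchy for the pipeline."""


class HspcMapError(Exception):
    """Base class for all package errors."""


class ChannelMapError(HspcMapError):
    """An analysis marker could not be resolved to a channel."""


class FormatError(HspcMapError):
    """A file could not be parsed as FCS."""


class ConfigError(HspcMapError):
    """Configuration schema violation; message lists the offending keys."""


class MetadataError(HspcMapError):
    """Inconsistent per-sample annotations (e.g. duplicate patient id)."""


class GateError(HspcMapError):
    """Invalid polygon gate definition."""


class GateAmbiguityError(HspcMapError):
    """A cell fell into two gates that are required to be disjoint."""


class ParameterError(HspcMapError):
    """Invalid analysis parameter (e.g. perplexity too large for n cells)."""


class DegenerateInputError(HspcMapError):
    """Input without usable variation (e.g. constant matrix for PCA)."""


class ConstantPictureError(HspcMapError):
    """Pearson correlation undefined: a density picture has zero variance."""


class ProtocolError(HspcMapError):
    """Leave-one-out protocol violation (e.g. exclusion empties a group)."""


class DependencyError(HspcMapError):
    """A pipeline stage was requested before its upstream artifacts exist."""
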