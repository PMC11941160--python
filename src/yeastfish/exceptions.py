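class ConfigurationError(ValueError):
    """Inconsistent or incomplete configuration (unknown gene, unmapped channel, ...)."""


class LayoutError(ValueError):
    """Invalid scene geometry (overlapping cells, spots outside footprints)."""


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for the given input (e.g. zero-variance Pearson)."""
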