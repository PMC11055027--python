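"""Exception hierarchy for brixspec."""


class BrixspecError(ValueError):
    """Base class for all brixspec errors."""


class ConfigurationError(BrixspecError):
    """A configuration field violates its invariant; the message names the field."""


class DimensionError(BrixspecError):
    """Array shapes or band counts are incompatible."""


class DegenerateDataError(BrixspecError):
    """Input data admit no valid computation (zero variance, white==black, ...)."""


class EmptySelectionError(BrixspecError):
    """A filtering step left nothing to operate on."""


class LeakageError(BrixspecError):
    """Train and test partitions overlap where they must be disjoint."""
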