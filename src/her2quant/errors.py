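"""Exception types raised across the pipeline."""


class Her2QuantError(Exception):
    """Base class for all package errors."""


class PatchTooCrowdedError(Her2QuantError, ValueError):
    """Cell layout could not be placed without center overlap."""


class DegenerateHistogramError(Her2QuantError, ValueError):
    """Histogram has fewer than two occupied bins; no threshold exists."""


class InvalidInputError(Her2QuantError, ValueError):
    """Input violates an operation's preconditions."""


class NoTumorTilesError(Her2QuantError, ValueError):
    """Slide yielded no tumor tiles to aggregate."""
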