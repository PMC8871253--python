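"""Exception hierarchy for the pipeline."""


class LVRadiomicsError(Exception):
    """Base class for all package errors."""


class ParameterError(LVRadiomicsError, ValueError):
    """An invalid parameter or configuration value."""


class GeometryError(LVRadiomicsError, ValueError):
    """A degenerate or out-of-bounds ROI geometry."""


class DataError(LVRadiomicsError, ValueError):
    """Invalid data passed to an analysis stage (empty mask, single class, ...)."""
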