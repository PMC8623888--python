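"""Exception hierarchy shared across the pipeline stages."""


class GranmorphError(Exception):
    """Base class for all granmorph errors."""


class ValidationError(GranmorphError, ValueError):
    """A specification or input value violates a documented invariant."""


class RenderError(GranmorphError):
    """A particle could not be rasterised inside the requested image extent."""


class MeasurementError(GranmorphError, ValueError):
    """A projection mask or measurement sequence is unusable."""


class DesignError(GranmorphError, ValueError):
    """An experiment design or regression design matrix is unusable."""
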