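"""Exception hierarchy shared by all pipeline stages."""


class CaWaveError(Exception):
    """Base class for all cawave errors."""


class ParameterError(CaWaveError, ValueError):
    """A stage parameter is outside its allowed range."""


class ShapeError(CaWaveError, ValueError):
    """Images in a sequence do not share a single shape."""


class ChannelLabelError(CaWaveError, ValueError):
    """A frame could not be assigned to a channel, or labels are inconsistent."""


class InsufficientDataError(CaWaveError, ValueError):
    """Too few frames or samples for the requested operation."""


class DecayCorrectionError(CaWaveError, RuntimeError):
    """The fitted marker-decay flux is unusable over the sequence span."""


class NoSourceError(CaWaveError, RuntimeError):
    """Automatic source localization found no structure above threshold."""


class DegenerateFitError(CaWaveError, ValueError):
    """A regression cannot be performed (too few or collapsed points)."""


class ModeNotSupportedError(CaWaveError, ValueError):
    """The requested analysis mode is invalid for this kind of input."""
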