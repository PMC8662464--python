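"""Exception hierarchy shared across the package."""


class PedalkinError(ValueError):
    """Base class for all domain errors raised by pedalkin."""


class SessionFormatError(PedalkinError):
    """A session or calibration file does not match the expected dialect."""


class SessionValidationError(PedalkinError):
    """A parsed session violates a structural invariant (ordering, signs...)."""


class InsufficientDataError(PedalkinError):
    """Too few records/samples to perform the requested fit or estimate."""


class UnfittedChannelError(PedalkinError):
    """Prediction was requested from a calibration channel that was never fitted."""
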