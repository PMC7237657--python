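"""Exception hierarchy shared across the pipeline."""


class ImprintLoopError(Exception):
    """Base class for all package errors."""


class ParseError(ImprintLoopError):
    """A text input could not be parsed; message names the offending line."""


class ValidationError(ImprintLoopError):
    """An input violated a documented invariant."""


class UndetectableControlError(ImprintLoopError):
    """Control-template band intensity was zero; the record cannot be normalized."""


class QCFailure(ImprintLoopError):
    """An operation was applied to a nucleus that failed quality control."""
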