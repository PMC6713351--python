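"""Exception hierarchy shared across the pipeline."""


class StromalightError(Exception):
    """Base class for all package errors."""


class FormatError(StromalightError):
    """Input data has the wrong shape, sign, or encoding."""


class DetectionError(StromalightError):
    """Corneal surface could not be detected in enough lateral columns."""


class RangeError(StromalightError):
    """A depth range or offset selection produced an empty result."""


class PreconditionError(StromalightError):
    """An operation's input contract is violated (too few points, bad window)."""


class InferenceError(StromalightError):
    """MCMC failed to produce a usable posterior (non-convergence, singular fit).

    Carries the convergence diagnostics that triggered the failure in
    ``self.diagnostics`` when available.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics
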