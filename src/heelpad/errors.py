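"""Exception hierarchy.

Every stage raises a subclass of :class:`HeelpadError`; the pipeline
orchestrator re-raises with the stage name attached so a failing cohort
member can be traced back to the offending processing step.
"""


class HeelpadError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(HeelpadError, ValueError):
    """A model, gait or cohort parameter violates its physical bounds."""


class NoContactError(HeelpadError):
    """The force channel never reaches the contact-detection threshold."""


class SplitError(HeelpadError):
    """The strain history has no loading/unloading structure to split."""


class DegenerateCurveError(HeelpadError):
    """The stress-strain loop is degenerate (non-positive loading area)."""


class UnidentifiableModelError(HeelpadError):
    """The regressor matrix is rank deficient (e.g. no strain-rate content)."""


class AlignmentError(HeelpadError):
    """Channels read from separate files disagree on frame count."""


class PairingError(HeelpadError):
    """Paired samples have unequal lengths."""


class InsufficientDataError(HeelpadError):
    """Too few observations for the requested statistical procedure."""


class StageError(HeelpadError):
    """Wraps an error from a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}': {original}")
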