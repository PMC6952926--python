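"""Exception hierarchy.

Every error raised by cellmech derives from :class:`CellmechError` so callers
can catch the package's failures without masking programming errors.
"""


class CellmechError(Exception):
    """Base class for all cellmech errors."""


class InvalidParameterError(CellmechError, ValueError):
    """A simulation or analysis parameter violates its contract."""


class LayoutError(CellmechError):
    """Simulated objects (events, puncta) do not fit in the requested space."""


class CurveFormatError(CellmechError):
    """A force-curve file is malformed or lacks required metadata."""


class NoContactError(CellmechError):
    """No tip-sample contact could be located in a segment."""


class FitError(CellmechError):
    """A model fit failed to converge or produced a non-physical result."""


class EmptyMaskError(CellmechError):
    """Image segmentation produced an empty mask."""


class StageError(CellmechError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"stage '{stage}' failed: {original}")
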