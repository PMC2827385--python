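"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`AortaflowError` so the CLI can
abort with the stage name attached.
"""


class AortaflowError(Exception):
    """Base class for all package errors."""


class GeometryError(AortaflowError):
    """Invalid vector/plane arithmetic input (zero vector, bad plane metadata)."""


class DegenerateGeometryError(GeometryError):
    """Two view planes are too close to parallel to reconstruct a 3-D axis."""


class InconsistentProjectionsError(GeometryError):
    """The two planar projections cannot come from a single 3-D direction."""


class InconsistentLandmarksError(GeometryError):
    """Landmark segments nearly cancel; the traced boundaries disagree."""


class NoForwardFlowError(AortaflowError):
    """No pixel inside the ROI flows forward along the reference axis.

    Usually means the wrong cardiac phase was selected or the channel
    axis points retrograde.
    """


class ValidationError(AortaflowError):
    """A config, file, or table failed schema/consistency validation."""


class StageError(AortaflowError):
    """Pipeline stage failure carrying the stage name and subject id."""

    def __init__(self, stage: str, subject: str | None, cause: Exception):
        self.stage = stage
        self.subject = subject
        self.cause = cause
        where = f"stage={stage}" + (f" subject={subject}" if subject else "")
        super().__init__(f"{where}: {cause}")
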