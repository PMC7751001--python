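"""Exception hierarchy for the lumbosacral-canal morphometrics pipeline."""


class LsomorphError(Exception):
    """Base class for all package errors."""


class InvalidInputError(LsomorphError):
    """A precondition on user-supplied data was violated."""


class WindowOutOfRangeError(LsomorphError):
    """The analysis window around the maximum-area section does not fit.

    Parameters
    ----------
    specimen_id : str
        Offending specimen.
    missing : int
        How many sections the profile is short of, on the tight side.
    """

    def __init__(self, specimen_id: str, missing: int, message: str | None = None):
        self.specimen_id = specimen_id
        self.missing = missing
        super().__init__(
            message
            or f"analysis window does not fit for specimen {specimen_id!r}: "
            f"{missing} section(s) missing beyond the maximum-area section"
        )


class OpenContourError(LsomorphError):
    """A section's lumen boundary is open to the image border after gap closing."""

    def __init__(self, plane_index: int, message: str | None = None):
        self.plane_index = plane_index
        super().__init__(
            message
            or f"open lumen contour at plane index {plane_index}: "
            "fill reaches the image border (increase the closing radius?)"
        )


class InvalidSpecError(LsomorphError):
    """A phantom specification is geometrically inconsistent."""


class InvalidConfigError(LsomorphError):
    """A cohort or pipeline configuration is invalid."""


class ParseError(LsomorphError):
    """A tabular or tree input file failed validation; carries row context."""

    def __init__(self, message: str, rows=None):
        self.rows = list(rows) if rows is not None else None
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


class StageError(LsomorphError):
    """A pipeline stage failed; tagged with the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"[{stage}] {cause}")
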