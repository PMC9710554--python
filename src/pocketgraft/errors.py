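"""Exception hierarchy.

Each failure class maps to a distinct CLI exit code (see :mod:`pocketgraft.cli`).
"""


class PocketGraftError(Exception):
    """Base class for all package errors."""


class ConfigError(PocketGraftError):
    """Invalid or unknown configuration keys/values."""


class FormatError(PocketGraftError):
    """Unparseable input file."""


class EmptyInputError(PocketGraftError):
    """Input contains no usable polymer content."""


class SchemaVersionError(PocketGraftError):
    """Artifact JSON schema version mismatch."""


class GeometryError(PocketGraftError):
    """Degenerate geometry (collinear atoms, zero-length vectors, ...)."""


class FrameError(GeometryError):
    """Internal coordinate frame could not be constructed."""


class FixtureError(PocketGraftError):
    """Infeasible synthetic-fixture placement request."""


class AssignmentError(PocketGraftError):
    """Residue type multisets do not match in an assignment problem."""


class GraftingError(PocketGraftError):
    """Pocket grafting failure."""


class InfeasibleGraftError(GraftingError):
    """No conflict-free combination of pocket grafts exists.

    ``conflicts`` lists the binder positions contested by more than one graft.
    """

    def __init__(self, message: str, conflicts=()):
        super().__init__(message)
        self.conflicts = list(conflicts)


class PipelineError(PocketGraftError):
    """A pipeline stage failed; the stage name is included in the message."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
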