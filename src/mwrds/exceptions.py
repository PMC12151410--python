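"""Exception hierarchy for the mwrds package.

Every error raised by the library derives from :class:`MWRDSError` so callers
can catch the package's failures with a single except clause. The CLI maps
these onto nonzero exit codes with the failing pipeline stage attached.
"""


class MWRDSError(Exception):
    """Base class for all mwrds errors."""


class ValidationError(MWRDSError, ValueError):
    """Invalid input data: non-finite cells, duplicate ids, bad labels."""


class AlignmentError(MWRDSError, ValueError):
    """Two per-feature objects do not share the same feature set/order."""


class ConfigurationError(MWRDSError, ValueError):
    """A configuration value is out of its admissible range."""


class InsufficientClassError(MWRDSError, ValueError):
    """A class has too few samples for the requested operation."""


class FitFailureError(MWRDSError, RuntimeError):
    """An underlying solver failed to converge; carries diagnostics."""


class EmptyRefinementError(MWRDSError, RuntimeError):
    """The L1 refinement zeroed every coefficient and no rescue applied."""


class StageError(MWRDSError, RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
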