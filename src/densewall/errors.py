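"""Exception hierarchy.

Validation-type errors (bad parameters, malformed files, inconsistent
configuration) derive from :class:`ValidationError`; failures of the
computation itself (degenerate geometry, unresolvable tracking, statistics
on unusable designs) derive from :class:`ComputationError`.  The CLI maps
the two branches to distinct exit codes.
"""


class DenseWallError(Exception):
    """Base class for all package errors."""


class ValidationError(DenseWallError):
    """Input failed a contract check before any computation ran."""


class ParameterError(ValidationError):
    """A numeric or structural parameter is out of its allowed range."""


class FormatError(ValidationError):
    """An on-disk container is missing keys or malformed."""


class ConfigurationError(ValidationError):
    """A pipeline run configuration is incomplete or inconsistent."""


class ComputationError(DenseWallError):
    """The computation could not proceed on otherwise well-formed input."""


class GeometryError(ComputationError):
    """A curve or polygon violates a geometric invariant (e.g. self-intersects)."""


class DegenerateInputError(ComputationError):
    """Input collapses the problem (empty mask, zero-length segment, ...)."""


class TrackingError(ComputationError):
    """A seeded point could not be displaced through the field."""


class EncodingConfigurationError(ComputationError):
    """The displacement-encoding direction set does not span the requested space."""


class StatisticsError(ComputationError):
    """A statistical routine received an unusable design or degenerate data."""


class AnalysisError(ComputationError):
    """A summary stage found an empty or inconsistent partition."""


class StageError(ComputationError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage
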