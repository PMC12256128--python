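"""Exception types shared across the package."""


class RpvAuditError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RpvAuditError):
    """A delimited file does not conform to the expected schema."""


class IntegrityError(RpvAuditError):
    """Input data violates an integrity constraint (e.g. duplicate ids,
    a prediction logged for a specimen that was in that run's training set)."""


class EmptyResultError(RpvAuditError):
    """An operation that must return data returned nothing.

    Carries ``counts``: the per-class specimen counts observed, so callers
    can report why the filter removed everything.
    """

    def __init__(self, message: str, counts: dict | None = None):
        super().__init__(message)
        self.counts = dict(counts) if counts else {}


class InvalidStateError(RpvAuditError):
    """The pipeline was invoked in an order that violates its contract
    (e.g. partitioning a class smaller than the per-run sample size)."""


class TrainingFailureError(RpvAuditError):
    """Optimisation produced a non-finite loss.  ``epoch`` is the 0-based
    index of the epoch (over the whole trace) at which it occurred."""

    def __init__(self, message: str, epoch: int):
        super().__init__(message)
        self.epoch = epoch
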