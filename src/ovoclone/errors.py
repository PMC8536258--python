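"""Exception hierarchy.

Every stage raises a subclass of :class:`OvocloneError` so that pipeline
drivers can surface the failing stage and offending quantity uniformly.
"""


class OvocloneError(Exception):
    """Base class for all package errors."""


class MalformedRecordError(OvocloneError):
    """A per-ovariole record violates its structural invariants."""


class EmptyInputError(OvocloneError):
    """An operation that needs at least one marked ovariole received none."""


class DegenerateInputError(OvocloneError):
    """Input lies on a boundary where the quantity is undefined."""


class UsageError(OvocloneError):
    """An operation was called on data it is not meant for."""


class InfeasibleFrequenciesError(OvocloneError):
    """No lineage-frequency solution exists in [0, 1] for the observations."""

    def __init__(self, message: str, equation: str | None = None):
        super().__init__(message)
        self.equation = equation


class EstimationFailureError(OvocloneError):
    """No grid value of the single-lineage fraction admits a solution."""


class UndefinedCompositionError(OvocloneError):
    """Double-clone composition weights are 0/0 for the requested category."""


class InconsistentInputsError(OvocloneError):
    """Subtraction-based disaggregation produced a negative cell budget."""


class NoFSCProductionError(OvocloneError):
    """No lineage type produces FSCs, so the census cannot be normalized."""


class ConfigError(OvocloneError):
    """A simulation or run configuration is invalid."""
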