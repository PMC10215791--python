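"""Package-wide error types."""


class VesicaError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(VesicaError, ValueError):
    pass


class OutOfViewError(VesicaError, ValueError):
    """Phantom cross-section does not fit the imaged field of view."""


class BudgetViolationError(VesicaError, RuntimeError):
    """Model exceeds the trainable-parameter budget."""


class NoRegionError(VesicaError, ValueError):
    """An operation requiring a non-empty mask received an empty one."""


class DegenerateRegionError(VesicaError, ValueError):
    """A chord/axis measurement could not be taken from the region."""


class GraphMismatchError(VesicaError, RuntimeError):
    """Weight sets do not come from the same model graph."""


class DataError(VesicaError, ValueError):
    """Dataset/manifest is missing required columns or labels."""
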