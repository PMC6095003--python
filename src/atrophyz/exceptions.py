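"""Exception types shared across the pipeline stages."""


class AtrophyzError(Exception):
    """Base class for all package errors."""


class ConfigError(AtrophyzError, ValueError):
    """Invalid generator or pipeline configuration."""


class ValidationError(AtrophyzError, ValueError):
    """Input data violates a documented precondition."""


class FitError(AtrophyzError, RuntimeError):
    """A normative model component could not be fitted."""


class EstimationError(AtrophyzError, RuntimeError):
    """A required intensity/moment estimate is unavailable."""


class PlacementError(AtrophyzError, RuntimeError):
    """Lesion blobs could not be placed in the phantom."""


class SchemaError(AtrophyzError, ValueError):
    """A cohort table does not match the documented column dictionary."""
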