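"""Exception hierarchy for the stepped-care cost-utility model."""


class SteppedCareError(Exception):
    """Base class for all package errors."""


class SchemaError(SteppedCareError):
    """A parameter file is missing a required field or has the wrong shape."""


class ValidationError(SteppedCareError):
    """A parameter value violates a model invariant."""


class ParameterLookupError(SteppedCareError, KeyError):
    """A dotted parameter identifier does not resolve to a stored value."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message plain
        return Exception.__str__(self)


class ConfigurationError(SteppedCareError):
    """A run was requested with an inconsistent or incomplete configuration."""


class GenerationError(SteppedCareError):
    """A synthetic-parameter configuration cannot produce a valid parameter set."""


class ConsistencyError(SteppedCareError):
    """Two pipeline stages were combined on mismatched inputs."""
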