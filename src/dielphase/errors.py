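"""Exception hierarchy shared across the package."""


class DielphaseError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(DielphaseError, ValueError):
    """Input violates a documented precondition (shape, sign, schema ...)."""


class NonPositiveGrowthError(DielphaseError):
    """The fitted effective growth rate K' is not positive."""


class NoExponentialPhaseError(DielphaseError):
    """No candidate window of the growth curve is acceptably log-linear."""


class ConfigError(DielphaseError):
    """A pipeline configuration file is malformed or references missing inputs."""
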