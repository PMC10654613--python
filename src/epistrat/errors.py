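"""Typed errors used across the pipeline.

Four families: configuration (bad parameters), data contract (inputs that
violate a documented precondition), numerical (degenerate or non-convergent
computations), dependency (a pipeline stage requested before its producer).
"""


class EpistratError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpistratError):
    """Invalid or infeasible configuration values."""


class DataContractError(EpistratError):
    """Input data violates a documented precondition."""


class NumericalError(EpistratError):
    """Degenerate numerical situation (no events, constant input, ...)."""


class DependencyError(EpistratError):
    """A pipeline stage was requested before the stage that produces its input."""
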