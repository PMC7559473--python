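"""Exception hierarchy for thermalsteps.

Every error raised on purpose by the package derives from
:class:`ThermalStepsError`, so callers can catch one type at pipeline level
while tests can assert on the specific subclass.
"""


class ThermalStepsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ThermalStepsError):
    """A config object violates its invariants (bad grid size, M < 1, ...)."""


class DataError(ThermalStepsError):
    """Input data violate a structural precondition (unsorted timestamps, ...)."""


class SpecificationError(ThermalStepsError):
    """A model specification names unknown terms or forbidden structure."""


class KernelError(ThermalStepsError):
    """Too few usable steps to build a movement kernel for an animal."""


class DomainError(ThermalStepsError):
    """A numeric argument lies outside the operation's domain."""


class ConvergenceError(ThermalStepsError):
    """An optimisation failed and no usable result exists."""
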