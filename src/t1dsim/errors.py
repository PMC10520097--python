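"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation problems exit 2, input
coverage gaps exit 3, fixture integrity failures exit 4.
"""


class T1DSimError(Exception):
    """Base class for all package errors."""


class ValidationError(T1DSimError, ValueError):
    """An input value or parameter violates a documented invariant."""


class ParameterError(ValidationError):
    """A function parameter is out of its allowed domain."""


class CoverageError(T1DSimError, KeyError):
    """A required (age, year) cell is missing from an input surface."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return self.args[0] if self.args else ""


class FitError(T1DSimError, RuntimeError):
    """Insufficient data to fit a model component."""


class ImputationError(T1DSimError, RuntimeError):
    """No usable donor pool at any stratum-widening level."""


class ScenarioError(T1DSimError, ValueError):
    """A projection scenario is infeasible with the supplied inputs."""


class IntegrityError(T1DSimError, RuntimeError):
    """A shipped fixture fails its checksum."""


class UndefinedShareError(ValidationError):
    """Mortality shares requested with a zero total."""
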