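"""Exception hierarchy shared across the package."""


class BrainDynError(Exception):
    """Base class for all braindyn errors."""


class NamingError(BrainDynError, ValueError):
    """Duplicate or otherwise invalid component name."""


class CompositionError(BrainDynError, ValueError):
    """Illegal model composition (e.g. a cycle in the component tree)."""


class PathError(BrainDynError, KeyError):
    """A dotted state path did not resolve to a state variable."""


class DivergenceError(BrainDynError, RuntimeError):
    """A state variable became non-finite during a simulation.

    Carries the step index and the offending variable's path so the failure
    is debuggable rather than silently propagating NaNs.
    """

    def __init__(self, step: int, path: str):
        self.step = step
        self.path = path
        super().__init__(
            f"non-finite value in state '{path}' at step {step}; aborting run"
        )


class GridError(BrainDynError, ValueError):
    """Malformed parameter grid for a batch run."""


class TableauError(BrainDynError, ValueError):
    """Inconsistent Butcher tableau."""


class StiffnessError(BrainDynError, RuntimeError):
    """Adaptive step-size controller underflowed its minimum step."""


class ParameterError(BrainDynError, ValueError):
    """Parameter outside its legal range."""


class ShapeError(BrainDynError, ValueError):
    """Operand dimensions incompatible with an operator."""


class ConfigError(BrainDynError, ValueError):
    """Invalid or incomplete run configuration."""
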