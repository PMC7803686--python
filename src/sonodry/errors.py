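"""Exception hierarchy shared across the package."""


class SonodryError(Exception):
    """Base class for all package-specific errors."""


class DomainError(SonodryError, ValueError):
    """An input lies outside the physical/mathematical domain of a correlation."""


class EstimationError(SonodryError, RuntimeError):
    """A parameter estimator could not produce a valid estimate."""


class SimulationError(SonodryError, RuntimeError):
    """The PDE solver failed or a solution invariant was breached."""
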