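"""Exception hierarchy for the C4 photosynthesis model."""


class C4ModelError(Exception):
    """Base class for all model-specific errors."""


class DomainError(C4ModelError, ValueError):
    """An input lies outside the physical/mathematical domain of an operation."""


class DegenerateInputError(C4ModelError, ValueError):
    """A quadratic has no real root for the given parameter combination."""


class InfeasibleError(C4ModelError, ValueError):
    """The requested state cannot be reached by the model (e.g. demanded
    carboxylation exceeds capacity, or a measured assimilation rate is
    unattainable at any electron transport rate)."""


class SolverError(C4ModelError, RuntimeError):
    """An iterative solver failed to bracket or converge."""


class ConfigError(C4ModelError, ValueError):
    """A parameter configuration contains unknown keys or invalid values."""


class WeakIdentifiabilityWarning(UserWarning):
    """Issued when a least-squares design leaves the free parameters nearly
    collinear (near-singular curvature matrix)."""
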