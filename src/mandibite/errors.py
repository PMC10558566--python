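"""Exception hierarchy for mandibite."""


class MandibiteError(Exception):
    """Base class for all package errors."""


class ParameterError(MandibiteError, ValueError):
    """A parameter violates its documented constraints.

    The message names the offending field.
    """


class TopologyError(MandibiteError):
    """The mesh is not watertight / not a valid tetrahedral complex."""


class MeshQualityError(MandibiteError):
    """Degenerate (non-positive volume) elements; carries their indices."""

    def __init__(self, message, element_ids=None):
        super().__init__(message)
        self.element_ids = [] if element_ids is None else list(element_ids)


class ConstraintError(MandibiteError):
    """Boundary conditions leave rigid-body modes / singular system."""


class ConfigurationError(MandibiteError):
    """A scenario or run configuration references something the mesh lacks."""


class ScenarioExclusionError(ConfigurationError):
    """An apical-tooth scenario was requested for an apical-incapable specimen."""


class DegenerateFieldError(MandibiteError):
    """A stress field is degenerate (all-zero, empty, zero reference scale)."""


class NonConvergenceError(MandibiteError):
    """A refinement ladder did not converge; carries the per-probe trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace
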