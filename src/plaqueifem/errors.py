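"""Exception hierarchy for the iFEM pipeline."""


class PlaqueIfemError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PlaqueIfemError, ValueError):
    """Invalid configuration (wrong constant count, bad sampling, ...)."""


class GeometryError(PlaqueIfemError, ValueError):
    """Geometrically impossible phantom specification or meshing failure."""


class OutOfRangeError(PlaqueIfemError, ValueError):
    """Input outside the supported physical range (e.g. compressive stretch)."""


class FESolverError(PlaqueIfemError, RuntimeError):
    """Newton divergence or singular system in the forward model.

    Carries ``last_converged_pressure_kpa`` so the optimizer can convert the
    failure into a penalized evaluation instead of aborting the search.
    """

    def __init__(self, message, last_converged_pressure_kpa=None):
        super().__init__(message)
        self.last_converged_pressure_kpa = last_converged_pressure_kpa
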