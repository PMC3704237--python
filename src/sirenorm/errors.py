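"""Exception hierarchy shared across the package."""


class SirenormError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SirenormError, ValueError):
    """A configuration value is out of its admissible range."""


class SimulationError(SirenormError):
    """The generative model produced an inadmissible dataset."""


class QcError(SirenormError):
    """Quality control cannot proceed (e.g. every individual removed)."""


class PedigreeError(SirenormError):
    """Pedigree is cyclic or references an unknown individual."""


class DegenerateDataError(SirenormError):
    """Input data carry no usable variation (zero SD, all missing, ...)."""


class IdentifiabilityError(SirenormError):
    """The record structure cannot identify the requested model."""


class ConvergenceError(SirenormError):
    """REML optimisation failed to converge; carries the best state found.

    Attributes
    ----------
    best_fit : object or None
        Best-so-far fit object, if one could be assembled.
    """

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit
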