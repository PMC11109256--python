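"""Exception hierarchy shared across the package."""


class DlaError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DlaError, ValueError):
    """An argument is outside its documented domain."""


class GeometryError(DlaError):
    """A lung mask cannot be partitioned into zones."""


class CoverageError(DlaError):
    """A required zone (or image id) is missing from the inputs."""


class StratificationError(DlaError):
    """A class has too few images to be spread over the requested folds."""


class DataError(DlaError):
    """A training or validation split is unusable (e.g. empty)."""


class DivergenceError(DlaError):
    """The training loss became non-finite."""


class DegenerateReferenceError(DlaError):
    """The histogram-matching reference image is constant."""
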