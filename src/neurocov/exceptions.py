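"""Exception types raised across the package."""


class NeurocovError(Exception):
    """Base class for package-specific errors."""


class StabilityError(NeurocovError, ValueError):
    """Recurrent coupling matrix is unstable (spectral radius too close to 1)."""


class DimensionError(NeurocovError, ValueError):
    """Shapes of matrices / vectors are inconsistent."""


class UndefinedRatioError(NeurocovError, ZeroDivisionError):
    """Relative variability rho = var/mean**2 undefined because the mean is zero."""


class TooFewTrialsError(NeurocovError, ValueError):
    """At least two trials are required to estimate a noise covariance."""


class TooFewWindowsError(NeurocovError, ValueError):
    """At least two count windows are required to estimate a count covariance."""


class TooFewStimuliError(NeurocovError, ValueError):
    """The operation needs more stimuli than the dataset provides."""


class DegenerateAbscissaError(NeurocovError, ValueError):
    """Moment-line fit impossible: the population-averaged response is constant."""


class InfeasibleMomentsError(NeurocovError, ValueError):
    """Moment matching produced parameters outside their feasible range."""


class NonPositiveSemidefiniteError(NeurocovError, ValueError):
    """A covariance matrix is too far from positive semidefinite to sample from."""


class MalformedFileError(NeurocovError, ValueError):
    """A dataset file does not conform to the expected on-disk format."""
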