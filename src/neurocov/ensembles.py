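"""Random network and stimulus ensembles.

Rather than fitting individual connections, circuits are described by
*ensembles*: coupling-matrix entries drawn i.i.d. from a normal distribution
with mean ``mean_w`` and standard deviation ``sd_w``, and stimulus drive
vectors drawn from a normal distribution across neurons and stimuli.  The
relative variability ``rho = var/mean^2`` of the matrix entries (and its
input analogue ``rho_ext``) are the effective parameters that control the
population-averaged correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .architectures import STABILITY_RADIUS, CouplingSpec, StimulusDrive, spectral_radius
from .exceptions import StabilityError, UndefinedRatioError

_TARGET_TO_KIND = {
    "direct_G": "recurrent_direct",
    "effective_B": "recurrent_effective",
    "feedforward_F": "feedforward",
}


@dataclass(frozen=True)
class NetworkEnsembleParams:
    """I.i.d.-normal ensemble of coupling matrices."""

    n: int
    mean_w: float
    sd_w: float
    target: Literal["direct_G", "effective_B", "feedforward_F"] = "effective_B"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sd_w < 0:
            raise ValueError("sd_w must be nonnegative")
        if self.target not in _TARGET_TO_KIND:
            raise ValueError(f"unknown target {self.target!r}")

    @property
    def rho(self) -> float:
        """Nominal relative variability var/mean^2 of the entries."""
        if self.mean_w == 0:
            raise UndefinedRatioError("rho undefined for zero mean weight")
        return (self.sd_w / self.mean_w) ** 2


@dataclass(frozen=True)
class StimulusEnsembleParams:
    """Random stimulus ensemble: normal drive vectors with optional shared component.

    ``c_in`` is the input signal correlation: the across-stimulus correlation
    between the mean drives of two different neurons.
    """

    n_neurons: int
    n_stimuli: int
    mean_rext: float
    var_rext: float
    c_in: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neurons < 1 or self.n_stimuli < 1:
            raise ValueError("counts must be >= 1")
        if self.var_rext < 0:
            raise ValueError("var_rext must be nonnegative")
        if not 0 <= self.c_in < 1:
            raise ValueError("c_in must lie in [0, 1)")

    @property
    def rho_ext(self) -> float:
        if self.mean_rext == 0:
            raise UndefinedRatioError("rho_ext undefined for zero mean input")
        return self.var_rext / self.mean_rext**2


def sample_network(params: NetworkEnsembleParams, max_tries: int = 100) -> CouplingSpec:
    """Draw a coupling matrix with i.i.d. normal entries.

    For ``direct_G`` the draw is repeated (up to ``max_tries``) until the
    spectral radius is below the stability threshold; dense positive matrices
    have spectral radius close to ``n * mean_w``, so strongly coupled direct
    ensembles may admit no stable sample.

    Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    kind = _TARGET_TO_KIND[params.target]
    for _ in range(max_tries):
        m = rng.normal(params.mean_w, params.sd_w, size=(params.n, params.n))
        if kind != "recurrent_direct" or spectral_radius(m) < STABILITY_RADIUS:
            return CouplingSpec(kind=kind, matrix=m)
    raise StabilityError(
        f"no stable direct coupling matrix found in {max_tries} draws "
        f"(n={params.n}, mean_w={params.mean_w}, sd_w={params.sd_w}); "
        f"note the spectral radius of a dense positive matrix is ~ n*mean_w"
    )


def sample_stimulus_ensemble(params: StimulusEnsembleParams) -> list[StimulusDrive]:
    """Draw a set of random stimulus drive vectors.

    Construction: ``r_ext,i(s) = mean + sd * (sqrt(1 - c_in) xi_i(s)
    + sqrt(c_in) eta(s))`` with ``xi`` i.i.d. per neuron and stimulus and
    ``eta`` shared across neurons within a stimulus — the minimal
    exchangeable construction with pairwise input correlation ``c_in``.
    Input variances follow Poisson statistics, ``v_ext = |r_ext|``.
    """
    rng = np.random.default_rng(params.seed)
    sd = np.sqrt(params.var_rext)
    private = rng.standard_normal((params.n_stimuli, params.n_neurons))
    shared = rng.standard_normal((params.n_stimuli, 1))
    r = params.mean_rext + sd * (
        np.sqrt(1.0 - params.c_in) * private + np.sqrt(params.c_in) * shared
    )
    return [StimulusDrive.poisson(r[s], stimulus_id=s) for s in range(params.n_stimuli)]


def relative_variability(values: np.ndarray) -> float:
    """Relative variability ``rho = var(values) / mean(values)^2``.

    Uses the population variance (divisor ``n``) over all entries, diagonal
    included for matrices.
    """
    v = np.asarray(values, dtype=float).ravel()
    mean = v.mean()
    if mean == 0:
        raise UndefinedRatioError("relative variability undefined for zero mean")
    return float(v.var() / mean**2)
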