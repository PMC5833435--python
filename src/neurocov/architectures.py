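"""Closed-form spike-count statistics for linearly interacting Poisson circuits.

Three prototypical architectures generate correlated trial-to-trial
variability in a population of Poisson-spiking neurons:

* **Recurrent network** — each neuron's rate is its external drive plus
  kernel-filtered recurrent spikes (a multivariate Hawkes process).  With
  integrated coupling matrix ``G`` (spectral radius < 1), the steady-state
  rates are ``r = (I - G)^-1 r_ext`` and the large-window spike-count
  covariance, normalised by the window length, is
  ``C = B (D[r + a] + D[V_ext]) B^T`` with transfer matrix
  ``B = (I - G)^-1``.  Internal Poisson noise is filtered by the network and
  is therefore correlated.

* **Feed-forward network with shared inputs** — output neurons pool a common
  bank of input spike trains through weights ``F``:
  ``r = F r_ext`` and ``C = F D[V_ext] F^T + D[r + a]``.  Only the shared
  input noise is correlated; the output Poisson noise stays diagonal.

* **Shared gain fluctuations** — the whole population's rate is modulated by
  a common multiplicative signal with unit mean and variance ``V_ext``:
  ``C = D[r + a] + (r + a)(r + a)^T V_ext``, so pairwise covariances are
  proportional to the product of the two firing rates.

The scalar offset ``a`` accounts for responses measured relative to
spontaneous activity (baseline-relative rates may be negative, but the
*true* rates entering the Poisson variance are ``r + a``).

Population-averaged predictions (the mean variance ``<C_ii>``, the mean
pairwise covariance ``<C_ij>_{i != j}``, and the average noise / signal
correlation coefficients) follow from treating the coupling matrix as a
random matrix with i.i.d. entries; see :func:`predicted_population_moments`
and :func:`predicted_average_correlations`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np

from .exceptions import DimensionError, StabilityError

#: Reject recurrent coupling matrices whose spectral radius reaches this value;
#: the steady-state rates and covariances diverge at radius 1.
STABILITY_RADIUS = 0.999

CouplingKind = Literal["recurrent_direct", "recurrent_effective", "feedforward"]


@dataclass(frozen=True)
class CouplingSpec:
    """Integrated interaction matrix of a circuit.

    Parameters
    ----------
    kind
        ``recurrent_direct`` for the direct coupling matrix ``G``,
        ``recurrent_effective`` for the effective (transfer) matrix ``B``
        sampled directly, ``feedforward`` for the projection matrix ``F``.
    matrix
        Square ``(n, n)`` array of integrated kernel weights (dimensionless).
    """

    kind: CouplingKind
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise DimensionError(f"coupling matrix must be square, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValueError("coupling matrix contains non-finite entries")
        object.__setattr__(self, "matrix", m)
        if self.kind == "recurrent_direct":
            radius = spectral_radius(m)
            if radius >= STABILITY_RADIUS:
                raise StabilityError(
                    f"spectral radius {radius:.4f} >= {STABILITY_RADIUS}; "
                    "the recurrent network has no stationary state"
                )

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class StimulusDrive:
    """External drive for one stimulus.

    ``r_ext`` is the mean external input per neuron (spikes/s; may be negative
    for baseline-relative inputs); ``v_ext`` is the normalised variance of the
    windowed input (spikes^2/s scale, i.e. same units as the normalised count
    covariance).  For Poisson input spike trains ``v_ext = |r_ext|``.
    """

    r_ext: np.ndarray
    v_ext: np.ndarray
    stimulus_id: object = None

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.r_ext, dtype=float))
        v = np.atleast_1d(np.asarray(self.v_ext, dtype=float))
        if r.shape != v.shape:
            raise DimensionError("r_ext and v_ext must have the same length")
        if np.any(v < 0):
            raise ValueError("v_ext entries must be nonnegative")
        object.__setattr__(self, "r_ext", r)
        object.__setattr__(self, "v_ext", v)

    @classmethod
    def poisson(cls, r_ext, stimulus_id=None) -> "StimulusDrive":
        """Drive with Poisson input statistics, ``v_ext = |r_ext|``."""
        r = np.atleast_1d(np.asarray(r_ext, dtype=float))
        return cls(r_ext=r, v_ext=np.abs(r), stimulus_id=stimulus_id)

    @property
    def n(self) -> int:
        return self.r_ext.shape[0]


@dataclass(frozen=True)
class MomentSet:
    """First and second spike-count moments for one stimulus.

    ``rates`` is the mean (baseline-relative) response vector in spikes/s and
    ``cov`` the normalised count covariance (spikes^2/s, window-normalised).
    ``offset_a`` records the baseline added to the rates inside the
    covariance formulas.
    """

    rates: np.ndarray
    cov: np.ndarray
    offset_a: float = 0.0
    source: Literal["analytic", "empirical"] = "analytic"
    stimulus_id: object = None

    def __post_init__(self) -> None:
        r = np.atleast_1d(np.asarray(self.rates, dtype=float))
        c = np.asarray(self.cov, dtype=float)
        if c.shape != (r.size, r.size):
            raise DimensionError(
                f"cov shape {c.shape} inconsistent with {r.size} rates"
            )
        scale = max(np.abs(c).max(), 1.0)
        if np.abs(c - c.T).max() > 1e-10 * scale:
            raise ValueError("covariance matrix is not symmetric")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "cov", 0.5 * (c + c.T))

    @property
    def n(self) -> int:
        return self.rates.shape[0]


def spectral_radius(matrix: np.ndarray) -> float:
    """Largest eigenvalue magnitude of a square matrix."""
    return float(np.abs(np.linalg.eigvals(np.asarray(matrix, dtype=float))).max())


def transfer_matrix(coupling: CouplingSpec) -> np.ndarray:
    """Effective coupling ``B = (I - G)^-1`` of a recurrent network.

    ``B`` maps external drive onto steady-state rates and collects direct plus
    all indirect interaction paths (the Neumann series ``sum_k G^k``).

    Raises
    ------
    StabilityError
        If the spectral radius of ``G`` is at or above ``STABILITY_RADIUS``.
    """
    if coupling.kind != "recurrent_direct":
        raise ValueError("transfer_matrix expects a direct coupling matrix G")
    g = coupling.matrix
    radius = spectral_radius(g)
    if radius >= STABILITY_RADIUS:
        raise StabilityError(f"spectral radius {radius:.4f} >= {STABILITY_RADIUS}")
    return np.linalg.inv(np.eye(g.shape[0]) - g)


def steady_state_rates(coupling: CouplingSpec, drive: StimulusDrive) -> np.ndarray:
    """Mean population rates for a given drive.

    For a direct recurrent matrix solves ``(I - G) r = r_ext``; for an
    effective or feed-forward matrix applies it directly, ``r = M r_ext``.
    """
    if coupling.n != drive.n:
        raise DimensionError(
            f"coupling is {coupling.n}x{coupling.n} but drive has {drive.n} entries"
        )
    if coupling.kind == "recurrent_direct":
        g = coupling.matrix
        radius = spectral_radius(g)
        if radius >= STABILITY_RADIUS:
            raise StabilityError(f"spectral radius {radius:.4f} >= {STABILITY_RADIUS}")
        return np.linalg.solve(np.eye(coupling.n) - g, drive.r_ext)
    return coupling.matrix @ drive.r_ext


def _check_drive_diagonal(inner_diag: np.ndarray) -> None:
    if np.any(inner_diag < 0):
        warnings.warn(
            "some diagonal drive entries r_i + a + v_ext_i are negative; "
            "the analytic covariance is not guaranteed positive semidefinite",
            RuntimeWarning,
            stacklevel=3,
        )


def recurrent_covariance(
    B: np.ndarray,
    rates: np.ndarray,
    v_ext: np.ndarray | float = 0.0,
    offset_a: float = 0.0,
) -> np.ndarray:
    """Normalised count covariance of the recurrent network.

    ``C = B (D[r + a] + D[v_ext]) B^T``: both the internal Poisson noise
    (variance = rate) and the external input noise are filtered by the
    effective coupling, hence correlated.
    """
    B = np.asarray(B, dtype=float)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    v = np.broadcast_to(np.asarray(v_ext, dtype=float), rates.shape)
    if np.any(v < 0):
        raise ValueError("v_ext entries must be nonnegative")
    if B.shape != (rates.size, rates.size):
        raise DimensionError(f"B shape {B.shape} inconsistent with {rates.size} rates")
    inner = rates + offset_a + v
    _check_drive_diagonal(inner)
    c = (B * inner) @ B.T
    return 0.5 * (c + c.T)


def feedforward_covariance(
    F: np.ndarray,
    rates: np.ndarray,
    v_ext: np.ndarray | float = 0.0,
    offset_a: float = 0.0,
) -> np.ndarray:
    """Normalised count covariance of the shared-input feed-forward network.

    ``C = F D[v_ext] F^T + D[r + a]``: only the shared input fluctuations are
    correlated; the output Poisson noise contributes to the diagonal only.
    """
    F = np.asarray(F, dtype=float)
    rates = np.atleast_1d(np.asarray(rates, dtype=float))
    v = np.broadcast_to(np.asarray(v_ext, dtype=float), rates.shape)
    if np.any(v < 0):
        raise ValueError("v_ext entries must be nonnegative")
    if F.shape != (rates.size, rates.size):
        raise DimensionError(f"F shape {F.shape} inconsistent with {rates.size} rates")
    _check_drive_diagonal(rates + offset_a + v)
    c = (F * v) @ F.T + np.diag(rates + offset_a)
    return 0.5 * (c + c.T)


def gain_covariance(
    rates: np.ndarray,
    v_ext_scalar: float,
    offset_a: float = 0.0,
) -> np.ndarray:
    """Normalised count covariance under shared multiplicative gain fluctuations.

    ``C = D[r + a] + (r + a)(r + a)^T V_ext``: the off-diagonal ratio
    ``C_ij / ((r_i + a)(r_j + a))`` equals the constant gain variance
    ``V_ext`` for every pair.
    """
    if v_ext_scalar < 0:
        raise ValueError("gain variance V_ext must be nonnegative")
    u = np.atleast_1d(np.asarray(rates, dtype=float)) + offset_a
    return np.diag(u) + v_ext_scalar * np.outer(u, u)


def predicted_population_moments(
    model_kind: Literal["recurrent", "feedforward", "gain"],
    *,
    n: int,
    mean_rate: float,
    offset_a: float = 0.0,
    mean_w: Optional[float] = None,
    var_w: Optional[float] = None,
    mean_v_ext: Optional[float] = None,
    v_ext_scalar: Optional[float] = None,
    rates: Optional[np.ndarray] = None,
) -> dict:
    """Predicted population-averaged variance and pairwise covariance.

    For a random coupling matrix with i.i.d. entries (mean ``mean_w``,
    variance ``var_w``) and input variance averaged over neurons
    ``mean_v_ext``:

    * recurrent:   ``<C_ii> = <C_ij> * <B^2>/<B>^2 = N <B^2> (<r> + a + <V_ext>)``
    * feed-forward: ``<C_ii> = <r> + a + N <V_ext> <F^2>``,
      ``<C_ij> = N <F>^2 <V_ext>`` (no direct dependence on ``<r>``)
    * gain:        ``<C_ii> = V_ext <(r+a)^2> + <r+a>``,
      ``<C_ij> = V_ext <r+a>^2`` (quadratic in the population response);
      requires the full rate vector.

    Returns a dict with ``mean_var`` and ``mean_cov``.
    """
    if n < 2:
        raise ValueError("population predictions require n >= 2")
    if model_kind in ("recurrent", "feedforward"):
        if mean_w is None or var_w is None or mean_v_ext is None:
            raise ValueError(f"{model_kind} model needs mean_w, var_w and mean_v_ext")
        second_moment = mean_w**2 + var_w
        if model_kind == "recurrent":
            drive = mean_rate + offset_a + mean_v_ext
            return {
                "mean_var": n * second_moment * drive,
                "mean_cov": n * mean_w**2 * drive,
            }
        return {
            "mean_var": mean_rate + offset_a + n * mean_v_ext * second_moment,
            "mean_cov": n * mean_w**2 * mean_v_ext,
        }
    if model_kind == "gain":
        if rates is None or v_ext_scalar is None:
            raise ValueError("gain model needs the full rate vector and v_ext_scalar")
        u = np.asarray(rates, dtype=float) + offset_a
        return {
            "mean_var": v_ext_scalar * float(np.mean(u**2)) + float(np.mean(u)),
            "mean_cov": v_ext_scalar * float(np.mean(u)) ** 2,
        }
    raise ValueError(f"unknown model kind {model_kind!r}")


def predicted_average_correlations(
    model_kind: Literal["recurrent", "feedforward", "gain"],
    rho: float,
    c_in: float = 0.0,
    n: int = 2,
) -> dict:
    """Predicted average noise / signal correlation coefficients.

    For a recurrent network with random effective couplings of relative
    variability ``rho = var(B)/<B>^2``:

    * ``c_N = 1 / (1 + rho)``
    * ``c_S = (1 + (N-1) c_in) / (1 + rho + (N-1) c_in)``

    The feed-forward network shares the same ``c_S`` expression (with ``rho``
    of ``F``); its ``c_N`` depends on additional parameters and is returned as
    ``None`` here.  The gain model has no defined signal-correlation
    prediction (its rate ensemble is arbitrary): both entries are ``None``.
    """
    if rho < 0:
        raise ValueError("rho must be nonnegative")
    if not 0 <= c_in < 1:
        raise ValueError("c_in must lie in [0, 1)")
    if n < 2:
        raise ValueError("n must be >= 2")
    amplified = (n - 1) * c_in
    c_s = (1 + amplified) / (1 + rho + amplified)
    if model_kind == "recurrent":
        return {"c_N": 1.0 / (1.0 + rho), "c_S": c_s}
    if model_kind == "feedforward":
        return {"c_N": None, "c_S": c_s}
    if model_kind == "gain":
        return {"c_N": None, "c_S": None}
    raise ValueError(f"unknown model kind {model_kind!r}")
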