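"""Empirical population statistics: noise/signal correlations and projected variances.

All second moments use the moment-form estimator (divisor = number of
trials), matching the definition of the noise covariance
``C_ij(s) = <r_i r_j>_T - <r_i>_T <r_j>_T``.  At 15 trials this is a known
(documented) multiplicative bias of 14/15 relative to the unbiased
estimator; it cancels in every ratio used downstream.

Scale convention: trial-level responses are time-averaged rates (spikes/s),
so their covariance is ``C / Delta`` where ``C`` is the normalised count
covariance of the analytic models.  :func:`empirical_moments` multiplies the
trial covariance by the window length to put empirical and analytic moments
on the same (count-normalised) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .architectures import MomentSet
from .datasets import ResponseDataset
from .exceptions import TooFewStimuliError, TooFewTrialsError

MomentsOrDataset = Union[ResponseDataset, Sequence[MomentSet]]


def trial_statistics(dataset: ResponseDataset, stimulus: int) -> tuple[np.ndarray, np.ndarray]:
    """Across-trial mean vector and noise covariance for one stimulus.

    Moment-form estimator (divisor = trial count), on the trial (rate) scale.
    """
    if dataset.n_trials < 2:
        raise TooFewTrialsError("need at least 2 trials for a noise covariance")
    trials = dataset.responses[stimulus]  # (n_trials, n_neurons)
    mean = trials.mean(axis=0)
    centered = trials - mean
    cov = centered.T @ centered / trials.shape[0]
    return mean, 0.5 * (cov + cov.T)


def empirical_moments(dataset: ResponseDataset) -> list[MomentSet]:
    """Per-stimulus empirical moments on the count-normalised scale (cov * Delta)."""
    out = []
    for s in range(dataset.n_stimuli):
        mean, cov = trial_statistics(dataset, s)
        out.append(
            MomentSet(
                rates=mean,
                cov=cov * dataset.window_delta,
                source="empirical",
                stimulus_id=s,
            )
        )
    return out


def as_moments(data: MomentsOrDataset) -> list[MomentSet]:
    """Normalise input: a dataset becomes its list of empirical moments."""
    if isinstance(data, ResponseDataset):
        return empirical_moments(data)
    return list(data)


def correlation_coefficients(data: MomentsOrDataset) -> dict:
    """Pairwise and population-averaged noise and signal correlations.

    * ``c_N_pairs[i, j]`` — per-pair noise correlation: the per-stimulus
      Pearson ratio ``C_ij / sqrt(C_ii C_jj)`` averaged over stimuli
      (stimuli where either variance vanishes are excluded per pair and
      counted in ``n_excluded``).
    * ``c_S_pairs[i, j]`` — signal correlation: across-stimulus Pearson
      correlation of the trial-averaged responses.
    * ``c_N``, ``c_S`` — averages over unordered pairs i < j.
    """
    moments = as_moments(data)
    if len(moments) < 2:
        raise TooFewStimuliError("need at least 2 stimuli for correlation statistics")
    n = moments[0].n
    iu = np.triu_indices(n, k=1)

    ratio_sum = np.zeros((n, n))
    ratio_count = np.zeros((n, n), dtype=int)
    for m in moments:
        var = np.diag(m.cov)
        valid = var > 0
        denom = np.sqrt(np.outer(np.clip(var, 0.0, None), np.clip(var, 0.0, None)))
        ok = np.outer(valid, valid)
        ratio = np.where(ok, m.cov / np.where(ok, denom, 1.0), 0.0)
        ratio_sum += np.where(ok, ratio, 0.0)
        ratio_count += ok.astype(int)
    with np.errstate(invalid="ignore"):
        c_n_pairs = np.where(ratio_count > 0, ratio_sum / np.maximum(ratio_count, 1), np.nan)
    np.fill_diagonal(c_n_pairs, 1.0)
    n_excluded = int((len(moments) - ratio_count[iu]).sum())

    rates = np.array([m.rates for m in moments])  # (n_stimuli, n_neurons)
    sd = rates.std(axis=0)
    tuned = sd > 0
    centered = rates - rates.mean(axis=0)
    cov_s = centered.T @ centered / rates.shape[0]
    with np.errstate(invalid="ignore", divide="ignore"):
        c_s_pairs = cov_s / np.outer(np.where(tuned, sd, np.nan), np.where(tuned, sd, np.nan))
    np.fill_diagonal(c_s_pairs, 1.0)

    c_n_vals = c_n_pairs[iu]
    c_s_vals = c_s_pairs[iu]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pair sets
        c_n_avg = float(np.nanmean(c_n_vals))
        c_s_avg = float(np.nanmean(c_s_vals))
    return {
        "c_N_pairs": c_n_pairs,
        "c_S_pairs": c_s_pairs,
        "c_N": c_n_avg,
        "c_S": c_s_avg,
        "n_excluded": n_excluded,
        "n_undefined_signal_pairs": int(np.isnan(c_s_vals).sum()),
    }


def projected_variances(cov: np.ndarray, rates: np.ndarray) -> dict:
    """Population variance projected on the mean-response and diagonal directions.

    ``sigma_mu2 = rbar^T C rbar`` with ``rbar = r/|r|``;
    ``sigma_d2 = dbar^T C dbar`` with ``dbar = (1,..,1)/sqrt(N)``;
    ``sigma_all2 = trace(C)``; ``cos_dr = rbar . dbar`` measures how far the
    mean response is from a uniform population response.

    ``sigma_mu2`` and ``cos_dr`` are NaN when the mean response vanishes.
    """
    cov = np.asarray(cov, dtype=float)
    r = np.asarray(rates, dtype=float)
    n = r.size
    dbar = np.full(n, 1.0 / np.sqrt(n))
    sigma_d2 = float(dbar @ cov @ dbar)
    sigma_all2 = float(np.trace(cov))
    norm = np.linalg.norm(r)
    if norm == 0:
        return {
            "sigma_mu2": np.nan,
            "sigma_d2": sigma_d2,
            "sigma_all2": sigma_all2,
            "cos_dr": np.nan,
        }
    rbar = r / norm
    return {
        "sigma_mu2": float(rbar @ cov @ rbar),
        "sigma_d2": sigma_d2,
        "sigma_all2": sigma_all2,
        "cos_dr": float(rbar @ dbar),
    }


def moment_curve(data: MomentsOrDataset) -> pd.DataFrame:
    """Per-stimulus population summaries, one row per stimulus.

    Columns: ``stimulus``, ``mean_rate`` (<r>), ``mean_var`` (<C_ii>),
    ``mean_cov`` (<C_ij>_{i!=j}, divisor N(N-1)), ``sigma_mu2_norm``,
    ``sigma_d2_norm`` (projected variances / trace) and ``cos_dr``.
    """
    moments = as_moments(data)
    rows = []
    for idx, m in enumerate(moments):
        n = m.n
        var = np.diag(m.cov)
        off_sum = m.cov.sum() - var.sum()
        proj = projected_variances(m.cov, m.rates)
        total = proj["sigma_all2"]
        rows.append(
            {
                "stimulus": m.stimulus_id if m.stimulus_id is not None else idx,
                "mean_rate": float(m.rates.mean()),
                "mean_var": float(var.mean()),
                "mean_cov": float(off_sum / (n * (n - 1))) if n > 1 else np.nan,
                "sigma_mu2_norm": proj["sigma_mu2"] / total if total > 0 else np.nan,
                "sigma_d2_norm": proj["sigma_d2"] / total if total > 0 else np.nan,
                "cos_dr": proj["cos_dr"],
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PopulationSummary:
    """Bundle of the per-stimulus moments and their population summaries."""

    moments: list[MomentSet]
    curve: pd.DataFrame
    c_N: float
    c_S: float
    c_N_pairs: np.ndarray = field(repr=False, default=None)
    c_S_pairs: np.ndarray = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.moments[0].n

    @property
    def n_stimuli(self) -> int:
        return len(self.moments)

    def pair_frame(self) -> pd.DataFrame:
        """Companion table: one row per unordered neuron pair."""
        n = self.n_neurons
        iu = np.triu_indices(n, k=1)
        return pd.DataFrame(
            {
                "neuron_i": iu[0],
                "neuron_j": iu[1],
                "c_N": self.c_N_pairs[iu],
                "c_S": self.c_S_pairs[iu],
            }
        )


def summarize(data: MomentsOrDataset) -> PopulationSummary:
    """Full population summary: moment curve plus correlation coefficients."""
    moments = as_moments(data)
    corr = correlation_coefficients(moments)
    return PopulationSummary(
        moments=moments,
        curve=moment_curve(moments),
        c_N=corr["c_N"],
        c_S=corr["c_S"],
        c_N_pairs=corr["c_N_pairs"],
        c_S_pairs=corr["c_S_pairs"],
        diagnostics={
            "n_excluded": corr["n_excluded"],
            "n_undefined_signal_pairs": corr["n_undefined_signal_pairs"],
        },
    )
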