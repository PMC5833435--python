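"""Fisher-discriminant stimulus-pair discriminability and shuffling controls.

For two stimuli with mean responses ``r1, r2`` and noise covariances
``C1, C2`` the most discriminant readout direction is

    w = (C1 + C2)^-1 (r1 - r2),

and the signal-to-noise ratio of the projected (assumed Gaussian) response
distributions is

    S = |wbar . (r1 - r2)| / (sigma_1 + sigma_2),   sigma_i = sqrt(wbar^T C_i wbar)

with ``wbar = w / |w|``.  ``S`` is invariant under any fixed invertible
linear transformation of the population (means -> M r, covariances ->
M C M^T), because the optimal readout absorbs the transformation.

The effect of noise correlations is quantified by comparing ``S`` with the
value obtained after removing correlations: zeroing the off-diagonal
covariance entries (model moments) or independently permuting each neuron's
trials within each stimulus (datasets) — both keep means and single-neuron
variances.  A ratio ``S_shuffled / S`` below one means the correlations were
beneficial for discriminating that stimulus pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional

import numpy as np
import pandas as pd

from .architectures import MomentSet
from .datasets import ResponseDataset
from .exceptions import TooFewStimuliError, TooFewTrialsError
from .popstats import MomentsOrDataset, as_moments, projected_variances

#: Relative ridge added to a singular summed covariance before solving.
RIDGE_EPS = 1e-8

#: Condition number beyond which the summed covariance counts as singular.
_SINGULAR_COND = 1e12


@dataclass(frozen=True)
class PairDiscrimination:
    """Discriminability record for one unordered stimulus pair."""

    stimulus_1: object
    stimulus_2: object
    S: float
    S_shuffled: float
    ratio: float
    cos_d_dr: float
    regularized: bool = False


def discriminant_snr(
    r1: np.ndarray,
    r2: np.ndarray,
    C1: np.ndarray,
    C2: np.ndarray,
) -> dict:
    """Fisher discriminant direction and signal-to-noise ratio for two stimuli.

    Singular ``C1 + C2`` (generic for empirical covariances with fewer trials
    than neurons) is handled by a small ridge, ``eps * trace / (2N)`` on the
    diagonal, and flagged with ``regularized=True`` in the result.
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    dr = r1 - r2
    n = dr.size
    total = np.asarray(C1, dtype=float) + np.asarray(C2, dtype=float)
    if np.linalg.norm(dr) == 0:
        return {"w": np.zeros(n), "S": 0.0, "regularized": False}
    regularized = False
    try:
        cond = np.linalg.cond(total)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > _SINGULAR_COND:
        total = total + np.eye(n) * (RIDGE_EPS * np.trace(total) / (2 * n))
        regularized = True
    w = np.linalg.solve(total, dr)
    wbar = w / np.linalg.norm(w)
    sigma1 = np.sqrt(max(float(wbar @ C1 @ wbar), 0.0))
    sigma2 = np.sqrt(max(float(wbar @ C2 @ wbar), 0.0))
    denom = sigma1 + sigma2
    s = abs(float(wbar @ dr)) / denom if denom > 0 else np.inf
    return {"w": w, "S": s, "regularized": regularized}


def shuffle(
    data,
    mode: str = "trials",
    seed: Optional[int] = None,
):
    """Remove noise correlations while preserving means and variances.

    ``mode="diag"`` (model moments): return the moment set with off-diagonal
    covariances zeroed.  ``mode="trials"`` (datasets): independently permute
    each neuron's trial order within each stimulus, seeded — the marginal
    per-neuron, per-stimulus response distributions are exactly preserved.
    """
    if mode == "diag":
        if isinstance(data, MomentSet):
            return MomentSet(
                rates=data.rates,
                cov=np.diag(np.diag(data.cov)),
                offset_a=data.offset_a,
                source=data.source,
                stimulus_id=data.stimulus_id,
            )
        return [shuffle(m, mode="diag") for m in data]
    if mode == "trials":
        if not isinstance(data, ResponseDataset):
            raise TypeError("trial shuffling requires a ResponseDataset")
        if data.n_trials < 2:
            raise TooFewTrialsError("trial shuffling needs at least 2 trials")
        rng = np.random.default_rng(seed)
        shuffled = data.responses.copy()
        for s in range(data.n_stimuli):
            for i in range(data.n_neurons):
                shuffled[s, :, i] = shuffled[s, rng.permutation(data.n_trials), i]
        return ResponseDataset(
            responses=shuffled,
            window_delta=data.window_delta,
            population_id=data.population_id,
            metadata={**data.metadata, "shuffled": True},
        )
    raise ValueError(f"unknown shuffle mode {mode!r}")


def discrimination_scan(
    data: MomentsOrDataset,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, dict]:
    """Fisher SNR for every unordered stimulus pair, before and after shuffling.

    For model moments the shuffled SNR uses the diagonal covariances; for a
    dataset, empirical moments are computed before and after seeded trial
    shuffling.  Returns ``(pairs, summary)`` where ``pairs`` has one row per
    pair (``s1, s2, S, S_shuffled, ratio, cos_d_dr, regularized``) and
    ``summary`` holds the pair-averaged ratio and cosine distribution.
    """
    if isinstance(data, ResponseDataset):
        moments = as_moments(data)
        moments_shuffled = as_moments(shuffle(data, mode="trials", seed=seed))
    else:
        moments = as_moments(data)
        moments_shuffled = [shuffle(m, mode="diag") for m in moments]
    if len(moments) < 2:
        raise TooFewStimuliError("need at least 2 stimuli to scan pairs")

    labels = [
        m.stimulus_id if m.stimulus_id is not None else i for i, m in enumerate(moments)
    ]
    order = np.argsort(np.asarray(labels, dtype=object))
    n = moments[0].n
    dbar = np.full(n, 1.0 / np.sqrt(n))
    rows = []
    for a, b in combinations(order, 2):
        m1, m2 = moments[a], moments[b]
        full = discriminant_snr(m1.rates, m2.rates, m1.cov, m2.cov)
        sh1, sh2 = moments_shuffled[a], moments_shuffled[b]
        shuf = discriminant_snr(sh1.rates, sh2.rates, sh1.cov, sh2.cov)
        dr = m1.rates - m2.rates
        norm = np.linalg.norm(dr)
        cos_d_dr = float(dr @ dbar / norm) if norm > 0 else np.nan
        s, s_sh = full["S"], shuf["S"]
        rows.append(
            {
                "s1": labels[a],
                "s2": labels[b],
                "S": s,
                "S_shuffled": s_sh,
                "ratio": s_sh / s if s > 0 else np.nan,
                "cos_d_dr": cos_d_dr,
                "regularized": full["regularized"] or shuf["regularized"],
            }
        )
    pairs = pd.DataFrame(rows)
    q75, q25 = np.nanpercentile(pairs["ratio"], [75, 25])
    summary = {
        "n_pairs": len(pairs),
        "mean_ratio": float(pairs["ratio"].mean()),
        "std_ratio": float(pairs["ratio"].std(ddof=0)),
        # near-singular pairs give heavy-tailed ratios; the IQR is the
        # robust width of the distribution
        "iqr_ratio": float(q75 - q25),
        "mean_abs_cos_d_dr": float(pairs["cos_d_dr"].abs().mean()),
        "fraction_beneficial": float((pairs["ratio"] < 1).mean()),
    }
    return pairs, summary
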