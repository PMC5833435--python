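"""Trial-resolved response datasets and their on-disk format.

A :class:`ResponseDataset` holds the responses of one neural population:
time-averaged, baseline-relative firing rates indexed by (stimulus, trial,
neuron), mirroring the structure of the auditory-cortex recordings the
analysis chain was designed for (65 stimuli x 15 trials, 250 ms windows,
responses relative to spontaneous activity so negative values occur).

On disk a dataset is a directory with

* ``responses.csv`` — header ``population_id,stimulus_id,trial_id,neuron_id,
  response``; 0-based integer IDs; responses in spikes/s.
* ``meta.json`` — generator configuration, seed and (for synthetic data) the
  ground-truth block.
* optionally ``networks/`` with sampled coupling matrices as CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import MalformedFileError

_COLUMNS = ["population_id", "stimulus_id", "trial_id", "neuron_id", "response"]


@dataclass
class ResponseDataset:
    """Responses of one population: array of shape (n_stimuli, n_trials, n_neurons)."""

    responses: np.ndarray
    window_delta: float = 0.25
    population_id: int = 0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        r = np.asarray(self.responses, dtype=float)
        if r.ndim != 3:
            raise ValueError("responses must be (n_stimuli, n_trials, n_neurons)")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses contain non-finite values")
        self.responses = r

    @property
    def n_stimuli(self) -> int:
        return self.responses.shape[0]

    @property
    def n_trials(self) -> int:
        return self.responses.shape[1]

    @property
    def n_neurons(self) -> int:
        return self.responses.shape[2]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view with one row per (stimulus, trial, neuron)."""
        s, t, n = self.responses.shape
        idx = np.indices((s, t, n)).reshape(3, -1)
        return pd.DataFrame(
            {
                "population_id": self.population_id,
                "stimulus_id": idx[0],
                "trial_id": idx[1],
                "neuron_id": idx[2],
                "response": self.responses.ravel(),
            }
        )


def write_dataset(dataset: ResponseDataset, path: str | Path) -> Path:
    """Write a dataset directory (``responses.csv`` + ``meta.json``)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.to_frame().to_csv(path / "responses.csv", index=False, lineterminator="\n")
    meta = {
        "window_delta": dataset.window_delta,
        "population_id": dataset.population_id,
        "n_stimuli": dataset.n_stimuli,
        "n_trials": dataset.n_trials,
        "n_neurons": dataset.n_neurons,
        **dataset.metadata,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=2, default=_jsonify) + "\n")
    return path


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def read_dataset(path: str | Path, population_id: int | None = None) -> ResponseDataset:
    """Read a dataset directory back; lossless for responses and metadata.

    ``population_id`` selects a population when the CSV contains several;
    with a single population it may be omitted.
    """
    path = Path(path)
    csv_path = path / "responses.csv"
    if not csv_path.exists():
        raise MalformedFileError(f"missing responses.csv in {path}")
    df = pd.read_csv(csv_path)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise MalformedFileError(f"responses.csv lacks columns {missing}")
    pops = sorted(df["population_id"].unique())
    if population_id is None:
        if len(pops) > 1:
            raise MalformedFileError(
                f"responses.csv holds populations {pops}; pass population_id"
            )
        population_id = int(pops[0])
    df = df[df["population_id"] == population_id]
    if df.empty:
        raise MalformedFileError(f"population {population_id} not present (found {pops})")

    stimuli = np.sort(df["stimulus_id"].unique())
    trials = np.sort(df["trial_id"].unique())
    neurons = np.sort(df["neuron_id"].unique())
    s, t, n = len(stimuli), len(trials), len(neurons)
    if len(df) != s * t * n:
        counts = df.groupby("stimulus_id").size()
        bad = counts[counts != t * n]
        stim = int(bad.index[0]) if len(bad) else "unknown"
        raise MalformedFileError(
            f"responses.csv is not rectangular: stimulus {stim} has "
            f"{int(bad.iloc[0]) if len(bad) else len(df)} rows, expected {t * n}"
        )
    arr = np.full((s, t, n), np.nan)
    arr[
        df["stimulus_id"].to_numpy(),
        df["trial_id"].to_numpy(),
        df["neuron_id"].to_numpy(),
    ] = df["response"].to_numpy()
    if np.isnan(arr).any():
        raise MalformedFileError("duplicate or missing (stimulus, trial, neuron) rows")

    meta_path = path / "meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    window_delta = float(meta.pop("window_delta", 0.25))
    for key in ("population_id", "n_stimuli", "n_trials", "n_neurons"):
        meta.pop(key, None)
    return ResponseDataset(
        responses=arr,
        window_delta=window_delta,
        population_id=population_id,
        metadata=meta,
    )
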