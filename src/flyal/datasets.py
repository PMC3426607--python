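"""Spike datasets: the tabular currency between the engine and the analyses.

A :class:`SpikeDataset` wraps a tidy pandas table with one row per spike,

    trial, odor, neuron_id, cls, glomerulus, spike_time_ms

plus free-form metadata (seeds, configuration hashes, generator ground
truth).  It round-trips through plain tab-separated text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SpikeDataset", "SPIKE_COLUMNS", "save_traces", "load_traces"]

SPIKE_COLUMNS = ["trial", "odor", "neuron_id", "cls", "glomerulus", "spike_time_ms"]


@dataclass
class SpikeDataset:
    """Per-trial, per-neuron spike times with odor and seed metadata."""

    spikes: pd.DataFrame
    horizon: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in SPIKE_COLUMNS if c not in self.spikes.columns]
        if missing:
            raise ValueError(f"spike table missing columns {missing}")

    @property
    def odors(self) -> list:
        return sorted(self.spikes["odor"].unique())

    @property
    def trials(self) -> list:
        return sorted(self.spikes["trial"].unique())

    def select(self, **filters) -> pd.DataFrame:
        """Rows matching equality filters on any spike-table column."""
        df = self.spikes
        for col, val in filters.items():
            if np.iterable(val) and not isinstance(val, str):
                df = df[df[col].isin(val)]
            else:
                df = df[df[col] == val]
        return df

    def spike_train(self, trial, odor, neuron_id) -> np.ndarray:
        df = self.select(trial=trial, odor=odor, neuron_id=neuron_id)
        return np.sort(df["spike_time_ms"].values)

    def counts(
        self,
        neuron_ids,
        window: tuple[float, float] | None = None,
    ) -> pd.DataFrame:
        """Spike counts per (odor, trial, neuron) in a time window.

        Includes explicit zero rows for neurons that never fired, which
        matters for count-distribution estimation.
        """
        lo, hi = window if window is not None else (0.0, self.horizon)
        df = self.spikes[self.spikes["neuron_id"].isin(neuron_ids)]
        df = df[(df["spike_time_ms"] >= lo) & (df["spike_time_ms"] < hi)]
        grouped = (
            df.groupby(["odor", "trial", "neuron_id"]).size().rename("count")
        )
        full = pd.MultiIndex.from_product(
            [self.odors, self.trials, list(neuron_ids)],
            names=["odor", "trial", "neuron_id"],
        )
        return grouped.reindex(full, fill_value=0).reset_index()

    def concat(self, other: "SpikeDataset") -> "SpikeDataset":
        if other.horizon != self.horizon:
            raise ValueError("cannot concatenate datasets with different horizons")
        meta = {**self.metadata, **other.metadata}
        return SpikeDataset(
            spikes=pd.concat([self.spikes, other.spikes], ignore_index=True),
            horizon=self.horizon,
            metadata=meta,
        )

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# horizon_ms={self.horizon}\n")
            for key, val in self.metadata.items():
                fh.write(f"# {key}={val}\n")
            self.spikes.to_csv(fh, sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "SpikeDataset":
        path = Path(path)
        meta: dict = {}
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val
        horizon = float(meta.pop("horizon_ms"))
        spikes = pd.read_csv(path, sep="\t", skiprows=skip)
        return cls(spikes=spikes, horizon=horizon, metadata=meta)


def save_traces(traces: dict, path) -> None:
    """Store probe traces (t, neuron_ids, V, gE, eta, D) in an HDF5 container."""
    import h5py

    with h5py.File(path, "w") as fh:
        for key, arr in traces.items():
            fh.create_dataset(key, data=np.asarray(arr))


def load_traces(path) -> dict:
    import h5py

    with h5py.File(path, "r") as fh:
        return {key: fh[key][...] for key in fh.keys()}
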