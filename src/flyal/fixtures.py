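"""Parametric spike-train fixtures with analytically known statistics.

Every analysis and discrimination operation can be exercised without the HH
engine: these generators produce :class:`~flyal.datasets.SpikeDataset`
objects whose ground-truth rate, ISI structure, pairwise correlation or
class separability is known by construction and embedded in the dataset
metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import SpikeDataset

__all__ = ["FixtureSpec", "generate"]

KINDS = (
    "poisson",
    "periodic",
    "two-atom",
    "bursty",
    "correlated-pair",
    "odor-separable-panel",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Generator kind, parameters and seed for one synthetic dataset."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; choose from {KINDS}")


def _rows(trial, odor, neuron, times):
    return pd.DataFrame(
        {
            "trial": trial,
            "odor": odor,
            "neuron_id": neuron,
            "cls": "PN",
            "glomerulus": 0,
            "spike_time_ms": np.asarray(times, dtype=float),
        }
    )


def generate(spec: FixtureSpec) -> SpikeDataset:
    """Sample the dataset described by ``spec`` (reproducible given seed)."""
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    horizon = float(p.pop("horizon", 1000.0))
    n_trials = int(p.pop("n_trials", 1))
    frames = []
    meta = {"kind": spec.kind, "seed": spec.seed}

    if spec.kind == "poisson":
        rate = float(p.pop("rate_hz", 50.0))
        n_neurons = int(p.pop("n_neurons", 1))
        for trial in range(n_trials):
            for nid in range(n_neurons):
                n_ev = rng.poisson(rate / 1000.0 * horizon)
                frames.append(
                    _rows(trial, "odor0", nid, np.sort(rng.random(n_ev) * horizon))
                )
        meta.update(rate_hz=rate, isi_cv=1.0)

    elif spec.kind == "periodic":
        period = float(p.pop("period_ms", 20.0))
        n_neurons = int(p.pop("n_neurons", 1))
        phase = float(p.pop("phase", 0.0))
        times = np.arange(phase if phase > 0 else period, horizon, period)
        for trial in range(n_trials):
            for nid in range(n_neurons):
                frames.append(_rows(trial, "odor0", nid, times))
        meta.update(period_ms=period, isi_variance=0.0)

    elif spec.kind == "two-atom":
        a = float(p.pop("isi_a", 15.0))
        b = float(p.pop("isi_b", 25.0))
        isis = np.tile([a, b], int(horizon / (a + b)) + 1)
        times = np.cumsum(isis)
        times = times[times < horizon]
        for trial in range(n_trials):
            frames.append(_rows(trial, "odor0", 0, times))
        # alternating a, b: mean (a+b)/2, population variance ((a-b)/2)^2
        meta.update(isi_variance=((a - b) / 2.0) ** 2, isi_mean=(a + b) / 2.0)

    elif spec.kind == "bursty":
        burst_rate = float(p.pop("burst_rate_hz", 5.0))
        spikes_per_burst = int(p.pop("spikes_per_burst", 5))
        intra_isi = float(p.pop("intra_isi_ms", 3.0))
        for trial in range(n_trials):
            n_b = rng.poisson(burst_rate / 1000.0 * horizon)
            starts = np.sort(rng.random(n_b) * horizon)
            times = (starts[:, None] + np.arange(spikes_per_burst) * intra_isi).ravel()
            frames.append(_rows(trial, "odor0", 0, np.sort(times[times < horizon])))
        meta.update(
            mean_rate_hz=burst_rate * spikes_per_burst,
            burst_rate_hz=burst_rate,
        )

    elif spec.kind == "correlated-pair":
        rate = float(p.pop("rate_hz", 50.0))
        corr = float(p.pop("corr", 0.5))
        if not 0 < corr <= 1:
            raise ValueError("corr must lie in (0, 1]")
        # common-mother thinning: each child keeps mother events with
        # probability corr, so windowed count correlation equals corr
        mother_rate = rate / corr
        for trial in range(n_trials):
            n_m = rng.poisson(mother_rate / 1000.0 * horizon)
            mother = np.sort(rng.random(n_m) * horizon)
            for nid in range(2):
                keep = rng.random(n_m) < corr
                frames.append(_rows(trial, "odor0", nid, mother[keep]))
        meta.update(rate_hz=rate, count_corr=corr)

    elif spec.kind == "odor-separable-panel":
        n_odors = int(p.pop("n_odors", 2))
        n_pns = int(p.pop("n_pns", 4))
        delta = float(p.pop("delta", 5.0))
        base = float(p.pop("base_count", 10.0))
        noise = float(p.pop("count_noise", 3.0))
        # odor o raises the mean count of PN i by delta when (i + o) is even:
        # a balanced, linearly separable pattern with separation delta
        for odor_i in range(n_odors):
            for trial in range(n_trials):
                for nid in range(n_pns):
                    mu = base + delta * ((nid + odor_i) % 2)
                    count = max(int(round(rng.normal(mu, noise))), 0)
                    times = np.sort(rng.random(count) * horizon)
                    frames.append(_rows(trial, f"odor{odor_i}", nid, times))
        meta.update(delta=delta, base_count=base, count_noise=noise)

    if p:
        raise ValueError(f"unknown parameters for {spec.kind!r}: {sorted(p)}")
    spikes = pd.concat(frames, ignore_index=True)
    return SpikeDataset(spikes=spikes, horizon=horizon, metadata=meta)
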