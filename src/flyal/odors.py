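"""Poisson input to the ORNs: background drive plus ramped odor-specific drive.

Each ORN receives a stream of input events drawn from a Poisson process.  In
background the rate is a constant 350 Hz.  An odor adds channel-specific
extra rate shaped by a stereotyped ramp: zero before onset, saturating rise
with time constant ``tau_on`` after onset, and a slower exponential decay
with ``tau_off`` after offset.  An odor is therefore a vector of peak extra
rates over the glomerular channels -- different chemical compositions drive
different channel subsets, different concentrations scale the same subset.

Events are converted to ORN stimulus current through a causal exponential
kernel; the current is a filtered shot-noise process.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OdorSpec",
    "InputEventStream",
    "odor_ramp",
    "odor_rate",
    "sample_events",
    "stimulus_current",
    "odor_input_streams",
    "make_odor_panel",
    "background_odor",
]

#: default background Poisson input rate (Hz)
BACKGROUND_RATE = 350.0


@dataclass(frozen=True)
class OdorSpec:
    """One odor: per-channel peak extra rates and the stimulus time course.

    ``rates[g]`` is the peak odor-specific Poisson rate (Hz) added to every
    ORN of glomerular channel g.  ``background_strength`` and
    ``odor_strength`` scale the current kernel of background and odor events
    respectively.
    """

    rates: np.ndarray
    t_on: float = 500.0
    t_off: float = 1500.0
    tau_on: float = 100.0
    tau_off: float = 300.0
    background_rate: float = BACKGROUND_RATE
    background_strength: float = 1.2
    odor_strength: float = 1.2
    name: str = "odor"

    def __post_init__(self) -> None:
        rates = np.asarray(self.rates, dtype=float)
        if np.any(rates < 0) or self.background_rate < 0:
            raise ValueError("rates must be non-negative")
        if not self.tau_off >= self.tau_on:
            raise ValueError("odor offset must ramp more slowly than onset")
        object.__setattr__(self, "rates", rates)

    @property
    def n_channels(self) -> int:
        return len(self.rates)


def background_odor(n_channels: int, **kwargs) -> OdorSpec:
    """Background-only stimulus (all odor-specific rates zero)."""
    kwargs.setdefault("name", "background")
    return OdorSpec(rates=np.zeros(n_channels), **kwargs)


@dataclass(frozen=True)
class InputEventStream:
    """Per-ORN event times with a per-event source tag (0=background, 1=odor)."""

    times: list = field(default_factory=list)  # list of float arrays, one per ORN
    source: list = field(default_factory=list)  # matching uint8 arrays

    @property
    def n_orns(self) -> int:
        return len(self.times)

    def total_events(self) -> int:
        return int(sum(len(t) for t in self.times))


def odor_ramp(t, t_on: float, t_off: float, tau_on: float, tau_off: float):
    """Stimulus ramp factor in [0, 1): saturating onset, slower offset decay."""
    t = np.asarray(t, dtype=float)
    rise = 1.0 - np.exp(-(t - t_on) / tau_on)
    level_off = 1.0 - np.exp(-(t_off - t_on) / tau_on)
    fall = level_off * np.exp(-(t - t_off) / tau_off)
    out = np.where(t < t_on, 0.0, np.where(t < t_off, rise, fall))
    return out if out.ndim else float(out)


def odor_rate(t, odor: OdorSpec, channel: int):
    """Total Poisson input rate (Hz) at time t (ms) for an ORN of ``channel``."""
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    extra = odor.rates[channel] * odor_ramp(
        t, odor.t_on, odor.t_off, odor.tau_on, odor.tau_off
    )
    return odor.background_rate + extra


def sample_events(
    rate_fn,
    horizon: float,
    seed,
    rate_bound: float,
) -> np.ndarray:
    """Inhomogeneous Poisson sampling on [0, horizon) ms by thinning.

    ``rate_fn(t_ms) -> Hz`` must be bounded by ``rate_bound`` on the horizon.
    Counts in any window are Poisson with mean equal to the integrated rate.
    """
    rng = np.random.default_rng(seed)
    if rate_bound < 0:
        raise ValueError("rate bound must be non-negative")
    if rate_bound == 0:
        return np.empty(0)
    # candidate homogeneous process at the bound (rate in events/ms)
    lam_ms = rate_bound / 1000.0
    n_cand = rng.poisson(lam_ms * horizon)
    t_cand = np.sort(rng.random(n_cand) * horizon)
    rates = np.asarray(rate_fn(t_cand), dtype=float)
    if np.any(rates < 0):
        t_bad = t_cand[np.argmax(rates < 0)]
        raise ValueError(f"negative rate encountered at t={t_bad:.3f} ms")
    if np.any(rates > rate_bound * (1 + 1e-12)):
        raise ValueError("rate exceeds the stated bound")
    keep = rng.random(n_cand) < rates / rate_bound
    return t_cand[keep]


def stimulus_current(
    t,
    events: np.ndarray,
    strengths,
    tau_kernel: float = 2.0,
):
    """ORN stimulus current at time(s) t from past input events.

    Each event contributes ``strength * exp(-(t - t_e)/tau_kernel)`` for
    t >= t_e (causal, unimodal, integrable kernel); contributions superpose
    linearly.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    events = np.asarray(events, dtype=float)
    strengths = np.broadcast_to(np.asarray(strengths, dtype=float), events.shape)
    lag = t[:, None] - events[None, :]
    contrib = np.where(lag >= 0, np.exp(-np.clip(lag, 0, None) / tau_kernel), 0.0)
    out = contrib @ strengths
    return out if out.shape != (1,) else float(out[0])


def odor_input_streams(
    odor: OdorSpec,
    n_orns_per_channel: int,
    horizon: float,
    seed: int,
) -> InputEventStream:
    """Sample the full per-ORN event streams for one odor presentation.

    Background events (homogeneous) and odor events (inhomogeneous, thinned)
    are sampled independently per ORN and merged in time order with source
    tags.  Deterministic given (odor, seed).
    """
    times: list[np.ndarray] = []
    source: list[np.ndarray] = []
    root = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    channel_seeds = root.spawn(odor.n_channels)
    for g in range(odor.n_channels):
        peak = float(odor.rates[g])
        for o, child in enumerate(channel_seeds[g].spawn(n_orns_per_channel)):
            bg_seed, od_seed = child.spawn(2)
            bg = sample_events(
                lambda t: np.full(np.shape(t), odor.background_rate),
                horizon,
                bg_seed,
                odor.background_rate,
            )
            if peak > 0:
                od = sample_events(
                    lambda t: peak
                    * odor_ramp(t, odor.t_on, odor.t_off, odor.tau_on, odor.tau_off),
                    horizon,
                    od_seed,
                    peak,
                )
            else:
                od = np.empty(0)
            t_all = np.concatenate([bg, od])
            s_all = np.concatenate(
                [np.zeros(len(bg), dtype=np.uint8), np.ones(len(od), dtype=np.uint8)]
            )
            order = np.argsort(t_all, kind="stable")
            times.append(t_all[order])
            source.append(s_all[order])
    return InputEventStream(times=times, source=source)


def make_odor_panel(
    channels,
    n_odors: int,
    seed: int = 0,
    *,
    n_channels: int = 5,
    strong_channel: int | None = None,
    weak_subset_size: int = 2,
    strong_rate: float = 4000.0,
    weak_rate: float = 1000.0,
    saturating: bool = False,
    saturation_rate: float = 4000.0,
    **odor_kwargs,
) -> list[OdorSpec]:
    """Construct an odor panel over the given glomerular channels.

    Two designs are supported:

    * subset panels (default): each odor drives a distinct
      ``weak_subset_size``-subset of ``channels`` at ``weak_rate``; if
      ``strong_channel`` is given it is additionally driven at
      ``strong_rate`` in every odor, and one extra strong-only odor is
      appended when ``n_odors`` equals the subset count plus one.
    * saturating panels (``saturating=True``): every odor drives *all* of
      ``channels``, with seeded per-channel peak rates drawn above
      ``saturation_rate`` so each directly driven channel is saturated.
    """
    channels = list(channels)
    if any(c >= n_channels or c < 0 for c in channels):
        raise ValueError("channels outside the glomerular range")
    rng = np.random.default_rng(seed)
    panel: list[OdorSpec] = []
    if saturating:
        for k in range(n_odors):
            rates = np.zeros(n_channels)
            rates[channels] = saturation_rate * (1.0 + rng.random(len(channels)))
            panel.append(OdorSpec(rates=rates, name=f"odor{k}", **odor_kwargs))
        return panel

    subsets = list(itertools.combinations(channels, weak_subset_size))
    max_odors = len(subsets) + (1 if strong_channel is not None else 0)
    if n_odors > max_odors:
        raise ValueError(
            f"n_odors={n_odors} exceeds the {max_odors} distinct designs available"
        )
    for k in range(min(n_odors, len(subsets))):
        rates = np.zeros(n_channels)
        rates[list(subsets[k])] = weak_rate
        if strong_channel is not None:
            rates[strong_channel] = strong_rate
        panel.append(OdorSpec(rates=rates, name=f"odor{k}", **odor_kwargs))
    if n_odors == len(subsets) + 1 and strong_channel is not None:
        rates = np.zeros(n_channels)
        rates[strong_channel] = strong_rate
        panel.append(OdorSpec(rates=rates, name=f"odor{n_odors - 1}", **odor_kwargs))
    return panel
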