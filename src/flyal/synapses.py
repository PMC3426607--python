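"""Synaptic conductances and ORN-terminal depression.

Three conductance channels are modeled, all driven by instantaneous
transmitter release on presynaptic spikes:

* fast excitation (nACh-type), single-exponential decay, 5-10 ms;
* fast inhibition (GABA-A), single-exponential decay, 10-15 ms;
* slow inhibition (GABA-B), a two-stage linear filter with separate rise
  (~100 ms) and decay (~300 ms) time scales.

ORN output synapses additionally carry an efficacy eta in [0, 1] that
combines two depression mechanisms:

* vesicle depletion: each ORN spike depletes a fraction ``p_ves`` of the
  remaining pool, D <- D + p_ves (1 - D); D recovers to 0 with tau_D;
* presynaptic inhibition: GABAergic drive A_pre from inhibitory local
  neurons onto the ORN terminal suppresses release multiplicatively.

The efficacy is eta = (1 - D) * exp(-s_pre * A_pre): bounded, equal to 1 for
an undepressed terminal, and separating the two mechanisms so the network
family can scan (p_ves, s_pre) independently.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "SynapseParams",
    "SynapseState",
    "update_conductances",
    "update_efficacy",
    "synaptic_current",
    "gabab_impulse_response",
]


@dataclass(frozen=True)
class SynapseParams:
    """Kinetic constants for the three synaptic channels and ORN depression.

    Time constants in ms, potentials in mV.  ``p_ves`` is the fraction of the
    remaining vesicle pool released per ORN spike; ``s_pre`` scales how
    strongly GABAergic drive onto the ORN terminal suppresses release.
    """

    sigma_E: float = 9.0
    sigma_A: float = 12.0
    sigma_B_rise: float = 100.0
    sigma_B_decay: float = 300.0
    VE: float = 0.0
    VI: float = -70.0
    tau_D: float = 300.0
    p_ves: float = 0.2
    s_pre: float = 0.5

    def __post_init__(self) -> None:
        for name in ("sigma_E", "sigma_A", "sigma_B_rise", "sigma_B_decay", "tau_D"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.p_ves <= 1.0:
            raise ValueError(f"p_ves={self.p_ves} outside [0, 1]")
        if self.s_pre < 0:
            raise ValueError("s_pre must be non-negative")
        if self.sigma_B_rise >= self.sigma_B_decay:
            raise ValueError("GABA-B rise constant must be below its decay constant")


@dataclass(frozen=True)
class SynapseState:
    """Conductance accumulators and ORN-terminal depression variables.

    ``gE``/``gA`` are the fast excitatory and GABA-A conductances, ``rB``
    feeds ``gB`` through the slow two-stage filter.  ``D`` is the depleted
    vesicle fraction, ``A_pre`` the accumulated presynaptic GABA drive, and
    ``eta`` the resulting release efficacy.
    """

    gE: float = 0.0
    gA: float = 0.0
    rB: float = 0.0
    gB: float = 0.0
    eta: float = 1.0
    D: float = 0.0
    A_pre: float = 0.0


def _decay(state: SynapseState, dt: float, p: SynapseParams) -> SynapseState:
    """Exact decay of all conductances over an interval dt with no spikes."""
    eE = np.exp(-dt / p.sigma_E)
    eA = np.exp(-dt / p.sigma_A)
    er = np.exp(-dt / p.sigma_B_rise)
    ed = np.exp(-dt / p.sigma_B_decay)
    # exact solution of gB' = (rB - gB)/sigma_d with rB' = -rB/sigma_r
    amp = state.rB * p.sigma_B_rise / (p.sigma_B_rise - p.sigma_B_decay)
    gB = (state.gB - amp) * ed + amp * er
    return replace(state, gE=state.gE * eE, gA=state.gA * eA, rB=state.rB * er, gB=gB)


def update_conductances(
    state: SynapseState,
    presyn_spikes: np.ndarray,
    weights: np.ndarray,
    params: SynapseParams,
    dt: float,
    channel: str = "E",
    eta_pre: np.ndarray | None = None,
) -> SynapseState:
    """Advance postsynaptic conductances by ``dt`` and apply spike increments.

    ``presyn_spikes`` are boolean flags for the presynaptic population and
    ``weights`` the per-connection coupling strengths for the given channel
    ("E", "A" or "B").  Excitatory increments from ORN terminals are scaled by
    the presynaptic efficacies ``eta_pre`` (default 1).  Between spikes each
    conductance decays exponentially with its own time constant; the GABA-B
    channel increments its rise stage ``rB`` which feeds ``gB``.
    """
    spikes = np.asarray(presyn_spikes, dtype=bool)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("synaptic weights must be non-negative")
    state = _decay(state, dt, params)
    if not spikes.any():
        return state
    if channel == "E":
        eta = np.ones_like(w) if eta_pre is None else np.asarray(eta_pre, dtype=float)
        return replace(state, gE=state.gE + float(np.sum(w[spikes] * eta[spikes])))
    if channel == "A":
        return replace(state, gA=state.gA + float(np.sum(w[spikes])))
    if channel == "B":
        return replace(state, rB=state.rB + float(np.sum(w[spikes])))
    raise ValueError(f"unknown channel {channel!r}")


def update_efficacy(
    state: SynapseState,
    orn_spiked: bool,
    params: SynapseParams,
    dt: float,
    gaba_drive: float | None = None,
) -> SynapseState:
    """Advance the ORN-terminal depression variables by ``dt``.

    The depleted fraction D relaxes toward 0 with ``tau_D`` and jumps by
    ``p_ves * (1 - D)`` when the ORN fires, so D stays in [0, 1] without
    clipping.  ``gaba_drive`` is the summed GABA-A + GABA-B conductance that
    inhibitory local neurons deposit on the terminal; if omitted, the
    terminal's own gA + gB accumulators are used.  The efficacy is

        eta = (1 - D) * exp(-s_pre * A_pre).
    """
    D = state.D * np.exp(-dt / params.tau_D)
    if orn_spiked:
        D = D + params.p_ves * (1.0 - D)
    A_pre = float(state.gA + state.gB) if gaba_drive is None else float(gaba_drive)
    if A_pre < 0:
        raise ValueError("presynaptic drive must be non-negative")
    eta = (1.0 - D) * np.exp(-params.s_pre * A_pre)
    return replace(state, D=float(D), A_pre=A_pre, eta=float(eta))


def synaptic_current(g: float, V: float, E_rev: float) -> float:
    """Synaptic current -g (V - E_rev) in uA/cm^2 for unit-scaled conductance.

    Positive (depolarizing) below the reversal potential, so an excitatory
    channel with E_rev = VE drives V upward when V < VE.
    """
    if np.any(np.asarray(g) < 0):
        raise ValueError("conductance must be non-negative")
    return -g * (V - E_rev)


def gabab_impulse_response(t: np.ndarray, params: SynapseParams) -> np.ndarray:
    """Analytic gB response to a unit rB increment at t = 0 (t in ms)."""
    t = np.asarray(t, dtype=float)
    sr, sd = params.sigma_B_rise, params.sigma_B_decay
    amp = sr / (sd - sr)
    return np.where(t >= 0, amp * (np.exp(-t / sd) - np.exp(-t / sr)), 0.0)
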