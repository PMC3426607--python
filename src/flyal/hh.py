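"""Single-compartment Hodgkin-Huxley dynamics shared by ORNs, PNs, LNEs and LNIs.

Every neuron in the antennal-lobe model is a point neuron with the classical
fast sodium and delayed-rectifier potassium currents,

    C dV/dt = -gL (V - VL) - gNa m^3 h (V - ENa) - gK n^4 (V - EK) + I_total,

with first-order gating kinetics dx/dt = alpha_x(V) (1 - x) - beta_x(V) x for
x in {m, h, n}.  The rate functions are the 1952 squid-axon forms expressed in
the modern convention where the resting potential sits near -65 mV.

Integration is fixed-step RK4; spikes are detected as upward threshold
crossings of the membrane potential with linear interpolation between samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "HHParams",
    "HHState",
    "gating_rates",
    "steady_gating",
    "resting_state",
    "step_hh",
    "integrate_hh",
    "detect_spikes",
    "IntegrationError",
]

#: abort threshold for runaway membrane potentials (mV)
V_GUARD = 200.0


class IntegrationError(RuntimeError):
    """Raised when the membrane potential leaves the physical range."""


@dataclass(frozen=True)
class HHParams:
    """Hodgkin-Huxley point-neuron parameters.

    Units follow the standard convention: capacitance in uF/cm^2,
    conductances in mS/cm^2, potentials in mV, time in ms.  Defaults are the
    classical squid-axon constants shifted to a -65 mV rest.
    """

    capacitance: float = 1.0
    gL: float = 0.3
    VL: float = -54.4
    gNa: float = 120.0
    ENa: float = 50.0
    gK: float = 36.0
    EK: float = -77.0
    Vthr: float = 0.0
    dt: float = 0.02

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if min(self.gNa, self.gK, self.gL) < 0:
            raise ValueError("conductances must be non-negative")
        if not self.ENa > self.EK:
            raise ValueError("ENa must exceed EK")


@dataclass(frozen=True)
class HHState:
    """Instantaneous state (V, m, h, n) of one HH neuron."""

    V: float
    m: float
    h: float
    n: float

    def __post_init__(self) -> None:
        for name in ("m", "h", "n"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"gating variable {name}={x} outside [0, 1]")


def _vtrap(x: np.ndarray | float, y: float):
    """x / (exp(x/y) - 1) with the removable singularity at x = 0 filled in."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    # near 0: x/(exp(x/y)-1) ~= y * (1 - x/(2y))
    safe = np.where(small, 1.0, x)
    out = np.where(small, y * (1.0 - x / (2.0 * y)), safe / np.expm1(safe / y))
    return out


def gating_rates(V):
    """Classical HH rate constants at potential ``V`` (mV).

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)`` in 1/ms.
    All rates are non-negative and continuous in V; the removable
    singularities of alpha_m and alpha_n are handled by their analytic limits.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    alpha_m = 0.1 * _vtrap(-(V + 40.0), 10.0)
    beta_m = 4.0 * np.exp(-(V + 65.0) / 18.0)
    alpha_h = 0.07 * np.exp(-(V + 65.0) / 20.0)
    beta_h = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    alpha_n = 0.01 * _vtrap(-(V + 55.0), 10.0)
    beta_n = 0.125 * np.exp(-(V + 65.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


def steady_gating(V: float) -> tuple[float, float, float]:
    """Voltage-clamped steady-state gating values (m_inf, h_inf, n_inf)."""
    am, bm, ah, bh, an, bn = gating_rates(V)
    return float(am / (am + bm)), float(ah / (ah + bh)), float(an / (an + bn))


def _derivs(y: np.ndarray, I_total: float, p: HHParams) -> np.ndarray:
    V, m, h, n = y
    am, bm, ah, bh, an, bn = gating_rates(V)
    I_na = p.gNa * m**3 * h * (V - p.ENa)
    I_k = p.gK * n**4 * (V - p.EK)
    I_leak = p.gL * (V - p.VL)
    dV = (-I_leak - I_na - I_k + I_total) / p.capacitance
    return np.array(
        [dV, am * (1 - m) - bm * m, ah * (1 - h) - bh * h, an * (1 - n) - bn * n]
    )


def step_hh(state: HHState, I_total: float, params: HHParams) -> HHState:
    """Advance one HH neuron by a single RK4 step of length ``params.dt``."""
    if not np.isfinite(I_total):
        raise ValueError("input current must be finite")
    y = np.array([state.V, state.m, state.h, state.n])
    dt = params.dt
    k1 = _derivs(y, I_total, params)
    k2 = _derivs(y + 0.5 * dt * k1, I_total, params)
    k3 = _derivs(y + 0.5 * dt * k2, I_total, params)
    k4 = _derivs(y + dt * k3, I_total, params)
    y = y + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if abs(y[0]) > V_GUARD:
        raise IntegrationError(
            f"|V|={abs(y[0]):.1f} mV exceeded guard {V_GUARD} mV at dt={dt} ms; "
            "reduce dt or check couplings"
        )
    m, h, n = np.clip(y[1:], 0.0, 1.0)
    return HHState(V=float(y[0]), m=float(m), h=float(h), n=float(n))


def resting_state(params: HHParams, t_settle: float = 200.0) -> HHState:
    """Relax a neuron with zero input to its resting fixed point."""
    m, h, n = steady_gating(-65.0)
    state = HHState(V=-65.0, m=m, h=h, n=n)
    n_steps = int(round(t_settle / params.dt))
    for _ in range(n_steps):
        state = step_hh(state, 0.0, params)
    return state


def integrate_hh(
    state: HHState,
    I_trace: np.ndarray,
    params: HHParams,
) -> tuple[np.ndarray, HHState]:
    """Integrate a single neuron against a pre-sampled input-current trace.

    ``I_trace[k]`` is held constant over step k.  Returns the membrane
    potential sampled after each step (prepended with the initial V) and the
    final state.
    """
    V_out = np.empty(len(I_trace) + 1)
    V_out[0] = state.V
    for k, I in enumerate(I_trace):
        state = step_hh(state, float(I), params)
        V_out[k + 1] = state.V
    return V_out, state


def detect_spikes(V_trace: np.ndarray, Vthr: float, dt: float) -> np.ndarray:
    """Spike times (ms) from upward threshold crossings of a sampled V trace.

    The crossing time is linearly interpolated between the bracketing samples,
    so returned times are strictly increasing and need not lie on the dt grid.
    """
    V = np.asarray(V_trace, dtype=float)
    if V.ndim != 1 or len(V) < 2:
        raise ValueError("V_trace must be a 1-d sequence of length >= 2")
    below = V[:-1] < Vthr
    above = V[1:] >= Vthr
    idx = np.nonzero(below & above)[0]
    if len(idx) == 0:
        return np.empty(0)
    frac = (Vthr - V[idx]) / (V[idx + 1] - V[idx])
    return (idx + frac) * dt
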