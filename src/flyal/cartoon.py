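"""Analyzable toy models distilling the two hypotheses.

Variance-coding cartoon
-----------------------
A single conductance-based integrate-and-fire PN driven by ``n_orn``
depressing Poisson ORN synapses.  Each ORN spike makes the PN conductance
jump by ``g (1 - D)`` and the depletion variable jump by ``rho (1 - D)``;
both decay exponentially.  D and G are filtered shot-noise (jump-decay)
processes whose stationary moments are available in closed form from the
moment ODEs -- including the G-D cross-moment -- so the Gaussian
equilibrium description can be checked exactly.  The punchline: as the ORN
rate grows, the mean conductance saturates at g sigma_G / (rho tau_D) while
its variance shrinks, so the PN fires at a nearly constant rate but ever
more regularly: the stimulus is coded in the *variance*.

Reliability-sensitivity cartoon
-------------------------------
Two ORN-LNI pairs, each presynaptically inhibiting the other.  Each LNI is
a perfect phase oscillator dv/dt = i (1 - d) while unfrozen; a spike of one
neuron freezes the other's potential for ``tau_f``.  The steady state is
solvable: with effective speeds a = i_A (1 - d) >= b = i_B (1 - d),

    f_A = a (1 - b tau_f) / (1 - a b tau_f^2),
    f_B = b (1 - a tau_f) / (1 - a b tau_f^2),

and each ISI distribution has exactly two atoms separated by tau_f whose
masses are fixed by the mean (interval lengths of the piecewise-linear
return map).  Increasing tau_f raises both the ISI variance (lower
reliability) and the rate separation f_A - f_B (higher sensitivity): the
tradeoff in its purest form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.optimize import brentq

__all__ = [
    "VarianceCartoonParams",
    "TwoNeuronParams",
    "ReturnMapResult",
    "simulate_variance_cartoon",
    "equilibrium_moments",
    "two_neuron_simulate",
    "closed_form_rates",
    "return_map",
    "iso_rate_tau_family",
    "kc_readout",
]


# --------------------------------------------------------------------------
# variance-coding cartoon
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceCartoonParams:
    """Integrate-and-fire PN driven by depressing Poisson ORN synapses.

    Potentials are in threshold units (reset 0, threshold ``V_T``); time in
    ms; ``rate_hz`` is the per-ORN Poisson rate.  ``rho`` is the fractional
    depletion per spike and ``tau_D`` the recovery time constant; ``g`` the
    conductance jump per (undepressed) spike, decaying with ``sigma_G``.
    """

    n_orn: int = 1
    rate_hz: float = 100.0
    g: float = 0.05
    rho: float = 0.02
    tau_D: float = 500.0
    gL: float = 0.05  # leak rate, 1/ms (20 ms membrane)
    V_reset: float = 0.0
    V_T: float = 1.0
    VE: float = 6.5  # excitatory reversal in threshold units
    sigma_G: float = 5.0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate must be non-negative")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not self.V_reset < self.V_T:
            raise ValueError("reset must lie below threshold")


@njit(cache=True)
def _if_cartoon_loop(
    ev_t, ev_orn, n_orn, horizon, dt, g, rho, tau_D, gL, V_reset, V_T, VE, sigma_G
):
    n_steps = int(horizon / dt)
    D = np.zeros(n_orn)
    V = 0.0
    G = 0.0
    dec_G = np.exp(-dt / sigma_G)
    dec_D = np.exp(-dt / tau_D)
    n_samp = n_steps // 10 + 1
    V_tr = np.zeros(n_samp)
    G_tr = np.zeros(n_samp)
    D_tr = np.zeros(n_samp)
    samp = 0
    spikes = np.empty(int(horizon) * 2 + 64)
    n_spk = 0
    pos = 0
    n_ev = ev_t.shape[0]
    for step in range(n_steps):
        t1 = (step + 1) * dt
        if step % 10 == 0:
            V_tr[samp] = V
            G_tr[samp] = G
            s = 0.0
            for o in range(n_orn):
                s += D[o]
            D_tr[samp] = s / n_orn
            samp += 1
        # continuous part (explicit Euler at fine dt; G frozen within step)
        V = V + dt * (-gL * V + G * (VE - V))
        G *= dec_G
        for o in range(n_orn):
            D[o] *= dec_D
        while pos < n_ev and ev_t[pos] <= t1:
            o = ev_orn[pos]
            G += g * (1.0 - D[o])
            D[o] = D[o] + rho * (1.0 - D[o])
            pos += 1
        if V >= V_T:
            if n_spk < spikes.shape[0]:
                spikes[n_spk] = t1
                n_spk += 1
            V = V_reset
    return spikes[:n_spk], V_tr[:samp], G_tr[:samp], D_tr[:samp]


def simulate_variance_cartoon(
    params: VarianceCartoonParams,
    horizon: float,
    seed: int,
    dt: float = 0.05,
):
    """Simulate the cartoon PN; returns (pn_spikes, traces dict).

    Traces (V, G, mean D over ORNs) are sampled every 10 dt.  ORN spikes are
    homogeneous Poisson at ``rate_hz`` per ORN, seed-reproducible.
    """
    rng = np.random.default_rng(seed)
    lam_ms = params.rate_hz / 1000.0 * params.n_orn
    n_ev = rng.poisson(lam_ms * horizon)
    ev_t = np.sort(rng.random(n_ev) * horizon)
    ev_orn = rng.integers(0, params.n_orn, n_ev)
    spikes, V_tr, G_tr, D_tr = _if_cartoon_loop(
        ev_t,
        ev_orn,
        params.n_orn,
        horizon,
        dt,
        params.g,
        params.rho,
        params.tau_D,
        params.gL,
        params.V_reset,
        params.V_T,
        params.VE,
        params.sigma_G,
    )
    t = np.arange(len(V_tr)) * 10 * dt
    return spikes, {"t": t, "V": V_tr, "G": G_tr, "D": D_tr}


def equilibrium_moments(params: VarianceCartoonParams):
    """Exact stationary moments (mu_D, sigma_D, mu_G, sigma_G) of the cartoon.

    Derived from the stationary moment equations of the joint (G, D)
    jump-decay process driven by Poisson spikes (PASTA gives the jump-time
    distribution).  The conductance jump uses the pre-jump D; the cross
    moment E[GD] is carried exactly, so no Gaussian or decoupling
    approximation enters.  Moments for ``n_orn`` independent ORNs add.
    """
    if params.rate_hz <= 0:
        raise ValueError("rate must be positive for stationary moments")
    r = params.rate_hz / 1000.0  # events per ms per ORN
    rho, tau = params.rho, params.tau_D
    g, sig = params.g, params.sigma_G

    mu_D = r * rho * tau / (1.0 + r * rho * tau)
    if rho == 0:
        mu_D = 0.0
        m2_D = 0.0
    else:
        m2_D = (
            r * (2.0 * rho * (1.0 - rho) * mu_D + rho**2)
            / (2.0 / tau + r * (1.0 - (1.0 - rho) ** 2))
        )
    var_D = max(m2_D - mu_D**2, 0.0)

    mu_G1 = r * g * sig * (1.0 - mu_D)
    # cross moment c = E[G D] for one ORN's (G-contribution, D) pair
    c = (
        r
        * (
            rho * mu_G1
            + g * ((1.0 - rho) * mu_D + rho - (1.0 - rho) * m2_D - rho * mu_D)
        )
        / (1.0 / sig + 1.0 / tau + r * rho)
    )
    m2_G1 = (sig * r / 2.0) * (
        2.0 * g * (mu_G1 - c) + g**2 * (1.0 - 2.0 * mu_D + m2_D)
    )
    var_G1 = max(m2_G1 - mu_G1**2, 0.0)

    n = params.n_orn
    return mu_D, np.sqrt(var_D), n * mu_G1, np.sqrt(n * var_G1)


# --------------------------------------------------------------------------
# two-LNI reliability/sensitivity cartoon
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TwoNeuronParams:
    """The 2-LNI phase-oscillator model with mutual presynaptic inhibition.

    ``i_a`` and ``i_b`` are the ORN inputs in threshold units per ms;
    ``d`` in [0, 1) is the vesicle-depletion factor scaling both inputs;
    ``tau_f`` (ms) is the freeze duration a spike of one neuron imposes on
    the other.  Threshold 1, reset 0 (phase-oscillator convention).
    """

    i_a: float = 0.02
    i_b: float = 0.015
    tau_f: float = 10.0
    d: float = 0.2

    def __post_init__(self) -> None:
        if self.i_a <= 0 or self.i_b <= 0:
            raise ValueError("inputs must be positive")
        if not 0.0 <= self.d < 1.0:
            raise ValueError("d must lie in [0, 1)")
        if self.tau_f < 0:
            raise ValueError("tau_f must be non-negative")

    @property
    def speeds(self) -> tuple[float, float]:
        """Effective phase speeds after depression, (a, b) with a >= b."""
        a = self.i_a * (1.0 - self.d)
        b = self.i_b * (1.0 - self.d)
        return (a, b) if a >= b else (b, a)


@njit(cache=True)
def _two_neuron_loop(a, b, tau_f, vA, vB, n_spikes):
    tA = np.empty(n_spikes)
    tB = np.empty(n_spikes)
    nA = 0
    nB = 0
    t = 0.0
    frA = 0.0  # A frozen until frA
    frB = 0.0
    while nA < n_spikes and nB < n_spikes:
        startA = t if t >= frA else frA
        startB = t if t >= frB else frB
        fireA = startA + (1.0 - vA) / a
        fireB = startB + (1.0 - vB) / b
        t_next = fireA if fireA <= fireB else fireB
        # advance unfrozen phase to t_next
        uA = t_next - startA
        if uA > 0:
            vA += a * uA
        uB = t_next - startB
        if uB > 0:
            vB += b * uB
        both = abs(fireA - fireB) < 1e-15
        if fireA <= fireB or both:
            vA = 0.0
            tA[nA] = t_next
            nA += 1
            frB = t_next + tau_f
        if fireB <= fireA or both:
            vB = 0.0
            tB[nB] = t_next
            nB += 1
            frA = t_next + tau_f
        t = t_next
    return tA[:nA], tB[:nB]


def two_neuron_simulate(
    params: TwoNeuronParams,
    n_spikes: int = 10000,
    v0: tuple[float, float] = (0.0, 0.37),
):
    """Exact event-driven integration of the 2-LNI model.

    Returns (spikes_A, spikes_B) where A is the faster neuron.  Simultaneous
    spikes are processed as both resets before either freeze is applied.
    Deterministic given the initial phases ``v0``.
    """
    a, b = params.speeds
    if params.tau_f * a >= 1.0:
        raise ValueError(
            "tau_f too long: the slower neuron is frozen faster than it can "
            "integrate and never fires"
        )
    return _two_neuron_loop(a, b, params.tau_f, v0[0], v0[1], n_spikes)


def closed_form_rates(params: TwoNeuronParams) -> tuple[float, float]:
    """Steady-state firing rates (f_A, f_B) from unfrozen-time accounting."""
    a, b = params.speeds
    tf = params.tau_f
    if tf * a >= 1.0:
        raise ValueError("regime error: slower neuron never fires (tau_f * a >= 1)")
    den = 1.0 - a * b * tf**2
    return a * (1.0 - b * tf) / den, b * (1.0 - a * tf) / den


@dataclass
class ReturnMapResult:
    """Closed-form steady-state description of the 2-LNI model."""

    rate_a: float
    rate_b: float
    atoms_a: list  # [(isi value ms, mass), ...]
    atoms_b: list
    mean_isi_a: float
    mean_isi_b: float
    var_isi_a: float
    var_isi_b: float
    L1: float  # return-map image sub-interval lengths (normalized)
    L2: float
    map_samples: np.ndarray  # (n, 2) consecutive B-ISI pairs


def return_map(params: TwoNeuronParams, n_map_samples: int = 200) -> ReturnMapResult:
    """Closed-form rates, two-atom ISI distributions and map structure.

    Rates follow from exact unfrozen-time accounting: each spike of one
    neuron removes ``tau_f`` of integration time from the other, giving the
    linear system f_A = a (1 - tau_f f_B), f_B = b (1 - tau_f f_A).  The
    faster neuron's ISI takes values {T_A, T_A + tau_f} and the slower one's
    {T_B + n tau_f, T_B + (n+1) tau_f}; masses are fixed by the mean ISI
    1/f.  ``L1``/``L2`` are the corresponding image-interval lengths of the
    piecewise-linear return map, normalized to unit total.
    """
    a, b = params.speeds
    tf = params.tau_f
    f_a, f_b = closed_form_rates(params)
    T_a, T_b = 1.0 / a, 1.0 / b

    if tf == 0.0:
        atoms_a = [(T_a, 1.0)]
        atoms_b = [(T_b, 1.0)]
        var_a = var_b = 0.0
        L1, L2 = 1.0, 0.0
    else:
        p = f_b / f_a  # fraction of A intervals containing a B spike
        atoms_a = [(T_a, 1.0 - p), (T_a + tf, p)]
        var_a = tf**2 * p * (1.0 - p)
        k_mean = f_a / f_b
        n_lo = int(np.floor(k_mean))
        m = k_mean - n_lo
        atoms_b = [(T_b + n_lo * tf, 1.0 - m), (T_b + (n_lo + 1) * tf, m)]
        var_b = tf**2 * m * (1.0 - m)
        L1, L2 = 1.0 - m, m

    t_a, t_b = two_neuron_simulate(params, n_spikes=max(n_map_samples + 3, 64))
    isi_b = np.diff(t_b)
    samples = np.column_stack([isi_b[:-1], isi_b[1:]])[:n_map_samples]

    mean_a = sum(v * w for v, w in atoms_a)
    mean_b = sum(v * w for v, w in atoms_b)
    return ReturnMapResult(
        rate_a=f_a,
        rate_b=f_b,
        atoms_a=atoms_a,
        atoms_b=atoms_b,
        mean_isi_a=mean_a,
        mean_isi_b=mean_b,
        var_isi_a=var_a,
        var_isi_b=var_b,
        L1=L1,
        L2=L2,
        map_samples=samples,
    )


def iso_rate_tau_family(
    params: TwoNeuronParams,
    target_rate: float,
    tau_grid,
) -> pd.DataFrame:
    """The 1-parameter (tau_f, d) family holding the mean rate fixed.

    For each tau_f on the grid, solves for the depletion factor d in [0, 1)
    such that the closed-form mean rate (f_A + f_B)/2 equals
    ``target_rate``.  The returned d(tau_f) curve is monotonically
    decreasing: trading vesicle depletion (type-B) for presynaptic
    inhibition (type-A).  Also tabulates the closed-form sensitivity proxy
    ``dmu = f_A - f_B`` and the count-noise scale
    ``sigma_bar = sqrt((f_A^3 var_A + f_B^3 var_B)/2)`` per unit time.
    Rows where no root exists in [0, 1) are flagged with d = NaN.
    """
    base_mean = (params.i_a + params.i_b) / 2.0
    if target_rate >= base_mean or target_rate <= 0:
        raise ValueError("target rate must be achievable at tau_f = 0 with d in (0,1)")
    rows = []
    for tf in tau_grid:
        def mean_rate(d):
            fa, fb = closed_form_rates(
                TwoNeuronParams(i_a=params.i_a, i_b=params.i_b, tau_f=tf, d=d)
            )
            return (fa + fb) / 2.0

        # feasible d must keep the slower neuron firing: a(d) tau_f < 1
        d_min = 0.0
        a0 = max(params.i_a, params.i_b)
        if tf > 0:
            d_min = max(0.0, 1.0 - 1.0 / (a0 * tf) + 1e-9)
        try:
            hi = mean_rate(d_min)
            if hi < target_rate:
                raise ValueError
            d_star = brentq(
                lambda d: mean_rate(d) - target_rate, d_min, 1.0 - 1e-12, xtol=1e-12
            )
        except ValueError:
            rows.append(
                {
                    "tau_f": tf,
                    "d": np.nan,
                    "rate_a": np.nan,
                    "rate_b": np.nan,
                    "var_isi_a": np.nan,
                    "var_isi_b": np.nan,
                    "dmu": np.nan,
                    "sigma_bar": np.nan,
                }
            )
            continue
        rm = return_map(
            TwoNeuronParams(i_a=params.i_a, i_b=params.i_b, tau_f=tf, d=d_star),
            n_map_samples=0,
        )
        sigma_bar = np.sqrt(
            (rm.rate_a**3 * rm.var_isi_a + rm.rate_b**3 * rm.var_isi_b) / 2.0
        )
        rows.append(
            {
                "tau_f": tf,
                "d": d_star,
                "rate_a": rm.rate_a,
                "rate_b": rm.rate_b,
                "var_isi_a": rm.var_isi_a,
                "var_isi_b": rm.var_isi_b,
                "dmu": rm.rate_a - rm.rate_b,
                "sigma_bar": sigma_bar,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Kenyon-cell readout
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class KCParams:
    """High-threshold conductance-based IF readout neuron."""

    w: float = 0.03  # conductance jump per PN spike
    sigma_G: float = 5.0
    gL: float = 0.1  # fast leak: only coincident input drives it over
    V_T: float = 1.0
    V_reset: float = 0.0
    VE: float = 6.5


def kc_readout(
    pn_spikes: np.ndarray,
    params: KCParams | None = None,
    horizon: float | None = None,
    dt: float = 0.05,
):
    """Drive a putative Kenyon cell with a PN spike train.

    The KC is a leaky conductance-based IF neuron with a fast leak, so
    regular input at moderate rate holds an elevated subthreshold voltage
    while clustered (bursty) input at the same mean rate makes it fire.
    Returns (kc_spike_times, traces dict).
    """
    params = params or KCParams()
    pn_spikes = np.sort(np.asarray(pn_spikes, dtype=float))
    if horizon is None:
        horizon = float(pn_spikes[-1] + 50.0) if len(pn_spikes) else 100.0
    n_steps = int(horizon / dt)
    V = 0.0
    G = 0.0
    dec = np.exp(-dt / params.sigma_G)
    pos = 0
    out = []
    V_tr = np.empty(n_steps)
    for step in range(n_steps):
        t1 = (step + 1) * dt
        V = V + dt * (-params.gL * V + G * (params.VE - V))
        G *= dec
        while pos < len(pn_spikes) and pn_spikes[pos] <= t1:
            G += params.w
            pos += 1
        if V >= params.V_T:
            out.append(t1)
            V = params.V_reset
        V_tr[step] = V
    t = (np.arange(n_steps) + 1) * dt
    return np.asarray(out), {"t": t, "V": V_tr}
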