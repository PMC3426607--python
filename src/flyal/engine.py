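"""Trial orchestration for the full network model.

``run_trial`` couples the HH dynamics, synaptic kinetics, ORN-terminal
depression and Poisson odor input into one deterministic integration;
``run_panel`` and ``run_scan`` organize trials over odor panels and over the
(p_ves, s_pre) depression-parameter grid.  The benchmark protocols probe the
depressing ORN synapse directly (EPSC attenuation under forced periodic
activation) and the presynaptic-inhibition pathway (suppression of
spontaneous EPSPs in an odor-shielded glomerulus).

Randomness enters through exactly two doors, both seed-controlled: the
Poisson input realization and the initial membrane-potential jitter.
Per-(odor, trial) seeds are keyed by the odor name, not its position in the
panel, so shuffling a panel never changes any individual trial.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel
from .datasets import SpikeDataset
from .hh import HHParams, IntegrationError, steady_gating
from .network import CLASSES, ArchitectureConfig, NetworkSpec, build_network
from .odors import OdorSpec, background_odor, odor_input_streams
from .synapses import SynapseParams

__all__ = [
    "SimParams",
    "TrialResult",
    "ScanResult",
    "run_trial",
    "run_panel",
    "run_scan",
    "epsc_attenuation_protocol",
    "shielded_suppression_protocol",
    "trial_seed",
]


@dataclass(frozen=True)
class SimParams:
    """Engine-level knobs: integration step, guards, input kernel, probes."""

    dt: float = 0.02
    tau_kernel: float = 2.0
    guard: float = 200.0
    init_jitter: float = 5.0  # uniform V jitter around rest at t=0 (mV)
    analysis_window: float = 400.0  # post-onset window for count statistics (ms)
    trace_stride: int = 25  # record probes every stride steps (0.5 ms at dt=0.02)
    max_rate_per_neuron: float = 500.0  # spike-buffer sizing (Hz)


@dataclass
class TrialResult:
    """Spikes (and optional probe traces) from one odor presentation."""

    spikes: pd.DataFrame
    odor: str
    seed: int
    horizon: float
    traces: dict | None = None

    def spike_times(self, neuron_id: int) -> np.ndarray:
        df = self.spikes[self.spikes["neuron_id"] == neuron_id]
        return np.sort(df["spike_time_ms"].values)


@dataclass
class ScanResult:
    """PN spike-count tensors over the (p_ves, s_pre) grid.

    ``counts[i, j, o, t]`` is the mean spike count per PN of the target
    glomerulus in the analysis window, for grid point (p_ves_grid[i],
    s_pre_grid[j]), odor o, trial t.  ``mean_map``/``std_map`` reduce over
    odors and trials (std is the trial-to-trial standard deviation, averaged
    over odors).
    """

    p_ves_grid: np.ndarray
    s_pre_grid: np.ndarray
    counts: np.ndarray
    odors: list
    target_glomerulus: int
    window: tuple

    @property
    def mean_map(self) -> np.ndarray:
        return self.counts.mean(axis=(2, 3))

    @property
    def std_map(self) -> np.ndarray:
        return self.counts.std(axis=3, ddof=1).mean(axis=2)


def _csr(W: np.ndarray):
    n = W.shape[0]
    indptr = np.zeros(n + 1, dtype=np.int64)
    targets = []
    weights = []
    for i in range(n):
        nz = np.nonzero(W[i])[0]
        indptr[i + 1] = indptr[i] + len(nz)
        targets.append(nz)
        weights.append(W[i, nz])
    tgt = np.concatenate(targets) if targets else np.empty(0, dtype=np.int64)
    wgt = np.concatenate(weights) if weights else np.empty(0)
    return indptr, tgt.astype(np.int64), wgt.astype(np.float64)


def trial_seed(base_seed: int, odor_name: str, trial: int) -> int:
    """Stable per-(odor, trial) seed, independent of panel order."""
    key = np.random.SeedSequence(
        [int(base_seed), zlib.crc32(odor_name.encode()), int(trial)]
    )
    return int(key.generate_state(1, dtype=np.uint32)[0] % (2**31))


def run_trial(
    network: NetworkSpec,
    odor: OdorSpec,
    horizon: float,
    seed: int,
    sim: SimParams | None = None,
    synapses: SynapseParams | None = None,
    hh: HHParams | None = None,
    probes=(),
) -> TrialResult:
    """Integrate one odor presentation of the full network.

    Deterministic given (network, odor, seed).  ``probes`` are neuron ids
    whose V, gE, eta and D traces are recorded every ``sim.trace_stride``
    steps.  Integration failures raise :class:`IntegrationError` naming the
    neuron and time.
    """
    sim = sim or SimParams()
    syn = synapses or SynapseParams(
        p_ves=network.config.p_ves, s_pre=network.config.s_pre
    )
    if (syn.p_ves, syn.s_pre) != (network.config.p_ves, network.config.s_pre):
        syn = SynapseParams(
            **{
                **{f: getattr(syn, f) for f in syn.__dataclass_fields__},
                "p_ves": network.config.p_ves,
                "s_pre": network.config.s_pre,
            }
        )
    hh = hh or HHParams(dt=sim.dt)
    cfg = network.config
    if odor.n_channels != cfg.n_glomeruli:
        raise ValueError(
            f"odor has {odor.n_channels} channels but network has "
            f"{cfg.n_glomeruli} glomeruli"
        )

    ss = np.random.SeedSequence(seed)
    input_ss, init_ss = ss.spawn(2)

    stream = odor_input_streams(odor, cfg.n_orn, horizon, input_ss)
    ev_indptr = np.zeros(stream.n_orns + 1, dtype=np.int64)
    for o, t in enumerate(stream.times):
        ev_indptr[o + 1] = ev_indptr[o] + len(t)
    ev_times = (
        np.concatenate(stream.times) if stream.n_orns else np.empty(0)
    ).astype(np.float64)
    strengths = np.where(
        np.concatenate(stream.source).astype(bool) if stream.n_orns else np.empty(0, bool),
        odor.odor_strength,
        odor.background_strength,
    ).astype(np.float64)

    n = network.n_neurons
    cls_idx = network.neurons["cls"].map({c: i for i, c in enumerate(CLASSES)}).values
    cls_idx = cls_idx.astype(np.uint8)
    orn_of = np.full(n, -1, dtype=np.int64)
    orn_ids = np.nonzero(cls_idx == 0)[0]
    orn_of[orn_ids] = np.arange(len(orn_ids))

    rng = np.random.default_rng(init_ss)
    V = -65.0 + sim.init_jitter * (2.0 * rng.random(n) - 1.0)
    m = np.empty(n)
    h = np.empty(n)
    ngate = np.empty(n)
    for i in range(n):
        m[i], h[i], ngate[i] = steady_gating(V[i])

    iE, tE, wE = _csr(network.W_E)
    iA, tA, wA = _csr(network.W_A)
    iB, tB, wB = _csr(network.W_B)

    n_steps = int(round(horizon / sim.dt))
    max_spikes = int(n * horizon / 1000.0 * sim.max_rate_per_neuron) + 1024
    probe_ids = np.asarray(list(probes), dtype=np.int64)

    (
        spk_id,
        spk_t,
        tr_V,
        tr_gE,
        tr_eta,
        tr_D,
        status,
        fail_neuron,
        fail_time,
    ) = _kernel.run_network(
        sim.dt,
        n_steps,
        cls_idx,
        V,
        m,
        h,
        ngate,
        iE,
        tE,
        wE,
        iA,
        tA,
        wA,
        iB,
        tB,
        wB,
        orn_of,
        ev_indptr,
        ev_times,
        strengths,
        hh.capacitance,
        hh.gL,
        hh.VL,
        hh.gNa,
        hh.ENa,
        hh.gK,
        hh.EK,
        hh.Vthr,
        syn.sigma_E,
        syn.sigma_A,
        syn.sigma_B_rise,
        syn.sigma_B_decay,
        syn.VE,
        syn.VI,
        syn.tau_D,
        syn.p_ves,
        syn.s_pre,
        sim.tau_kernel,
        sim.guard,
        probe_ids,
        sim.trace_stride,
        max_spikes,
    )
    if status == 2:
        raise IntegrationError(
            f"neuron {fail_neuron} ({network.neurons['cls'].iloc[fail_neuron]}) "
            f"exceeded the {sim.guard} mV guard at t={fail_time:.2f} ms (dt={sim.dt})"
        )
    if status == 1:
        raise IntegrationError("spike buffer overflow; raise max_rate_per_neuron")

    spikes = pd.DataFrame(
        {
            "neuron_id": spk_id,
            "cls": network.neurons["cls"].values[spk_id],
            "glomerulus": network.neurons["glomerulus"].values[spk_id],
            "spike_time_ms": spk_t,
        }
    )
    traces = None
    if len(probe_ids):
        t_grid = np.arange(tr_V.shape[1]) * sim.dt * sim.trace_stride
        traces = {
            "t": t_grid,
            "neuron_ids": probe_ids,
            "V": tr_V,
            "gE": tr_gE,
            "eta": tr_eta,
            "D": tr_D,
        }
    return TrialResult(
        spikes=spikes, odor=odor.name, seed=seed, horizon=horizon, traces=traces
    )


def run_panel(
    network: NetworkSpec,
    panel,
    n_trials: int,
    horizon: float,
    base_seed: int,
    sim: SimParams | None = None,
    synapses: SynapseParams | None = None,
    out_path=None,
) -> SpikeDataset:
    """Present every odor of the panel ``n_trials`` times.

    Seeds are keyed by (base_seed, odor name, trial index); results are
    appended to ``out_path`` as tab-separated text incrementally when given.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    frames = []
    first_write = True
    for odor in panel:
        for trial in range(n_trials):
            seed = trial_seed(base_seed, odor.name, trial)
            res = run_trial(network, odor, horizon, seed, sim=sim, synapses=synapses)
            df = res.spikes.copy()
            df.insert(0, "odor", odor.name)
            df.insert(0, "trial", trial)
            frames.append(df)
            if out_path is not None:
                try:
                    if first_write:
                        with open(out_path, "w") as fh:
                            fh.write(f"# horizon_ms={horizon}\n")
                            fh.write(f"# base_seed={base_seed}\n")
                    df.to_csv(
                        out_path, sep="\t", index=False, mode="a", header=first_write
                    )
                except OSError as exc:
                    raise OSError(f"failed writing spike table to {out_path}") from exc
                first_write = False
    spikes = pd.concat(frames, ignore_index=True)
    return SpikeDataset(
        spikes=spikes,
        horizon=horizon,
        metadata={"base_seed": base_seed, "n_trials": n_trials},
    )


def run_scan(
    family,
    panel,
    n_trials: int,
    horizon: float,
    base_seed: int,
    target_glomerulus: int = 0,
    window: tuple[float, float] | None = None,
    sim: SimParams | None = None,
) -> ScanResult:
    """Run the (p_ves, s_pre) scan of the iso-rate network family.

    ``family`` is the grid of configs from
    :func:`flyal.network.iso_rate_family` (shared wiring seed).  For each
    grid point the panel is presented with *matched* per-(odor, trial) seeds,
    so differences across the grid reflect only the depression parameters.
    """
    sim = sim or SimParams()
    p_grid = np.array([row[0].p_ves for row in family])
    s_grid = np.array([c.s_pre for c in family[0]])
    if window is None:
        t_on = panel[0].t_on
        window = (t_on, t_on + sim.analysis_window)
    counts = np.zeros((len(p_grid), len(s_grid), len(panel), n_trials))
    for i, row in enumerate(family):
        for j, cfg in enumerate(row):
            net = build_network(cfg)
            pn_ids = net.ids_of("PN", target_glomerulus)
            for o, odor in enumerate(panel):
                for t in range(n_trials):
                    seed = trial_seed(base_seed, odor.name, t)
                    res = run_trial(net, odor, horizon, seed, sim=sim)
                    df = res.spikes
                    sel = (
                        df["neuron_id"].isin(pn_ids)
                        & (df["spike_time_ms"] >= window[0])
                        & (df["spike_time_ms"] < window[1])
                    )
                    counts[i, j, o, t] = sel.sum() / len(pn_ids)
    return ScanResult(
        p_ves_grid=p_grid,
        s_pre_grid=s_grid,
        counts=counts,
        odors=[o.name for o in panel],
        target_glomerulus=target_glomerulus,
        window=window,
    )


def epsc_attenuation_protocol(
    network: NetworkSpec,
    drive_freqs,
    baseline_freq: float = 5.0,
    n_equil_cycles: int = 200,
    n_test_cycles: int = 60,
    synapses: SynapseParams | None = None,
    target_pn: int | None = None,
):
    """EPSC attenuation of the depressing ORN synapse under forced activation.

    The ORN synapses onto one PN are activated periodically at
    ``baseline_freq`` until the vesicle pools equilibrate, then stepped to
    each test frequency; the per-activation EPSC peak (the efficacy-scaled
    summed conductance jump) is recorded.  Returns a dict keyed by frequency
    with arrays ``t`` (ms from the frequency step), ``envelope`` (peak EPSC
    normalized to the first test activation) and the steady-state mean
    depletion ``D_ss``.

    Only the feedforward depletion pathway operates here (the forced
    activations bypass ORN somata, so no LNI recruitment): with
    ``p_ves = 0`` the envelope is flat.
    """
    syn = synapses or SynapseParams(
        p_ves=network.config.p_ves, s_pre=network.config.s_pre
    )
    p, tau = network.config.p_ves, syn.tau_D
    if target_pn is None:
        target_pn = int(network.ids_of("PN")[0])
    w_total = float(network.W_E[:, target_pn].sum())

    out = {}
    for f in drive_freqs:
        if f <= 0:
            raise ValueError("drive frequencies must be positive")
        # equilibrate at baseline
        D = 0.0
        T0 = 1000.0 / baseline_freq
        for _ in range(n_equil_cycles):
            D = D * np.exp(-T0 / tau)
            D = D + p * (1.0 - D)
        T = 1000.0 / f
        t = np.arange(n_test_cycles) * T
        peaks = np.empty(n_test_cycles)
        D_trace = np.empty(n_test_cycles)
        for k in range(n_test_cycles):
            D = D * np.exp(-T / tau) if k > 0 else D * np.exp(-T0 / tau)
            D_trace[k] = D
            peaks[k] = (1.0 - D) * w_total
            D = D + p * (1.0 - D)
        out[float(f)] = {
            "t": t,
            "envelope": peaks / peaks[0],
            "D_ss": float(D_trace[-5:].mean()),
        }
    return out


def attenuation_time(envelope: np.ndarray, t: np.ndarray) -> float:
    """Time to reach the (1+e^-1)/2 attenuation level of a decaying envelope."""
    lo = envelope[-1]
    level = lo + (1.0 + np.e**-1) / 2.0 * (envelope[0] - lo)
    below = np.nonzero(envelope <= level)[0]
    if len(below) == 0:
        return float("inf")
    k = below[0]
    if k == 0:
        return float(t[0])
    # linear interpolation between the bracketing activations
    f = (envelope[k - 1] - level) / (envelope[k - 1] - envelope[k])
    return float(t[k - 1] + f * (t[k] - t[k - 1]))


def shielded_suppression_protocol(
    network: NetworkSpec,
    panel,
    shielded_glomerulus: int,
    horizon: float = 1500.0,
    base_seed: int = 0,
    sim: SimParams | None = None,
):
    """Correlate total ORN activity with suppression of spontaneous PN EPSPs.

    Every panel odor must leave the shielded glomerulus undriven, so its PNs
    receive only spontaneous spikes from their own ORNs.  For each odor the
    mean release efficacy of the shielded glomerulus' ORN terminals during
    the stimulus window -- the amplitude factor of the spontaneous EPSPs the
    PNs see -- is compared between a background-only presentation and the
    odor presentation with matched seeds.  The drop is the EPSP suppression:
    zero when presynaptic inhibition is off (the shielded ORNs' own firing,
    hence vesicle depletion, is unchanged), positive and growing with total
    network ORN activity when LNIs reach the shielded terminals.  Returns a
    DataFrame (odor, total_orn_spikes, suppression, v_suppression), the last
    column being the raw mean-membrane-potential difference of the PNs.
    """
    sim = sim or SimParams()
    cfg = network.config
    for odor in panel:
        if odor.rates[shielded_glomerulus] > 0:
            raise ValueError(
                f"odor {odor.name!r} drives the shielded glomerulus "
                f"{shielded_glomerulus}"
            )
    pn_ids = network.ids_of("PN", shielded_glomerulus)
    orn_ids = network.ids_of("ORN", shielded_glomerulus)
    probes = list(pn_ids) + list(orn_ids)
    n_pn = len(pn_ids)
    rows = []
    for odor in panel:
        seed = trial_seed(base_seed, odor.name, 0)
        bg = background_odor(
            cfg.n_glomeruli,
            t_on=odor.t_on,
            t_off=odor.t_off,
            background_strength=odor.background_strength,
            odor_strength=odor.odor_strength,
        )
        res_bg = run_trial(network, bg, horizon, seed, sim=sim, probes=probes)
        res_od = run_trial(network, odor, horizon, seed, sim=sim, probes=probes)
        t = res_bg.traces["t"]
        win = (t >= odor.t_on) & (t < min(odor.t_off, horizon))
        eta_bg = res_bg.traces["eta"][n_pn:, win].mean()
        eta_od = res_od.traces["eta"][n_pn:, win].mean()
        v_bg = res_bg.traces["V"][:n_pn, win].mean()
        v_od = res_od.traces["V"][:n_pn, win].mean()
        orn_spikes = int((res_od.spikes["cls"] == "ORN").sum())
        rows.append(
            {
                "odor": odor.name,
                "total_orn_spikes": orn_spikes,
                "suppression": float(eta_bg - eta_od),
                "v_suppression": float(v_bg - v_od),
            }
        )
    return pd.DataFrame(rows)
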