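"""Numba-compiled inner loop of the full antennal-lobe network integration.

One fixed-step pass couples, per dt:

1. membrane currents from the frozen synaptic conductances (ORN somata see
   only their input-kernel current, never synaptic conductances);
2. an RK4 advance of (V, m, h, n) for every neuron;
3. exact exponential decay of the conductance accumulators, the ORN
   depletion variables D and the input-kernel states;
4. deposit of input events falling inside the step onto the ORN kernels;
5. spike detection (interpolated upward threshold crossing) and synaptic
   delivery: ORN spikes deposit efficacy-scaled excitation and deplete
   their vesicle pool; LNI spikes feed GABA onto somata and ORN terminals.

Everything is float64 and deterministic given the pre-sampled event streams
and initial state.
"""

import numpy as np
from numba import njit

# cell-class codes shared with flyal.network.CLASSES
ORN, PN, LNE, LNI = 0, 1, 2, 3


@njit(cache=True)
def _hh_derivs(V, m, h, n, I, C, gL, VL, gNa, ENa, gK, EK):
    # classical HH rates, -65 mV rest convention, with removable singularities
    x = -(V + 40.0)
    if abs(x) < 1e-6:
        am = 0.1 * 10.0 * (1.0 - x / 20.0)
    else:
        am = 0.1 * x / (np.expm1(x / 10.0))
    bm = 4.0 * np.exp(-(V + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(V + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(V + 35.0) / 10.0))
    x = -(V + 55.0)
    if abs(x) < 1e-6:
        an = 0.01 * 10.0 * (1.0 - x / 20.0)
    else:
        an = 0.01 * x / (np.expm1(x / 10.0))
    bn = 0.125 * np.exp(-(V + 65.0) / 80.0)
    dV = (
        -gL * (V - VL)
        - gNa * m * m * m * h * (V - ENa)
        - gK * n * n * n * n * (V - EK)
        + I
    ) / C
    dm = am * (1.0 - m) - bm * m
    dh = ah * (1.0 - h) - bh * h
    dn = an * (1.0 - n) - bn * n
    return dV, dm, dh, dn


@njit(cache=True)
def run_network(
    dt,
    n_steps,
    cls_idx,  # (n,) uint8
    V,
    m,
    h,
    n_gate,  # (n,) float64 state, modified in place
    indptr_E,
    targets_E,
    weights_E,
    indptr_A,
    targets_A,
    weights_A,
    indptr_B,
    targets_B,
    weights_B,
    orn_of,  # (n,) int64: index into ORN arrays, -1 for non-ORNs
    ev_indptr,  # (n_orn+1,)
    ev_times,
    ev_strength,
    C_m,
    gL,
    VL,
    gNa,
    ENa,
    gK,
    EK,
    Vthr,
    sigma_E,
    sigma_A,
    sigma_Br,
    sigma_Bd,
    VE,
    VI,
    tau_D,
    p_ves,
    s_pre,
    tau_kernel,
    guard,
    probe_ids,  # (n_probe,) int64 (may be empty)
    trace_stride,
    max_spikes,
):
    """Integrate the network; returns spike arrays, traces and a status code.

    status 0 = ok, 1 = spike buffer overflow, 2 = |V| guard exceeded.
    """
    n = V.shape[0]
    n_orn = ev_indptr.shape[0] - 1

    gE = np.zeros(n)
    gA = np.zeros(n)
    rB = np.zeros(n)
    gB = np.zeros(n)
    D = np.zeros(n_orn)
    sIn = np.zeros(n_orn)
    ev_pos = ev_indptr[:-1].copy()

    dec_E = np.exp(-dt / sigma_E)
    dec_A = np.exp(-dt / sigma_A)
    dec_r = np.exp(-dt / sigma_Br)
    dec_d = np.exp(-dt / sigma_Bd)
    amp_B = sigma_Br / (sigma_Br - sigma_Bd)
    dec_D = np.exp(-dt / tau_D)
    dec_k = np.exp(-dt / tau_kernel)

    spike_id = np.empty(max_spikes, dtype=np.int64)
    spike_t = np.empty(max_spikes, dtype=np.float64)
    n_spk = 0

    n_probe = probe_ids.shape[0]
    n_samp = (n_steps // trace_stride + 1) if n_probe > 0 else 0
    tr_V = np.zeros((n_probe, n_samp))
    tr_gE = np.zeros((n_probe, n_samp))
    tr_eta = np.zeros((n_probe, n_samp))
    tr_D = np.zeros((n_probe, n_samp))
    samp = 0

    status = 0
    fail_neuron = -1
    fail_time = 0.0

    V_prev = np.empty(n)

    for step in range(n_steps):
        t0 = step * dt
        t1 = t0 + dt

        if n_probe > 0 and step % trace_stride == 0:
            for q in range(n_probe):
                i = probe_ids[q]
                tr_V[q, samp] = V[i]
                tr_gE[q, samp] = gE[i]
                oi = orn_of[i]
                if oi >= 0:
                    tr_eta[q, samp] = (1.0 - D[oi]) * np.exp(
                        -s_pre * (gA[i] + gB[i])
                    )
                    tr_D[q, samp] = D[oi]
            samp += 1

        # 1-2: currents and RK4 advance
        for i in range(n):
            V_prev[i] = V[i]
            if cls_idx[i] == ORN:
                I = sIn[orn_of[i]]
            else:
                I = (
                    -gE[i] * (V[i] - VE)
                    - (gA[i] + gB[i]) * (V[i] - VI)
                )
            v0 = V[i]
            m0 = m[i]
            h0 = h[i]
            n0 = n_gate[i]
            k1v, k1m, k1h, k1n = _hh_derivs(v0, m0, h0, n0, I, C_m, gL, VL, gNa, ENa, gK, EK)
            k2v, k2m, k2h, k2n = _hh_derivs(
                v0 + 0.5 * dt * k1v,
                m0 + 0.5 * dt * k1m,
                h0 + 0.5 * dt * k1h,
                n0 + 0.5 * dt * k1n,
                I, C_m, gL, VL, gNa, ENa, gK, EK,
            )
            k3v, k3m, k3h, k3n = _hh_derivs(
                v0 + 0.5 * dt * k2v,
                m0 + 0.5 * dt * k2m,
                h0 + 0.5 * dt * k2h,
                n0 + 0.5 * dt * k2n,
                I, C_m, gL, VL, gNa, ENa, gK, EK,
            )
            k4v, k4m, k4h, k4n = _hh_derivs(
                v0 + dt * k3v,
                m0 + dt * k3m,
                h0 + dt * k3h,
                n0 + dt * k3n,
                I, C_m, gL, VL, gNa, ENa, gK, EK,
            )
            V[i] = v0 + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
            mm = m0 + dt / 6.0 * (k1m + 2.0 * k2m + 2.0 * k3m + k4m)
            hh = h0 + dt / 6.0 * (k1h + 2.0 * k2h + 2.0 * k3h + k4h)
            nn = n0 + dt / 6.0 * (k1n + 2.0 * k2n + 2.0 * k3n + k4n)
            m[i] = min(max(mm, 0.0), 1.0)
            h[i] = min(max(hh, 0.0), 1.0)
            n_gate[i] = min(max(nn, 0.0), 1.0)
            if abs(V[i]) > guard:
                status = 2
                fail_neuron = i
                fail_time = t1
        if status == 2:
            break

        # 3: exact decays
        for i in range(n):
            a = amp_B * rB[i]
            gB[i] = (gB[i] - a) * dec_d + a * dec_r
            gE[i] *= dec_E
            gA[i] *= dec_A
            rB[i] *= dec_r
        for o in range(n_orn):
            D[o] *= dec_D
            sIn[o] *= dec_k

        # 4: input events in (t0, t1]
        for o in range(n_orn):
            pos = ev_pos[o]
            end = ev_indptr[o + 1]
            while pos < end and ev_times[pos] <= t1:
                sIn[o] += ev_strength[pos]
                pos += 1
            ev_pos[o] = pos

        # 5: spikes and delivery
        for i in range(n):
            if V_prev[i] < Vthr and V[i] >= Vthr:
                if n_spk >= max_spikes:
                    status = 1
                    break
                frac = (Vthr - V_prev[i]) / (V[i] - V_prev[i])
                spike_id[n_spk] = i
                spike_t[n_spk] = t0 + frac * dt
                n_spk += 1
                if cls_idx[i] == ORN:
                    oi = orn_of[i]
                    eta = (1.0 - D[oi]) * np.exp(-s_pre * (gA[i] + gB[i]))
                    for e in range(indptr_E[i], indptr_E[i + 1]):
                        gE[targets_E[e]] += weights_E[e] * eta
                    D[oi] = D[oi] + p_ves * (1.0 - D[oi])
                else:
                    for e in range(indptr_E[i], indptr_E[i + 1]):
                        gE[targets_E[e]] += weights_E[e]
                    for e in range(indptr_A[i], indptr_A[i + 1]):
                        gA[targets_A[e]] += weights_A[e]
                    for e in range(indptr_B[i], indptr_B[i + 1]):
                        rB[targets_B[e]] += weights_B[e]
        if status == 1:
            break

    return (
        spike_id[:n_spk],
        spike_t[:n_spk],
        tr_V,
        tr_gE,
        tr_eta,
        tr_D,
        status,
        fail_neuron,
        fail_time,
    )
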