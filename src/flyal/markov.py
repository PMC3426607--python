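"""Discrete-state ORN-LNI network: exact equilibrium analysis and the
subnetwork (weak-coupling) expansion.

Each ORN-LNI pair k carries three binary state variables: v (LNI firing),
d (vesicle depletion at the ORN synapse) and a (presynaptic inhibition of
the ORN terminal) -- 8 states per pair, 8^N jointly.  Per time step, with
input c_k ~ Bernoulli(lambda_k):

* v: from 0, fires with probability c_k * P0 * r(d, a) where
  r(d, a) = logistic(gamma (1 - d - a)) / logistic(gamma) is the logistic
  reduction (1 when undepressed, strongly reduced when d = 1 or a = 1);
  from 1, returns to 0 with probability 1/tau_on.
* d: from 0, set with probability p * c_k (depletion rides on input);
  from 1, recovers with probability 1/tau_off.
* a: from 0, set with probability 1 - exp(-S sum_j A[j, k] v_j) (smooth in
  S and in every edge weight, which is what makes exact operator
  differentiation possible); from 1, recovers with probability 1/tau_off.

With S = 0 the joint evolution operator factorizes into a tensor product of
per-pair operators.  For small coupling, equilibrium quantities expand in
the edge strengths; the terms correspond to connectivity motifs (autapse,
in-edge, fan-in, chain).  The vesicle parameter p is co-varied along the
expansion to hold the target firing rate fixed, so the expansion isolates
how shifting depression from vesicle depletion to presynaptic inhibition
(type-B -> type-A) changes reliability (ISI variance) and sensitivity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.stats import binom

from . import _jets as J

__all__ = [
    "MarkovNet",
    "ExpansionTerms",
    "pair_transition_matrix",
    "build_full_operator",
    "equilibrium",
    "rate_and_isi",
    "sensitivity",
    "iso_rate_direction",
    "subnetwork_expansion",
    "hypothesis2_check",
    "er_ncrit",
]

MAX_EXACT_PAIRS = 4


def _logistic(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class MarkovNet:
    """Parameters of the discrete-state ORN-LNI network.

    ``A[j, k] > 0`` means LNI j presynaptically inhibits ORN k; ``S`` is the
    overall presynaptic-inhibition strength and ``p`` the vesicle-depletion
    strength.  ``tau_on``/``tau_off`` are the persistence times (in steps)
    of the active and refractory-like states; ``P0`` the undepressed firing
    probability given input.
    """

    lambdas: np.ndarray
    A: np.ndarray
    p: float = 0.3
    S: float = 0.2
    tau_on: float = 2.0
    tau_off: float = 6.0
    P0: float = 0.5
    steepness: float = 4.0

    def __post_init__(self) -> None:
        lam = np.atleast_1d(np.asarray(self.lambdas, dtype=float))
        A = np.asarray(self.A, dtype=float)
        if A.shape != (len(lam), len(lam)):
            raise ValueError("A must be (N, N) matching lambdas")
        if np.any(A < 0):
            raise ValueError("A entries must be non-negative")
        if np.any((lam < 0) | (lam > 1)):
            raise ValueError("input probabilities must lie in [0, 1]")
        for name in ("p", "P0"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.S < 0:
            raise ValueError("S must be non-negative")
        object.__setattr__(self, "lambdas", lam)
        object.__setattr__(self, "A", A)

    @property
    def n_pairs(self) -> int:
        return len(self.lambdas)

    def reduction(self, d: int, a: int) -> float:
        g = self.steepness
        return _logistic(g * (1.0 - d - a)) / _logistic(g)


# state coding: s = v + 2 d + 4 a
def _v(s):
    return s & 1


def _d(s):
    return (s >> 1) & 1


def _a(s):
    return (s >> 2) & 1


def _pair_rows_jet(net: MarkovNet, k: int, x_jet: dict, p_jet: dict, lam_jet: dict, nvars: int):
    """8 rows of pair k's conditional transition operator as jets.

    ``x_jet`` is the presynaptic drive S * sum_j A[j,k] v_j for the current
    joint firing pattern.  Input c is marginalized inside, which correlates
    the v and d transitions as they ride on the same input draw.
    """
    one = J.const(1.0, nvars)
    p_off_on = 1.0 / net.tau_on
    p_off = 1.0 / net.tau_off
    pa1_from0 = J.add(one, J.scale(J.exp(J.scale(x_jet, -1.0)), -1.0))  # 1 - e^-x
    rows = []
    for s in range(8):
        v, d, a = _v(s), _d(s), _a(s)
        row = [J.const(0.0, nvars) for _ in range(8)]
        for c in (0, 1):
            pc = lam_jet if c == 1 else J.add(one, J.scale(lam_jet, -1.0))
            # v transition
            if v == 1:
                pv1 = J.const(1.0 - p_off_on, nvars)
            elif c == 1:
                pv1 = J.const(net.P0 * net.reduction(d, a), nvars)
            else:
                pv1 = J.const(0.0, nvars)
            # d transition
            if d == 1:
                pd1 = J.const(1.0 - p_off, nvars)
            elif c == 1:
                pd1 = p_jet
            else:
                pd1 = J.const(0.0, nvars)
            # a transition
            pa1 = J.const(1.0 - p_off, nvars) if a == 1 else pa1_from0
            for s2 in range(8):
                v2, d2, a2 = _v(s2), _d(s2), _a(s2)
                term = pc
                term = J.mul(term, pv1 if v2 else J.add(one, J.scale(pv1, -1.0)))
                term = J.mul(term, pd1 if d2 else J.add(one, J.scale(pd1, -1.0)))
                term = J.mul(term, pa1 if a2 else J.add(one, J.scale(pa1, -1.0)))
                row[s2] = J.add(row[s2], term)
        rows.append(row)
    return rows


def pair_transition_matrix(net: MarkovNet, k: int, n_active_neighbors_drive: float) -> np.ndarray:
    """The 8x8 row-stochastic operator of pair k given its presynaptic drive.

    ``n_active_neighbors_drive`` is sum_j A[j, k] v_j for the surrounding
    firing pattern; the a-variable turns on with probability
    1 - exp(-S * drive).
    """
    lam = float(net.lambdas[k])
    p_off_on = 1.0 / net.tau_on
    p_off = 1.0 / net.tau_off
    pa1_from0 = 1.0 - np.exp(-net.S * float(n_active_neighbors_drive))
    M = np.zeros((8, 8))
    for s in range(8):
        v, d, a = _v(s), _d(s), _a(s)
        for c, pc in ((0, 1.0 - lam), (1, lam)):
            if pc == 0.0:
                continue
            if v == 1:
                pv1 = 1.0 - p_off_on
            else:
                pv1 = net.P0 * net.reduction(d, a) if c == 1 else 0.0
            if d == 1:
                pd1 = 1.0 - p_off
            else:
                pd1 = net.p if c == 1 else 0.0
            pa1 = (1.0 - p_off) if a == 1 else pa1_from0
            pv = np.array([1.0 - pv1, pv1])
            pd = np.array([1.0 - pd1, pd1])
            pa = np.array([1.0 - pa1, pa1])
            for s2 in range(8):
                M[s, s2] += pc * pv[_v(s2)] * pd[_d(s2)] * pa[_a(s2)]
    return M


def _operator_jets(
    net: MarkovNet,
    edge_vars: list,
    var_p: bool,
    var_lambda_k: int | None,
):
    """Joint evolution operator as a jet in the requested directions.

    ``edge_vars`` lists edges (j, k) whose strengths u = S * A[j, k] are
    formal variables *centered at zero* (all other couplings are also zero:
    the expansion base point is the uncoupled network).  ``var_p`` makes the
    vesicle parameter a variable centered at net.p; ``var_lambda_k`` makes
    one input probability a variable.  Returns (jet matrix, nvars).
    """
    N = net.n_pairs
    if N > MAX_EXACT_PAIRS:
        raise ValueError(
            f"exact operator capped at {MAX_EXACT_PAIRS} pairs (8^N states); "
            "use Monte-Carlo simulation for larger networks"
        )
    nvars = len(edge_vars) + int(var_p) + (1 if var_lambda_k is not None else 0)
    p_idx = len(edge_vars) if var_p else None
    lam_idx = len(edge_vars) + int(var_p) if var_lambda_k is not None else None

    p_jet = J.variable(net.p, p_idx, nvars) if var_p else J.const(net.p, nvars)
    n_states = 8**N
    dim_rows = []
    for s_joint in range(n_states):
        states = [(s_joint >> (3 * k)) & 7 for k in range(N)]
        v_pat = [_v(s) for s in states]
        row_jet = J.const(np.ones(1), nvars)
        for k in range(N - 1, -1, -1):
            # drive onto pair k from currently firing neighbors
            x = J.const(0.0, nvars)
            for e_idx, (j, kk) in enumerate(edge_vars):
                if kk == k and v_pat[j]:
                    x = J.add(x, J.variable(0.0, e_idx, nvars))
            if var_lambda_k == k:
                lam = J.variable(float(net.lambdas[k]), lam_idx, nvars)
            else:
                lam = J.const(float(net.lambdas[k]), nvars)
            rows = _pair_rows_jet(net, k, x, p_jet, lam, nvars)
            row_k = rows[states[k]]
            vec = {key: np.array([row_k[s2].get(key, 0.0) for s2 in range(8)]) for key in _jet_keys(row_k)}
            row_jet = J._combine(row_jet, vec, lambda xx, yy: np.kron(xx, yy))
        dim_rows.append(row_jet)
    keys = set()
    for r in dim_rows:
        keys.update(r.keys())
    M_jet = {}
    for key in keys:
        M_jet[key] = np.vstack(
            [r.get(key, np.zeros(n_states)) for r in dim_rows]
        )
    return M_jet, nvars


def _jet_keys(jet_list):
    keys = set()
    for j in jet_list:
        keys.update(j.keys())
    return keys


def build_full_operator(net: MarkovNet) -> np.ndarray:
    """Exact joint evolution operator over the 8^N state space.

    At S = 0 this is the tensor product of the per-pair operators.  Capped
    at N = 4 (4096 states); larger networks should be simulated instead.
    """
    N = net.n_pairs
    if N > MAX_EXACT_PAIRS:
        raise ValueError(
            f"exact operator capped at {MAX_EXACT_PAIRS} pairs; "
            "analyze larger networks by expansion plus simulation"
        )
    n_states = 8**N
    M = np.empty((n_states, n_states))
    cache: dict = {}
    for s_joint in range(n_states):
        states = [(s_joint >> (3 * k)) & 7 for k in range(N)]
        v_pat = np.array([_v(s) for s in states], dtype=float)
        row = np.ones(1)
        for k in range(N - 1, -1, -1):
            drive = float(net.A[:, k] @ v_pat)
            key = (k, drive)
            if key not in cache:
                cache[key] = pair_transition_matrix(net, k, drive)
            row = np.kron(row, cache[key][states[k]])
        M[s_joint] = row
    return M


def equilibrium(M: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unique stationary distribution of a row-stochastic operator.

    Eigen-solve of M^T with a power-iteration fallback; warns if the
    eigenvalue-1 eigenspace is (numerically) degenerate, which signals a
    reducible chain.
    """
    vals, vecs = np.linalg.eig(M.T)
    close = np.abs(vals - 1.0) < 1e-8
    if close.sum() > 1:
        warnings.warn("multiple unit eigenvalues: chain may be reducible")
    if close.sum() >= 1:
        rho = np.real(vecs[:, np.argmax(close)])
        rho = np.abs(rho)
        rho = rho / rho.sum()
    else:  # pragma: no cover - fallback for pathological conditioning
        rho = np.full(M.shape[0], 1.0 / M.shape[0])
    for _ in range(1000):
        new = rho @ M
        if np.max(np.abs(new - rho)) < tol:
            rho = new
            break
        rho = new
    return rho / rho.sum()


def _fire_mask(N: int, k: int) -> np.ndarray:
    states = np.arange(8**N)
    return ((states >> (3 * k)) & 1).astype(bool)


def rate_and_isi(
    net: MarkovNet,
    k: int,
    max_isi: int = 5000,
    tail_tol: float = 1e-12,
):
    """Steady-state firing rate, ISI distribution and ISI variance of LNI k.

    f_k is the equilibrium probability of the firing state.  The ISI
    distribution is the path sum over state sequences that start and end in
    a firing step of neuron k with none in between, truncated when the
    remaining survival mass drops below ``tail_tol`` (the discarded tail
    mass is returned for bookkeeping).
    """
    M = build_full_operator(net)
    rho = equilibrium(M)
    fire = _fire_mask(net.n_pairs, k)
    f_k = float(rho[fire].sum())
    if f_k == 0:
        raise ValueError(f"LNI {k} never fires: ISI undefined")
    w = rho * fire
    w = w / w.sum()
    probs = []
    total = 0.0
    w = w @ M
    for tau in range(1, max_isi + 1):
        p_tau = float(w[fire].sum())
        probs.append(p_tau)
        total += p_tau
        w = (w * (~fire)) @ M
        if 1.0 - total < tail_tol:
            break
    probs = np.asarray(probs)
    taus = np.arange(1, len(probs) + 1)
    norm = probs.sum()
    mean = float((taus * probs).sum() / norm)
    var = float((taus**2 * probs).sum() / norm - mean**2)
    return f_k, probs, var


def _rate_from_operator(M: np.ndarray, N: int, k: int) -> float:
    rho = equilibrium(M)
    return float(rho[_fire_mask(N, k)].sum())


def sensitivity(net: MarkovNet, k: int, h: float = 1e-3, rtol: float = 1e-2) -> float:
    """d f_k / d lambda_k by central differences with a Richardson check."""
    def f_at(lam_k):
        lam = net.lambdas.copy()
        lam[k] = lam_k
        return _rate_from_operator(
            build_full_operator(replace(net, lambdas=lam)), net.n_pairs, k
        )

    lam0 = float(net.lambdas[k])
    h = min(h, lam0 / 2 if lam0 > 0 else h, (1 - lam0) / 2 if lam0 < 1 else h)
    d1 = (f_at(lam0 + h) - f_at(lam0 - h)) / (2 * h)
    d2 = (f_at(lam0 + h / 2) - f_at(lam0 - h / 2)) / h
    richardson = (4 * d2 - d1) / 3.0
    err = abs(d2 - d1) / 3.0
    if err > rtol * max(abs(richardson), 1e-12):
        raise ValueError(
            f"finite-difference derivative did not converge (err {err:.2e}); "
            "adjust the step size"
        )
    return float(richardson)


def iso_rate_direction(net: MarkovNet, k: int, h: float = 1e-3) -> float:
    """dp/dS along the constant-f_k family, by the implicit function theorem.

    Both partials are negative in the small-coupling regime (either form of
    depression lowers the rate), so the direction is negative: raising
    presynaptic inhibition must be paid for by lowering vesicle depletion.
    """
    f_S = _partial_S(net, k, h)
    f_p = _partial_p(net, k, h)
    if abs(f_p) < 1e-12:
        raise ValueError("degenerate: f_k is insensitive to p at this point")
    return -f_S / f_p


def _partial_S(net: MarkovNet, k: int, h: float) -> float:
    f = lambda S: _rate_from_operator(
        build_full_operator(replace(net, S=S)), net.n_pairs, k
    )
    S0 = net.S
    lo = max(S0 - h, 0.0)
    return (f(S0 + h) - f(lo)) / (S0 + h - lo)


def _partial_p(net: MarkovNet, k: int, h: float) -> float:
    f = lambda p: _rate_from_operator(
        build_full_operator(replace(net, p=p)), net.n_pairs, k
    )
    p0 = net.p
    lo, hi = max(p0 - h, 0.0), min(p0 + h, 1.0)
    return (f(hi) - f(lo)) / (hi - lo)


# --------------------------------------------------------------------------
# subnetwork expansion
# --------------------------------------------------------------------------


def _equilibrium_jets(M_jet: dict, nvars: int) -> dict:
    """Stationary distribution as a jet, solved order by order."""
    zero = tuple([0] * nvars)
    M0 = M_jet[zero]
    n = M0.shape[0]
    rho0 = equilibrium(M0)
    rho = {zero: rho0}
    A_sys = np.vstack([(np.eye(n) - M0).T, np.ones((1, n))])
    keys = sorted(M_jet.keys(), key=lambda kk: (sum(kk), kk))
    for key in keys:
        if key == zero:
            continue
        rhs = np.zeros(n)
        for beta, Mb in M_jet.items():
            if beta == zero or any(b > g for b, g in zip(beta, key)):
                continue
            alpha = tuple(g - b for g, b in zip(key, beta))
            if alpha in rho:
                rhs += rho[alpha] @ Mb
        b_sys = np.concatenate([rhs, [0.0]])
        sol, *_ = np.linalg.lstsq(A_sys, b_sys, rcond=None)
        rho[key] = sol
    return rho


def _scalar_from_vec_jet(vec_jet: dict, weights: np.ndarray) -> dict:
    return {key: float(arr @ weights) for key, arr in vec_jet.items()}


def _isi_var_jets(M_jet: dict, rho_jet: dict, fire: np.ndarray, nvars: int, tail_tol=1e-12, max_isi=5000):
    """Jet of the ISI variance of the neuron selected by ``fire``."""
    zero = tuple([0] * nvars)
    mask = fire.astype(float)
    w = {key: arr * mask for key, arr in rho_jet.items()}
    norm = {key: float(arr.sum()) for key, arr in w.items()}
    w = J._combine(J.inv(norm), w, lambda s, v: s * v)
    w = J.matmul(w, M_jet)
    m0 = J.const(0.0, nvars)
    m1 = J.const(0.0, nvars)
    m2 = J.const(0.0, nvars)
    survived = 1.0
    for tau in range(1, max_isi + 1):
        p_tau = {key: float(arr @ mask) for key, arr in w.items()}
        m0 = J.add(m0, p_tau)
        m1 = J.add(m1, J.scale(p_tau, float(tau)))
        m2 = J.add(m2, J.scale(p_tau, float(tau**2)))
        survived -= J.value(p_tau)
        if survived < tail_tol:
            break
        w = {key: arr * (1.0 - mask) for key, arr in w.items()}
        w = J.matmul(w, M_jet)
    inv0 = J.inv(m0)
    mean = J.mul(m1, inv0)
    var = J.add(J.mul(m2, inv0), J.scale(J.mul(mean, mean), -1.0))
    return var


def _f_var_jets(net: MarkovNet, k: int, edge_vars: list, var_lambda: bool = False):
    """Jets of (f_k, var_ISI_k) in (edges..., p[, lambda_k]) directions."""
    M_jet, nvars = _operator_jets(
        net, edge_vars, var_p=True, var_lambda_k=k if var_lambda else None
    )
    rho_jet = _equilibrium_jets(M_jet, nvars)
    fire = _fire_mask(net.n_pairs, k)
    f_jet = {key: float(arr[fire].sum()) for key, arr in rho_jet.items()}
    var_jet = _isi_var_jets(M_jet, rho_jet, fire, nvars)
    return f_jet, var_jet, nvars


def _motif_of_edge(edge, k):
    j, t = edge
    if t == k:
        return "autapse" if j == k else "in-edge"
    if j == k:
        return "out-edge"
    return "extrinsic"


def _motif_of_pair(e, f, k):
    (j1, t1), (j2, t2) = e, f
    if t1 == k and t2 == k:
        return "fan-in"
    if (t1 == k and t2 == j1) or (t2 == k and t1 == j2):
        return "chain"
    return "other"


@dataclass
class ExpansionTerms:
    """Weak-coupling expansion of f_k and iso-rate var(ISI_k) around S = 0.

    ``first[edge]`` carries the per-edge coefficients (df: unconstrained
    rate derivative; dvar: iso-rate-constrained variance derivative) and the
    edge's strength value u = S * A[j, k]; ``second[(e, f)]`` the analogous
    second-order coefficients, motif-tagged.  ``predict_var(scale)``
    evaluates the truncated series with all edge strengths multiplied by
    ``scale``.
    """

    k: int
    f0: float
    var0: float
    first: dict = field(default_factory=dict)
    second: dict = field(default_factory=dict)

    def predict_f(self, scale: float = 1.0) -> float:
        out = self.f0
        for e, t in self.first.items():
            out += t["df"] * t["u"] * scale
        for (e, f), t in self.second.items():
            factor = 0.5 if e == f else 1.0
            out += factor * t["d2f"] * t["u"][0] * t["u"][1] * scale**2
        return out

    def predict_var(self, scale: float = 1.0) -> float:
        out = self.var0
        for e, t in self.first.items():
            out += t["dvar"] * t["u"] * scale
        for (e, f), t in self.second.items():
            factor = 0.5 if e == f else 1.0
            out += factor * t["d2var"] * t["u"][0] * t["u"][1] * scale**2
        return out

    def var_slope(self, scale: float = 1.0) -> float:
        """d predict_var / d scale: the iso-rate reliability trend."""
        out = 0.0
        for e, t in self.first.items():
            out += t["dvar"] * t["u"]
        for (e, f), t in self.second.items():
            factor = 0.5 if e == f else 1.0
            out += 2.0 * scale * factor * t["d2var"] * t["u"][0] * t["u"][1]
        return out


def subnetwork_expansion(net: MarkovNet, k: int, order: int = 2) -> ExpansionTerms:
    """Motif-resolved expansion of f_k and var(ISI_k) in the edge strengths.

    Coefficients are exact directional derivatives of the evolution-operator
    family at the uncoupled point (S = 0), computed by second-order forward
    Taylor propagation -- no finite differences.  For the variance, the
    vesicle parameter p is co-varied so that f_k stays constant along the
    expansion (the iso-rate constraint): with p_e = -f_e / f_p,

        dvar_e = var_e + var_p p_e,
        d2var_ef = var_ef + var_ep p_f + var_fp p_e + var_pp p_e p_f
                   + var_p p_ef.
    """
    if order > 2:
        raise ValueError("expansion supported up to second order")
    edges = [tuple(e) for e in np.argwhere(net.A > 0)]
    base = ExpansionTerms(k=k, f0=0.0, var0=0.0)

    # zeroth order: uncoupled network
    f_jet0, var_jet0, _ = _f_var_jets(net, k, [])
    base.f0 = J.value(f_jet0)
    base.var0 = J.value(var_jet0)
    if order == 0 or not edges:
        return base

    # first + diagonal-second order, one edge at a time
    partials = {}
    for e in edges:
        f_jet, var_jet, nv = _f_var_jets(net, k, [e])
        fe = J.deriv(f_jet, 0)
        fp = J.deriv(f_jet, 1)
        pe = -fe / fp if abs(fp) > 1e-14 else 0.0
        ve = J.deriv(var_jet, 0)
        vp = J.deriv(var_jet, 1)
        dvar = ve + vp * pe
        u = net.S * float(net.A[e[0], e[1]])
        base.first[e] = {
            "df": fe,
            "dvar": dvar,
            "u": u,
            "motif": _motif_of_edge(e, k),
        }
        partials[e] = {
            "fe": fe,
            "fp": fp,
            "pe": pe,
            "fee": J.deriv2(f_jet, 0, 0),
            "fep": J.deriv2(f_jet, 0, 1),
            "fpp": J.deriv2(f_jet, 1, 1),
            "ve": ve,
            "vp": vp,
            "vee": J.deriv2(var_jet, 0, 0),
            "vep": J.deriv2(var_jet, 0, 1),
            "vpp": J.deriv2(var_jet, 1, 1),
        }
        if order >= 2:
            pp = partials[e]
            # p'' from f(u, p(u)) = const along the single-edge direction
            pee = (
                -(pp["fee"] + 2 * pp["fep"] * pp["pe"] + pp["fpp"] * pp["pe"] ** 2)
                / pp["fp"]
                if abs(pp["fp"]) > 1e-14
                else 0.0
            )
            d2var = (
                pp["vee"]
                + 2 * pp["vep"] * pp["pe"]
                + pp["vpp"] * pp["pe"] ** 2
                + pp["vp"] * pee
            )
            base.second[(e, e)] = {
                "d2f": pp["fee"],
                "d2var": d2var,
                "u": (u, u),
                "motif": _motif_of_pair(e, e, k),
            }

    if order >= 2:
        for e, f in itertools.combinations(edges, 2):
            f_jet, var_jet, nv = _f_var_jets(net, k, [e, f])
            fef = J.deriv2(f_jet, 0, 1)
            vef = J.deriv2(var_jet, 0, 1)
            fep = J.deriv2(f_jet, 0, 2)
            ffp = J.deriv2(f_jet, 1, 2)
            vep = J.deriv2(var_jet, 0, 2)
            vfp = J.deriv2(var_jet, 1, 2)
            pe = partials[e]["pe"]
            pf = partials[f]["pe"]
            fp = partials[e]["fp"]
            fpp = partials[e]["fpp"]
            vp = partials[e]["vp"]
            vpp = partials[e]["vpp"]
            pef = (
                -(fef + fep * pf + ffp * pe + fpp * pe * pf) / fp
                if abs(fp) > 1e-14
                else 0.0
            )
            d2var = vef + vep * pf + vfp * pe + vpp * pe * pf + vp * pef
            base.second[(e, f)] = {
                "d2f": fef,
                "d2var": d2var,
                "u": (
                    net.S * float(net.A[e[0], e[1]]),
                    net.S * float(net.A[f[0], f[1]]),
                ),
                "motif": _motif_of_pair(e, f, k),
            }
    return base


def _iso_rate_var(net: MarkovNet, k: int, S: float, p_bracket=(1e-6, 0.999)):
    """Exact var(ISI_k) at coupling S with p adjusted to hold f_k fixed."""
    f_target = _rate_from_operator(build_full_operator(net), net.n_pairs, k)

    def f_of_p(p):
        return _rate_from_operator(
            build_full_operator(replace(net, S=S, p=p)), net.n_pairs, k
        ) - f_target

    p_star = brentq(f_of_p, *p_bracket, xtol=1e-12)
    _, _, var = rate_and_isi(replace(net, S=S, p=p_star), k)
    return var, p_star


def hypothesis2_check(net: MarkovNet, k: int, h: float = 0.02) -> dict:
    """Evaluate hypotheses 2.0-2.2 for LNI k, by expansion and exactly.

    * H2.0: an iso-rate family exists (both depression routes move f_k).
    * H2.1: var(ISI_k) increases along the family as presynaptic inhibition
      replaces vesicle depletion.
    * H2.2: the sensitivity df_k/dlambda_k increases along the same family.

    Exact evaluations use the full operator (N <= 4) with p re-solved at
    S +/- h; the expansion evaluation uses the motif series slope.
    """
    has_input = bool(np.any(net.A[:, k] > 0))
    out = {"H2.0": False, "H2.1": None, "H2.2": None}
    if not has_input:
        return out
    try:
        direction = iso_rate_direction(net, k, h=min(h, 1e-3))
    except ValueError:
        return out
    out["H2.0"] = True
    out["iso_rate_direction"] = direction

    terms = subnetwork_expansion(net, k, order=2)
    slope_expansion = terms.var_slope(scale=1.0)
    var_hi, _ = _iso_rate_var(net, k, net.S + h)
    var_lo, _ = _iso_rate_var(net, k, max(net.S - h, 0.0))
    slope_exact = (var_hi - var_lo) / (net.S + h - max(net.S - h, 0.0))
    out["H2.1"] = bool(slope_exact > 0)
    out["H2.1_expansion"] = bool(slope_expansion > 0)
    out["var_slope_exact"] = slope_exact
    out["var_slope_expansion"] = slope_expansion

    def sens_at(S):
        _, p_star = _iso_rate_var(net, k, S)
        return sensitivity(replace(net, S=S, p=p_star), k)

    s_hi = sens_at(net.S + h)
    s_lo = sens_at(max(net.S - h, 0.0))
    slope_sens = (s_hi - s_lo) / (net.S + h - max(net.S - h, 0.0))
    out["H2.2"] = bool(slope_sens > 0)
    out["sens_slope_exact"] = slope_sens
    return out


def er_ncrit(
    net_template: MarkovNet,
    sparsity: float,
    confidence: float = 0.75,
) -> dict:
    """Critical network size for hypothesis 2.1 in Erdos-Renyi networks.

    An autapse-bearing LNI obeys H2.1 when the positive in-edge
    contributions to the iso-rate ISI-variance slope outweigh its own
    negative autapse contribution.  Per-motif magnitudes come from the
    subnetwork expansion on canonical 1- and 2-pair networks; in an E-R
    network with sparsity kappa the in-degree is Binomial(N-1, kappa), so
    N_crit is the smallest N for which P(K >= K*) >= confidence, with K*
    the minimum number of in-edges needed.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    lam = float(net_template.lambdas[0])
    # autapse-only single pair
    net1 = replace(
        net_template, lambdas=np.array([lam]), A=np.array([[1.0]])
    )
    t1 = subnetwork_expansion(net1, 0, order=2)
    b_aut = t1.first[(0, 0)]["dvar"] * t1.first[(0, 0)]["u"] + 0.5 * t1.second[
        ((0, 0), (0, 0))
    ]["d2var"] * t1.first[(0, 0)]["u"] ** 2
    # one foreign in-edge on a 2-pair network
    net2 = replace(
        net_template,
        lambdas=np.array([lam, lam]),
        A=np.array([[0.0, 1.0], [0.0, 0.0]]),
    )
    t2 = subnetwork_expansion(net2, 1, order=2)
    e = (0, 1)
    b_in = t2.first[e]["dvar"] * t2.first[e]["u"] + 0.5 * t2.second[(e, e)][
        "d2var"
    ] * t2.first[e]["u"] ** 2

    out = {"b_autapse": float(b_aut), "b_in_edge": float(b_in)}
    if b_in <= 0:
        out.update({"K_star": np.inf, "N_crit": np.inf})
        return out
    K_star = int(np.ceil(-b_aut / b_in + 1e-12)) if b_aut < 0 else 0
    out["K_star"] = K_star
    if K_star == 0:
        out["N_crit"] = 1
        return out
    for N in range(2, 100001):
        if binom.sf(K_star - 1, N - 1, sparsity) >= confidence:
            out["N_crit"] = N
            return out
    out["N_crit"] = np.inf  # effectively unreachable at this sparsity
    return out
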