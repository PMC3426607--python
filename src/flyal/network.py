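"""Construction of the glomerular antennal-lobe architecture.

The default network has 5 glomerular channels, each with 60 ORNs, 6 PNs,
6 LNEs and 6 LNIs.  ORNs and PNs project only within their own glomerulus;
LNEs and LNIs project laterally across glomeruli.  Every ordered pair of
neurons is connected independently with a probability that depends only on
the (pre-class, post-class) pair and on whether the pair shares a glomerulus,
so the wiring is Erdos-Renyi within each class block.

Connection strengths likewise depend only on the class pair, with separate
arrays for the fast-excitatory, GABA-A and GABA-B channels: only ORN, PN and
LNE rows carry excitatory strengths and only the LNI row carries GABA
strengths.  LNI->ORN edges are special: they deposit GABA drive on the ORN
*terminal* (suppressing release efficacy via ``s_pre``) and never produce a
somatic conductance on the ORN.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "ArchitectureConfig",
    "NetworkSpec",
    "build_network",
    "empirical_connection_fraction",
    "iso_rate_family",
]

CLASSES = ("ORN", "PN", "LNE", "LNI")
_IDX = {c: i for i, c in enumerate(CLASSES)}


def _default_p_intra() -> np.ndarray:
    # rows: presynaptic class, cols: postsynaptic class (ORN, PN, LNE, LNI)
    p = np.zeros((4, 4))
    p[_IDX["ORN"], _IDX["PN"]] = 0.80  # high ORN->PN convergence
    p[_IDX["ORN"], _IDX["LNE"]] = 0.50
    p[_IDX["ORN"], _IDX["LNI"]] = 0.50
    p[_IDX["PN"], _IDX["LNE"]] = 0.30
    p[_IDX["PN"], _IDX["LNI"]] = 0.30
    p[_IDX["LNE"], _IDX["PN"]] = 0.20  # sparse: direct LNE->PN rarely observed
    p[_IDX["LNE"], _IDX["LNE"]] = 0.30
    p[_IDX["LNE"], _IDX["LNI"]] = 0.30
    p[_IDX["LNI"], _IDX["ORN"]] = 0.50  # presynaptic route onto ORN terminals
    p[_IDX["LNI"], _IDX["PN"]] = 0.30
    p[_IDX["LNI"], _IDX["LNE"]] = 0.30
    p[_IDX["LNI"], _IDX["LNI"]] = 0.30
    return p


def _default_p_inter() -> np.ndarray:
    # ORN and PN rows are zero: they never leave their glomerulus
    p = np.zeros((4, 4))
    p[_IDX["LNE"], _IDX["PN"]] = 0.50  # dense lateral excitation between glomeruli
    p[_IDX["LNE"], _IDX["LNE"]] = 0.30
    p[_IDX["LNE"], _IDX["LNI"]] = 0.30
    p[_IDX["LNI"], _IDX["ORN"]] = 0.30
    p[_IDX["LNI"], _IDX["PN"]] = 0.30
    p[_IDX["LNI"], _IDX["LNE"]] = 0.30
    p[_IDX["LNI"], _IDX["LNI"]] = 0.30
    return p


def _default_s_exc() -> np.ndarray:
    # calibrated so that odor-driven PNs are mean-driven (saturated, regular)
    # while single background EPSPs stay subthreshold
    s = np.zeros((4, 4))
    s[_IDX["ORN"], _IDX["PN"]] = 0.05
    s[_IDX["ORN"], _IDX["LNE"]] = 0.05
    s[_IDX["ORN"], _IDX["LNI"]] = 0.05
    s[_IDX["PN"], _IDX["LNE"]] = 0.02
    s[_IDX["PN"], _IDX["LNI"]] = 0.02
    s[_IDX["LNE"], _IDX["PN"]] = 0.01
    s[_IDX["LNE"], _IDX["LNE"]] = 0.01
    s[_IDX["LNE"], _IDX["LNI"]] = 0.01
    return s


def _default_s_gabaa() -> np.ndarray:
    # IPSC onto PNs split ~50% fast / ~50% slow in current contribution
    # (slow weight scaled by the ratio of filter areas); LNI->PN kept weak
    s = np.zeros((4, 4))
    s[_IDX["LNI"], _IDX["PN"]] = 0.005
    s[_IDX["LNI"], _IDX["LNE"]] = 0.03
    s[_IDX["LNI"], _IDX["LNI"]] = 0.03
    s[_IDX["LNI"], _IDX["ORN"]] = 0.05  # terminal drive, acts through s_pre
    return s


def _default_s_gabab() -> np.ndarray:
    s = np.zeros((4, 4))
    s[_IDX["LNI"], _IDX["PN"]] = 0.0006
    s[_IDX["LNI"], _IDX["ORN"]] = 0.006
    return s


@dataclass(frozen=True)
class ArchitectureConfig:
    """Full parameterization of the antennal-lobe wiring.

    Probability and strength arrays are 4x4 (pre-class x post-class) in the
    order (ORN, PN, LNE, LNI).  ``p_ves`` and ``s_pre`` are the vesicle
    depletion and presynaptic inhibition strengths applied at every ORN
    terminal; the wiring ``seed`` makes the sampled connectivity matrix
    deterministic.
    """

    n_glomeruli: int = 5
    n_orn: int = 60
    n_pn: int = 6
    n_lne: int = 6
    n_lni: int = 6
    p_intra: np.ndarray = field(default_factory=_default_p_intra)
    p_inter: np.ndarray = field(default_factory=_default_p_inter)
    s_exc: np.ndarray = field(default_factory=_default_s_exc)
    s_gabaa: np.ndarray = field(default_factory=_default_s_gabaa)
    s_gabab: np.ndarray = field(default_factory=_default_s_gabab)
    p_ves: float = 0.2
    s_pre: float = 0.5
    allow_self: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_intra", "p_inter"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (4, 4):
                raise ValueError(f"{name} must be 4x4")
            bad = np.argwhere((arr < 0) | (arr > 1))
            if len(bad):
                i, j = bad[0]
                raise ValueError(
                    f"{name}[{CLASSES[i]}->{CLASSES[j]}] = {arr[i, j]} "
                    "outside [0, 1]"
                )
            object.__setattr__(self, name, arr)
        for name in ("s_exc", "s_gabaa", "s_gabab"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not 0.0 <= self.p_ves <= 1.0:
            raise ValueError("p_ves must be in [0, 1]")
        if self.s_pre < 0:
            raise ValueError("s_pre must be non-negative")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_orn, self.n_pn, self.n_lne, self.n_lni)

    @property
    def n_neurons(self) -> int:
        return self.n_glomeruli * sum(self.counts)


@dataclass(frozen=True)
class NetworkSpec:
    """A sampled network: neuron table, wiring and per-edge channel weights.

    ``neurons`` has columns (id, cls, glomerulus); ``C`` is the binary
    connectivity matrix indexed (pre, post); ``W_E``/``W_A``/``W_B`` carry the
    per-edge strengths for the three channels.  ORN columns of ``W_E`` are
    zero and LNI->ORN GABA weights target the ORN terminal, not the soma.
    """

    config: ArchitectureConfig
    neurons: pd.DataFrame
    C: np.ndarray
    W_E: np.ndarray
    W_A: np.ndarray
    W_B: np.ndarray

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    def ids_of(self, cls: str, glomerulus: int | None = None) -> np.ndarray:
        sel = self.neurons["cls"] == cls
        if glomerulus is not None:
            sel &= self.neurons["glomerulus"] == glomerulus
        return self.neurons.index.values[sel.values]

    def edge_list(self) -> pd.DataFrame:
        """Exportable (pre_id, post_id, channel, weight) table."""
        rows = []
        for channel, W in (("E", self.W_E), ("A", self.W_A), ("B", self.W_B)):
            pre, post = np.nonzero(W)
            rows.append(
                pd.DataFrame(
                    {
                        "pre_id": pre,
                        "post_id": post,
                        "channel": channel,
                        "weight": W[pre, post],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def _neuron_table(config: ArchitectureConfig) -> pd.DataFrame:
    cls_col, glom_col = [], []
    for g in range(config.n_glomeruli):
        for cls, n in zip(CLASSES, config.counts):
            cls_col.extend([cls] * n)
            glom_col.extend([g] * n)
    return pd.DataFrame({"cls": cls_col, "glomerulus": glom_col})


def build_network(config: ArchitectureConfig) -> NetworkSpec:
    """Sample a network from the architecture's class-pair probabilities.

    Each ordered pair (i, j) is connected independently with the probability
    of its (class_i, class_j, intra/inter) cell; the draw is deterministic
    given ``config.seed``.  Routes the architecture forbids (ORN or PN output
    leaving its glomerulus, synaptic input onto ORN somata through the
    excitatory channel) carry probability or weight zero regardless of the
    arrays.
    """
    neurons = _neuron_table(config)
    n = len(neurons)
    cls_idx = neurons["cls"].map(_IDX).values
    glom = neurons["glomerulus"].values

    same_glom = glom[:, None] == glom[None, :]
    prob = np.where(
        same_glom,
        config.p_intra[cls_idx[:, None], cls_idx[None, :]],
        config.p_inter[cls_idx[:, None], cls_idx[None, :]],
    )
    # hard topology constraints: ORN/PN outputs never leave their glomerulus
    local_only = np.isin(cls_idx, [_IDX["ORN"], _IDX["PN"]])
    prob[local_only[:, None] & ~same_glom] = 0.0
    if not config.allow_self:
        np.fill_diagonal(prob, 0.0)

    rng = np.random.default_rng(config.seed)
    C = (rng.random((n, n)) < prob).astype(np.uint8)

    W_E = C * config.s_exc[cls_idx[:, None], cls_idx[None, :]]
    W_A = C * config.s_gabaa[cls_idx[:, None], cls_idx[None, :]]
    W_B = C * config.s_gabab[cls_idx[:, None], cls_idx[None, :]]
    # ORN somata receive no excitatory conductance (only terminal GABA drive)
    is_orn = cls_idx == _IDX["ORN"]
    W_E[:, is_orn] = 0.0
    return NetworkSpec(config=config, neurons=neurons, C=C, W_E=W_E, W_A=W_A, W_B=W_B)


def empirical_connection_fraction(
    specs,
    pre_class: str,
    post_class: str,
    scope: str = "intra",
) -> float:
    """Pooled connected-pair fraction over eligible ordered pairs.

    ``scope`` selects intra- or inter-glomerular pairs.  Pools numerator and
    denominator over all supplied networks; raises on an empty eligible set.
    """
    if scope not in ("intra", "inter"):
        raise ValueError("scope must be 'intra' or 'inter'")
    if isinstance(specs, NetworkSpec):
        specs = [specs]
    hits = total = 0
    for spec in specs:
        pre = spec.ids_of(pre_class)
        post = spec.ids_of(post_class)
        glom = spec.neurons["glomerulus"].values
        same = glom[pre][:, None] == glom[post][None, :]
        eligible = same if scope == "intra" else ~same
        if pre_class == post_class:
            eligible = eligible & (pre[:, None] != post[None, :])
        hits += int(spec.C[np.ix_(pre, post)][eligible].sum())
        total += int(eligible.sum())
    if total == 0:
        raise ValueError(
            f"no eligible {pre_class}->{post_class} ({scope}) pairs in the networks given"
        )
    return hits / total


def iso_rate_family(
    config: ArchitectureConfig,
    p_ves_grid,
    s_pre_grid,
) -> list[list[ArchitectureConfig]]:
    """Cartesian grid of configs differing only in (p_ves, s_pre).

    All configs share the base wiring seed, so the sampled connectivity
    matrix is identical across the grid; only the depression parameters move.
    The (max s_pre, min p_ves) corner is the type-A regime (presynaptic
    inhibition dominated) and the (min s_pre, max p_ves) corner the type-B
    regime (vesicle depletion dominated).
    """
    p_ves_grid = list(p_ves_grid)
    s_pre_grid = list(s_pre_grid)
    if not p_ves_grid or not s_pre_grid:
        raise ValueError("grids must be non-empty")
    return [
        [replace(config, p_ves=float(p), s_pre=float(s)) for s in s_pre_grid]
        for p in p_ves_grid
    ]
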