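"""Spike-train statistics: PSTHs, ISI moments, reliability, rank correlations
and iso-rate contour extraction over the depression-parameter grid.

Conventions used throughout: a coefficient of variation is reported as NaN
(never zero) wherever its mean is zero; Spearman correlations use average
ranks for ties; constant response vectors are excluded from correlation
histograms with the exclusion count reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats
from skimage import measure

from .datasets import SpikeDataset

__all__ = [
    "PSTH",
    "ISISummary",
    "psth",
    "isi_stats",
    "significant_acf_peaks",
    "rate_table",
    "rank_correlation_histograms",
    "iso_rate_contours",
    "sample_bilinear",
    "profile_along_contour",
]


@dataclass
class PSTH:
    """Trial-resolved peri-stimulus time histogram for a neuron selection."""

    bin_edges: np.ndarray
    counts: np.ndarray  # (n_trials, n_bins), pooled over the selection
    mean: np.ndarray
    std: np.ndarray
    cv: np.ndarray  # NaN where mean == 0

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def peak_time(self) -> float:
        return float(self.bin_centers[int(np.argmax(self.mean))])


@dataclass
class ISISummary:
    """Inter-spike-interval sample moments and binned autocorrelation."""

    isis: np.ndarray
    mean: float
    variance: float
    cv: float
    acf_lags: np.ndarray
    acf: np.ndarray
    peak_lags: np.ndarray


def psth(
    dataset: SpikeDataset,
    neuron_ids,
    bin_width: float,
    odor=None,
    window: tuple[float, float] | None = None,
) -> PSTH:
    """Per-bin spike counts of a neuron selection, mean/std/CV across trials."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    neuron_ids = np.atleast_1d(np.asarray(neuron_ids))
    df = dataset.spikes[dataset.spikes["neuron_id"].isin(neuron_ids)]
    if odor is not None:
        df = df[df["odor"] == odor]
    if df.empty and not len(dataset.trials):
        raise ValueError("empty selection")
    lo, hi = window if window is not None else (0.0, dataset.horizon)
    edges = np.arange(lo, hi + bin_width, bin_width)
    trials = dataset.trials
    counts = np.zeros((len(trials), len(edges) - 1))
    for k, trial in enumerate(trials):
        t = df[df["trial"] == trial]["spike_time_ms"].values
        counts[k], _ = np.histogram(t, bins=edges)
    mean = counts.mean(axis=0)
    std = counts.std(axis=0, ddof=1) if len(trials) > 1 else np.zeros_like(mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, std / mean, np.nan)
    return PSTH(bin_edges=edges, counts=counts, mean=mean, std=std, cv=cv)


def isi_stats(
    spike_train: np.ndarray,
    acf_bin: float = 2.0,
    acf_max_lag: float = 200.0,
    n_surrogates: int = 100,
    seed: int = 0,
) -> ISISummary:
    """ISI moments plus the normalized autocorrelation of the binned train.

    Requires at least 3 spikes (2 intervals) for an unbiased variance.
    Autocorrelation is normalized to unit zero lag; peaks are the lags whose
    autocorrelation exceeds 3 standard deviations above the ISI-shuffled
    surrogate ensemble.
    """
    t = np.sort(np.asarray(spike_train, dtype=float))
    if len(t) < 3:
        raise ValueError("need at least 3 spikes for ISI moments")
    isis = np.diff(t)
    if np.any(isis <= 0):
        isis = isis[isis > 0]
    mean = float(isis.mean())
    var = float(isis.var(ddof=1))
    cv = float(np.sqrt(var) / mean)
    lags, acf = _binned_acf(t, acf_bin, acf_max_lag)
    peak_lags = significant_acf_peaks(
        t, acf_bin, acf_max_lag, n_surrogates=n_surrogates, seed=seed
    )
    return ISISummary(
        isis=isis,
        mean=mean,
        variance=var,
        cv=cv,
        acf_lags=lags,
        acf=acf,
        peak_lags=peak_lags,
    )


def _binned_acf(t: np.ndarray, bin_width: float, max_lag: float):
    span = t[-1] - t[0]
    edges = np.arange(t[0], t[-1] + bin_width, bin_width)
    x = np.histogram(t, bins=edges)[0].astype(float)
    x = x - x.mean()
    n_lags = min(int(max_lag / bin_width), len(x) - 1)
    full = np.correlate(x, x, mode="full")
    mid = len(x) - 1
    acf = full[mid : mid + n_lags + 1]
    if acf[0] > 0:
        acf = acf / acf[0]
    lags = np.arange(n_lags + 1) * bin_width
    return lags, acf


def significant_acf_peaks(
    spike_train: np.ndarray,
    bin_width: float = 2.0,
    max_lag: float = 200.0,
    n_surrogates: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Lags of autocorrelation peaks exceeding the shuffled-ISI envelope.

    Surrogates permute the inter-spike intervals, destroying serial order but
    preserving the ISI marginal; a peak is significant when the observed
    autocorrelation exceeds surrogate mean + 3 surrogate std at that lag and
    is a local maximum.
    """
    t = np.sort(np.asarray(spike_train, dtype=float))
    lags, acf = _binned_acf(t, bin_width, max_lag)
    rng = np.random.default_rng(seed)
    isis = np.diff(t)
    sur = np.empty((n_surrogates, len(acf)))
    for s in range(n_surrogates):
        tt = t[0] + np.concatenate([[0.0], np.cumsum(rng.permutation(isis))])
        _, sur[s] = _binned_acf(tt, bin_width, max_lag)
    thresh = sur.mean(axis=0) + 3.0 * sur.std(axis=0, ddof=1)
    peaks, _ = signal.find_peaks(acf[1:])
    peaks = peaks + 1
    sig = peaks[acf[peaks] > thresh[peaks]]
    return lags[sig]


def rate_table(
    dataset: SpikeDataset,
    window: tuple[float, float],
    classes=("ORN", "PN"),
) -> pd.DataFrame:
    """Trial-averaged firing rate (Hz) per (neuron, odor) in the window."""
    lo, hi = window
    dur_s = (hi - lo) / 1000.0
    df = dataset.spikes
    df = df[(df["spike_time_ms"] >= lo) & (df["spike_time_ms"] < hi)]
    df = df[df["cls"].isin(classes)]
    n_trials = len(dataset.trials)
    counts = df.groupby(["neuron_id", "cls", "glomerulus", "odor"]).size()
    rates = (counts / (n_trials * dur_s)).rename("rate_hz").reset_index()
    # re-insert zero rows for silent (neuron, odor) combinations
    neurons = df[["neuron_id", "cls", "glomerulus"]].drop_duplicates()
    full = (
        neurons.assign(key=1)
        .merge(pd.DataFrame({"odor": dataset.odors, "key": 1}), on="key")
        .drop(columns="key")
    )
    out = full.merge(rates, on=["neuron_id", "cls", "glomerulus", "odor"], how="left")
    out["rate_hz"] = out["rate_hz"].fillna(0.0)
    return out


def rank_correlation_histograms(rates: pd.DataFrame) -> dict:
    """Spearman rank-correlation histograms over odor-response vectors.

    For each glomerulus, correlates the across-odor rate vectors of every
    same-glomerulus PN pair (PN-PN) and every PN-ORN pair, then pools over
    glomeruli.  Constant vectors make the correlation undefined and are
    excluded; the exclusion count is reported.
    """
    odors = sorted(rates["odor"].unique())
    if len(odors) < 3:
        raise ValueError("need at least 3 odors for rank correlations")
    pn_pn, pn_orn, excluded = [], [], 0
    for g, grp in rates.groupby("glomerulus"):
        vecs = {}
        for nid, sub in grp.groupby("neuron_id"):
            v = sub.set_index("odor")["rate_hz"].reindex(odors).values
            cls = sub["cls"].iloc[0]
            if np.ptp(v) == 0:
                excluded += 1
                continue
            vecs[nid] = (cls, v)
        pns = [n for n, (c, _) in vecs.items() if c == "PN"]
        orns = [n for n, (c, _) in vecs.items() if c == "ORN"]
        for a_idx, a in enumerate(pns):
            for b in pns[a_idx + 1 :]:
                pn_pn.append(stats.spearmanr(vecs[a][1], vecs[b][1]).statistic)
            for b in orns:
                pn_orn.append(stats.spearmanr(vecs[a][1], vecs[b][1]).statistic)
    pn_pn = np.asarray(pn_pn)
    pn_orn = np.asarray(pn_orn)
    return {
        "pn_pn": pn_pn,
        "pn_orn": pn_orn,
        "pn_pn_mean": float(np.mean(pn_pn)) if len(pn_pn) else np.nan,
        "pn_orn_mean": float(np.mean(pn_orn)) if len(pn_orn) else np.nan,
        "n_excluded_constant": excluded,
    }


def iso_rate_contours(
    mean_map: np.ndarray,
    x_grid: np.ndarray,
    y_grid: np.ndarray,
    levels,
) -> dict:
    """Iso-level polylines of a map sampled on an (x, y) parameter grid.

    Marching squares with linear interpolation along cell edges (exact for a
    bilinear surface on the edges).  Returns ``{level: [polyline, ...]}``
    with each polyline an (n, 2) array of (x, y) points parameterized in
    order of increasing arc length.  A constant map is degenerate and raises;
    levels outside the data range return empty lists.
    """
    mean_map = np.asarray(mean_map, dtype=float)
    if mean_map.ndim != 2 or min(mean_map.shape) < 2:
        raise ValueError("need at least a 2x2 map")
    if np.ptp(mean_map) == 0:
        raise ValueError("constant map: iso-rate contours are degenerate")
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    out = {}
    for level in np.atleast_1d(levels):
        polys = []
        for seg in measure.find_contours(mean_map, float(level)):
            # seg is in (row, col) index coordinates; map to grid values
            x = np.interp(seg[:, 0], np.arange(len(x_grid)), x_grid)
            y = np.interp(seg[:, 1], np.arange(len(y_grid)), y_grid)
            polys.append(np.column_stack([x, y]))
        out[float(level)] = polys
    return out


def contour_arc_length(poly: np.ndarray) -> np.ndarray:
    """Cumulative arc length along a polyline, starting at 0."""
    steps = np.sqrt(np.sum(np.diff(poly, axis=0) ** 2, axis=1))
    return np.concatenate([[0.0], np.cumsum(steps)])


def sample_bilinear(
    zmap: np.ndarray,
    x_grid: np.ndarray,
    y_grid: np.ndarray,
    points: np.ndarray,
) -> np.ndarray:
    """Bilinear interpolation of a gridded map at (x, y) points."""
    from scipy.interpolate import RegularGridInterpolator

    f = RegularGridInterpolator(
        (np.asarray(x_grid, float), np.asarray(y_grid, float)),
        np.asarray(zmap, float),
        method="linear",
        bounds_error=False,
        fill_value=None,
    )
    return f(np.asarray(points, dtype=float))


def profile_along_contour(
    contour: np.ndarray,
    maps: dict,
    x_grid: np.ndarray,
    y_grid: np.ndarray,
) -> pd.DataFrame:
    """Bilinearly sample named maps along a contour polyline.

    Returns a tidy frame with the arc-length coordinate and one column per
    map (e.g. trial-to-trial spike-count std, discriminability), so
    reliability and sensitivity can be read off as functions of position
    between the type-A and type-B ends of an iso-rate contour.
    """
    s = contour_arc_length(contour)
    data = {"arc_length": s, "x": contour[:, 0], "y": contour[:, 1]}
    for name, zmap in maps.items():
        data[name] = sample_bilinear(zmap, x_grid, y_grid, contour)
    return pd.DataFrame(data)
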