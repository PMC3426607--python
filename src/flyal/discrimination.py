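"""Odor discrimination from PN population activity.

The decoder is a per-PN weighted vote: for each PN i and odor o an empirical
distribution rho_i^o of the PN's spike count is estimated from training
trials (discrete histogram with Laplace pseudo-count).  To classify a test
vector in a pairwise task (a vs b), each PN votes for the odor under which
its observed count is more probable, and votes are tallied with weight

    w_i = log((h_i + s) / (e_i + s)),

the log information ratio of the PN's hit rate h_i and error rate e_i.  This
weighting makes k votes at error rate e carry the same weight as one vote at
error rate e^k (up to smoothing).  k-way tasks run all pairwise tasks and
take the majority, with ties counted as incorrect.

The module also provides the Gaussian signal-to-noise analysis of a general
two-stimulus discrimination: with mean separation dmu, per-sample variance
sigma_bar^2, M averaged samples and observation noise sigma_eta, the best
linear classifier errs with probability

    eps = 1/2 erfc( |dmu| / (2 sqrt(2) sqrt(sigma_bar^2 / M + sigma_eta^2)) ).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erfc

from .datasets import SpikeDataset

__all__ = [
    "OdorClassifier",
    "DiscrimResult",
    "fit_model",
    "vote_weight",
    "classify_pairwise",
    "classify_kway",
    "count_features",
    "correlation_features",
    "loto_accuracy",
    "erf_discrimination_error",
    "optimal_depression_mix",
]

TIE = "__tie__"


def vote_weight(h: float, e: float, smoothing: float = 1e-3) -> float:
    """Log information-ratio weight of a voter with hit rate h, error rate e.

    Zero when h == e; the smoothing pseudo-count keeps the weight finite for
    perfect voters.  The defining scaling property: k voters at error rate e
    match one voter at error rate e**k, since k log(h/e) = log(h**k/e**k).
    """
    if not (0 <= h <= 1 and 0 <= e <= 1):
        raise ValueError("hit and error rates must lie in [0, 1]")
    return float(np.log((h + smoothing) / (e + smoothing)))


class OdorClassifier:
    """Per-PN weighted-vote odor classifier (sklearn-style estimator).

    Parameters
    ----------
    smoothing : float
        Laplace pseudo-count added to every histogram bin.
    weight_smoothing : float
        Pseudo-count in the log information-ratio vote weights.
    n_bins : int or None
        If None (default), features are treated as small non-negative
        integers (spike counts) and binned at unit width over the training
        range; otherwise continuous features are digitized into ``n_bins``
        uniform bins fit on the training data.

    Attributes (after fit)
    ----------------------
    classes_ : array of odor labels
    distributions_ : dict mapping odor -> (n_features, n_bins) row-normalized
        probability tables
    weights_ : dict mapping (odor_a, odor_b) -> per-feature vote weights
    """

    def __init__(self, smoothing: float = 1.0, weight_smoothing: float = 1e-3, n_bins=None):
        self.smoothing = smoothing
        self.weight_smoothing = weight_smoothing
        self.n_bins = n_bins

    # minimal get/set_params so the estimator composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {
            "smoothing": self.smoothing,
            "weight_smoothing": self.weight_smoothing,
            "n_bins": self.n_bins,
        }

    def set_params(self, **params) -> "OdorClassifier":
        for key, val in params.items():
            if key not in self.get_params():
                raise ValueError(f"invalid parameter {key!r}")
            setattr(self, key, val)
        return self

    def _digitize(self, X: np.ndarray) -> np.ndarray:
        if self.n_bins is None:
            return np.clip(np.round(X).astype(int), 0, self._n_levels - 1)
        scaled = (X - self._lo) / np.where(self._span > 0, self._span, 1.0)
        return np.clip((scaled * self.n_bins).astype(int), 0, self.n_bins - 1)

    def fit(self, X, y) -> "OdorClassifier":
        """Estimate per-(feature, odor) count distributions.

        X is (n_trials, n_features) of spike counts (or digitizable
        features); y gives the odor label per trial.  Requires >= 2 odors
        and >= 2 trials per odor.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2-d (trials x features)")
        if np.any(~np.isfinite(X)):
            raise ValueError("features must be finite")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 odors to fit a discriminator")
        if counts.min() < 2:
            raise ValueError("need at least 2 trials per odor")
        self.classes_ = classes
        self.n_features_in_ = X.shape[1]
        if self.n_bins is None:
            self._n_levels = int(np.max(X)) + 2  # one spare level for unseen counts
            self._lo = self._span = None
            n_bins = self._n_levels
        else:
            self._lo = X.min(axis=0)
            self._span = np.ptp(X, axis=0)
            n_bins = self.n_bins
        B = self._digitize(X)
        self.distributions_ = {}
        for odor in classes:
            rows = B[y == odor]
            hist = np.zeros((self.n_features_in_, n_bins))
            for i in range(self.n_features_in_):
                hist[i] = np.bincount(rows[:, i], minlength=n_bins)
            hist += self.smoothing
            self.distributions_[odor] = hist / hist.sum(axis=1, keepdims=True)
        self.weights_ = {}
        for a, b in itertools.combinations(classes, 2):
            pa, pb = self.distributions_[a], self.distributions_[b]
            vote_a = pa > pb
            vote_b = pb > pa
            h = 0.5 * ((pa * vote_a).sum(axis=1) + (pb * vote_b).sum(axis=1))
            e = 0.5 * ((pa * vote_b).sum(axis=1) + (pb * vote_a).sum(axis=1))
            w = np.log((h + self.weight_smoothing) / (e + self.weight_smoothing))
            self.weights_[(a, b)] = w
        return self

    def _check_fitted(self):
        if not hasattr(self, "distributions_"):
            raise RuntimeError("classifier is not fitted")

    def decide_pair(self, x, a, b):
        """Weighted-vote decision between odors a and b for one test vector."""
        self._check_fitted()
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n_features_in_,):
            raise ValueError(
                f"expected {self.n_features_in_} features, got {x.shape}"
            )
        key = (a, b) if (a, b) in self.weights_ else (b, a)
        if key not in self.weights_:
            raise ValueError(f"model was not fitted on odors {a!r}, {b!r}")
        bins = self._digitize(x[None, :])[0]
        pa = self.distributions_[a][np.arange(self.n_features_in_), bins]
        pb = self.distributions_[b][np.arange(self.n_features_in_), bins]
        w = self.weights_[key]
        score = float(np.sum(np.where(pa > pb, w, np.where(pb > pa, -w, 0.0))))
        if score > 0:
            return a
        if score < 0:
            return b
        return TIE

    def decide_kway(self, x, odor_set=None):
        """Round-robin pairwise winners, majority vote; ties are incorrect."""
        self._check_fitted()
        odor_set = list(self.classes_ if odor_set is None else odor_set)
        if len(odor_set) < 2:
            raise ValueError("arity must be >= 2")
        wins = {o: 0 for o in odor_set}
        for a, b in itertools.combinations(odor_set, 2):
            winner = self.decide_pair(x, a, b)
            if winner != TIE:
                wins[winner] += 1
        best = max(wins.values())
        leaders = [o for o, w in wins.items() if w == best]
        return leaders[0] if len(leaders) == 1 else TIE

    def predict(self, X) -> np.ndarray:
        """k-way prediction over all fitted odors; ties labelled '__tie__'."""
        X = np.asarray(X, dtype=float)
        return np.asarray([self.decide_kway(x) for x in X], dtype=object)

    def score(self, X, y) -> float:
        pred = self.predict(X)
        return float(np.mean(pred == np.asarray(y, dtype=object)))


def fit_model(X, y, smoothing: float = 1.0, n_bins=None) -> OdorClassifier:
    """Fit the weighted-vote classifier on training count vectors."""
    return OdorClassifier(smoothing=smoothing, n_bins=n_bins).fit(X, y)


def classify_pairwise(x, model: OdorClassifier, odor_pair):
    a, b = odor_pair
    return model.decide_pair(x, a, b)


def classify_kway(x, model: OdorClassifier, odor_set):
    return model.decide_kway(x, odor_set)


@dataclass
class DiscrimResult:
    """Correct-classification rates over a set of discrimination tasks."""

    accuracies: np.ndarray
    arity: int
    window: tuple
    features: str = "rates"
    percentile: float = 25.0

    @property
    def chance(self) -> float:
        return 1.0 / self.arity

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def low_percentile(self) -> float:
        return float(np.percentile(self.accuracies, self.percentile))


def count_features(
    dataset: SpikeDataset,
    neuron_ids,
    window: tuple[float, float],
):
    """Per-(odor, trial) spike-count vectors over the given PNs.

    Returns (X, y, trials): X is (n_observations, n_neurons) integer counts,
    y the odor label and trials the trial index of each row.
    """
    table = dataset.counts(neuron_ids, window=window)
    wide = table.pivot_table(
        index=["odor", "trial"], columns="neuron_id", values="count"
    )[list(neuron_ids)]
    y = wide.index.get_level_values("odor").values
    trials = wide.index.get_level_values("trial").values
    return wide.values.astype(float), y, trials


def correlation_features(
    dataset: SpikeDataset,
    trial,
    odor,
    neuron_ids,
    corr_window: float = 50.0,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Windowed pairwise spike-count correlations within one trial.

    Counts are binned at ``corr_window`` ms inside the observation window;
    the feature vector holds the Pearson correlation of the binned counts
    for every PN pair (0 where either train is constant across bins).
    """
    if corr_window <= 0:
        raise ValueError("correlation window must be positive")
    lo, hi = window if window is not None else (0.0, dataset.horizon)
    edges = np.arange(lo, hi + corr_window, corr_window)
    binned = []
    for nid in neuron_ids:
        t = dataset.spike_train(trial, odor, nid)
        binned.append(np.histogram(t, bins=edges)[0].astype(float))
    feats = []
    for i, j in itertools.combinations(range(len(neuron_ids)), 2):
        a, b = binned[i], binned[j]
        if a.std() == 0 or b.std() == 0:
            feats.append(0.0)
        else:
            feats.append(float(np.corrcoef(a, b)[0, 1]))
    return np.asarray(feats)


def rate_and_correlation_features(
    dataset: SpikeDataset,
    neuron_ids,
    window: tuple[float, float],
    corr_window: float = 50.0,
):
    """Count vectors augmented with pairwise-correlation feature components."""
    X, y, trials = count_features(dataset, neuron_ids, window)
    corr = np.vstack(
        [
            correlation_features(
                dataset, t, o, neuron_ids, corr_window=corr_window, window=window
            )
            for o, t in zip(y, trials)
        ]
    )
    return np.hstack([X, corr]), y, trials


def loto_accuracy(
    X,
    y,
    trials,
    odor_subset=None,
    smoothing: float = 1.0,
    n_bins=None,
) -> float:
    """Leave-one-trial-out accuracy of the weighted-vote classifier.

    Classifies each held-out observation among ``odor_subset`` (default all
    odors).  The entire trial layer of the held-out observation (its trial
    index across every odor) is removed from training, which keeps the
    estimate symmetric across classes and free of the anti-bias that
    removing only the test observation introduces.  Ties count as incorrect.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    trials = np.asarray(trials)
    odor_subset = list(np.unique(y) if odor_subset is None else odor_subset)
    mask = np.isin(y, odor_subset)
    correct = total = 0
    for k in np.nonzero(mask)[0]:
        train = mask & (trials != trials[k])
        model = OdorClassifier(smoothing=smoothing, n_bins=n_bins).fit(
            X[train], y[train]
        )
        pred = model.decide_kway(X[k], odor_subset)
        correct += int(pred == y[k])
        total += 1
    return correct / total


def erf_discrimination_error(
    dmu: float,
    sigma_bar: float,
    M: int = 1,
    sigma_eta: float = 0.0,
) -> float:
    """Best-linear-classifier error for two Gaussian response distributions.

    The two stimuli produce samples with means ``dmu`` apart; each decision
    averages ``M`` samples of per-sample variance ``sigma_bar**2`` and adds
    observation noise ``sigma_eta**2``.  Monotone decreasing in ``dmu`` and
    ``M``; equals 1/2 at zero separation.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if sigma_bar < 0 or sigma_eta < 0:
        raise ValueError("standard deviations must be non-negative")
    var = sigma_bar**2 / M + sigma_eta**2
    if var == 0:
        if dmu == 0:
            raise ValueError("zero variance and zero separation: error undefined")
        return 0.0
    return float(0.5 * erfc(abs(dmu) / (2.0 * np.sqrt(2.0) * np.sqrt(var))))


def optimal_depression_mix(
    family: pd.DataFrame,
    M: int,
    sigma_eta: float = 0.0,
):
    """Depression mix tau_f* minimizing discrimination error along a family.

    ``family`` is the iso-rate table from
    :func:`flyal.cartoon.iso_rate_tau_family` with columns ``tau_f``,
    ``dmu`` (rate separation) and ``sigma_bar`` (per-sample response std).
    Returns (tau_f_star, errors) where errors is the per-row error curve.
    With ``M = inf`` and no observation noise the trial noise vanishes and
    the most sensitive (largest ``dmu``, type-A) end wins.
    """
    dmu = family["dmu"].values
    sig = family["sigma_bar"].values
    if np.isinf(M):
        if sigma_eta == 0:
            errors = np.where(dmu > 0, 0.0, 0.5)
            star = int(np.argmax(dmu))
            return float(family["tau_f"].values[star]), errors
        var = np.full_like(dmu, sigma_eta**2)
    else:
        var = sig**2 / M + sigma_eta**2
    with np.errstate(divide="ignore"):
        errors = 0.5 * erfc(np.abs(dmu) / (2.0 * np.sqrt(2.0) * np.sqrt(var)))
    star = int(np.argmin(errors))
    return float(family["tau_f"].values[star]), errors
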