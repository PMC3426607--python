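"""Weighted-vote odor classifier and discriminability theory."""

import numpy as np
import pytest

from flyal.datasets import SpikeDataset
from flyal.discrimination import (
    TIE,
    OdorClassifier,
    classify_kway,
    classify_pairwise,
    correlation_features,
    count_features,
    erf_discrimination_error,
    fit_model,
    loto_accuracy,
    optimal_depression_mix,
    vote_weight,
)
from flyal.fixtures import FixtureSpec, generate


class TestVoteWeight:
    def test_zero_when_hit_equals_error(self):
        assert vote_weight(0.4, 0.4) == 0.0

    def test_log_two_when_hit_is_double_error(self):
        assert vote_weight(0.4, 0.2, smoothing=1e-12) == pytest.approx(np.log(2))

    def test_k_votes_match_single_vote_at_power_error_rate(self):
        # the defining scaling: k voters at small error rate e combine to the
        # weight of one voter at error rate e^k
        e, k = 0.01, 3
        combined = k * vote_weight(1 - e, e, smoothing=1e-15)
        single = vote_weight(1 - e**k, e**k, smoothing=1e-15)
        assert combined == pytest.approx(single, rel=5e-3)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            vote_weight(1.2, 0.0)


class TestClassifier:
    def test_disjoint_supports_classify_perfectly(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.poisson(4, (15, 5)), rng.poisson(40, (15, 5))])
        y = np.array(["a"] * 15 + ["b"] * 15)
        model = fit_model(X, y)
        assert model.score(X, y) == 1.0

    def test_identical_distributions_stay_near_chance(self):
        rng = np.random.default_rng(1)
        accs = []
        for rep in range(3):
            X = rng.poisson(10, (200, 4))
            y = np.array(["a", "b"] * 100)
            trials = np.arange(200) // 2
            accs.append(loto_accuracy(X, y, trials))
        se = np.sqrt(0.25 / 200)
        assert np.mean(accs) > 0.5 - 3 * se

    def test_all_voters_agree(self):
        X = np.vstack([np.full((3, 4), 2.0), np.full((3, 4), 9.0)])
        y = np.array(["a"] * 3 + ["b"] * 3)
        model = fit_model(X, y)
        assert classify_pairwise(np.full(4, 2.0), model, ("a", "b")) == "a"

    def test_symmetric_sample_ties_are_incorrect(self):
        X = np.array([[0.0], [0.0], [8.0], [8.0]])
        y = np.array(["a", "a", "b", "b"])
        model = fit_model(X, y)
        assert model.decide_pair(np.array([4.0]), "a", "b") == TIE

    def test_single_informative_voter_dominates_noise(self):
        rng = np.random.default_rng(2)
        noise = rng.poisson(10, (40, 6))
        informative = np.concatenate([np.full(20, 2.0), np.full(20, 25.0)])
        X = np.column_stack([informative, noise])
        y = np.array(["a"] * 20 + ["b"] * 20)
        model = fit_model(X, y)
        x = np.concatenate([[25.0], rng.poisson(10, 6)]).astype(float)
        assert classify_pairwise(x, model, ("a", "b")) == "b"

    def test_kway_reduces_to_pairwise_for_two_odors(self):
        rng = np.random.default_rng(3)
        X = np.vstack([rng.poisson(4, (10, 3)), rng.poisson(30, (10, 3))])
        y = np.array(["a"] * 10 + ["b"] * 10)
        model = fit_model(X, y)
        for x in X[::5]:
            assert classify_kway(x, model, ["a", "b"]) == model.decide_pair(
                x, "a", "b"
            )

    def test_three_way_dominant_odor_wins(self):
        X = np.vstack(
            [np.full((4, 2), v) for v in (2.0, 10.0, 25.0)]
        )
        y = np.repeat(["a", "b", "c"], 4)
        model = fit_model(X, y)
        assert classify_kway(np.array([25.0, 25.0]), model, ["a", "b", "c"]) == "c"

    def test_fit_validation(self):
        with pytest.raises(ValueError, match="2 odors"):
            fit_model(np.ones((4, 2)), np.array(["a"] * 4))
        with pytest.raises(ValueError, match="2 trials"):
            fit_model(np.ones((3, 2)), np.array(["a", "a", "b"]))

    def test_sklearn_style_params_roundtrip(self):
        model = OdorClassifier(smoothing=2.0)
        assert model.get_params()["smoothing"] == 2.0
        model.set_params(n_bins=8)
        assert model.n_bins == 8
        with pytest.raises(ValueError):
            model.set_params(bogus=1)


class TestCorrelationFeatures:
    def test_duplicated_trains_fully_correlated(self):
        ds = generate(
            FixtureSpec(
                "correlated-pair", {"rate_hz": 40.0, "corr": 1.0, "horizon": 4000.0}
            )
        )
        feats = correlation_features(ds, 0, "odor0", [0, 1], corr_window=100.0)
        assert feats[0] == pytest.approx(1.0)

    def test_thinned_common_mother_recovers_target_correlation(self):
        target = 0.5
        vals = []
        for seed in range(8):
            ds = generate(
                FixtureSpec(
                    "correlated-pair",
                    {"rate_hz": 60.0, "corr": target, "horizon": 20000.0},
                    seed=seed,
                )
            )
            vals.append(
                correlation_features(ds, 0, "odor0", [0, 1], corr_window=50.0)[0]
            )
        assert np.mean(vals) == pytest.approx(target, abs=0.08)

    def test_independent_trains_near_zero(self):
        vals = []
        for seed in range(10):
            ds = generate(
                FixtureSpec(
                    "poisson",
                    {"rate_hz": 50.0, "n_neurons": 2, "horizon": 10000.0},
                    seed=seed,
                )
            )
            vals.append(
                correlation_features(ds, 0, "odor0", [0, 1], corr_window=50.0)[0]
            )
        assert abs(np.mean(vals)) < 0.05

    def test_antiphase_regular_trains_anticorrelate(self):
        import pandas as pd

        period = 100.0
        t1 = np.arange(10.0, 4000.0, period)
        t2 = t1 + period / 2
        rows = []
        for nid, tt in ((0, t1), (1, t2)):
            for t in tt:
                rows.append((0, "o", nid, "PN", 0, t))
        spikes = pd.DataFrame(
            rows,
            columns=["trial", "odor", "neuron_id", "cls", "glomerulus", "spike_time_ms"],
        )
        ds = SpikeDataset(spikes=spikes, horizon=4000.0)
        feats = correlation_features(ds, 0, "o", [0, 1], corr_window=25.0)
        assert feats[0] < -0.2


class TestErfError:
    def test_zero_separation_is_chance(self):
        assert erf_discrimination_error(0.0, 1.0, 1, 0.0) == pytest.approx(0.5)

    def test_noiseless_separation_is_perfect(self):
        assert erf_discrimination_error(3.0, 0.0, 1, 0.0) == 0.0

    def test_monotone_in_samples_and_separation(self):
        errs_M = [erf_discrimination_error(1.0, 1.0, M, 0.1) for M in (1, 4, 16)]
        assert errs_M[0] > errs_M[1] > errs_M[2]
        errs_d = [erf_discrimination_error(d, 1.0, 2, 0.1) for d in (0.5, 1.0, 2.0)]
        assert errs_d[0] > errs_d[1] > errs_d[2]

    def test_degenerate_input_flagged(self):
        with pytest.raises(ValueError):
            erf_discrimination_error(0.0, 0.0, 1, 0.0)

    @pytest.mark.parametrize(
        "dmu,sigma,M,eta", [(1.0, 1.0, 1, 0.0), (0.5, 1.0, 4, 0.2), (2.0, 1.5, 2, 0.5)]
    )
    def test_matches_monte_carlo_optimal_classifier(self, dmu, sigma, M, eta):
        rng = np.random.default_rng(17)
        n = 10**5
        s = np.sqrt(sigma**2 / M + eta**2)
        xa = rng.normal(0.0, s, n)
        xb = rng.normal(dmu, s, n)
        emp = 0.5 * np.mean(xa > dmu / 2) + 0.5 * np.mean(xb <= dmu / 2)
        se = np.sqrt(emp * (1 - emp) / n)
        assert erf_discrimination_error(dmu, sigma, M, eta) == pytest.approx(
            emp, abs=3 * se
        )


class TestOptimalDepressionMix:
    @staticmethod
    def _family():
        from flyal.cartoon import TwoNeuronParams, iso_rate_tau_family

        base = TwoNeuronParams(i_a=0.02, i_b=0.015, tau_f=0.0, d=0.0)
        return iso_rate_tau_family(base, 0.012, np.linspace(0.0, 25.0, 26))

    def test_unlimited_samples_favor_type_a_extreme(self):
        fam = self._family()
        tau_star, _ = optimal_depression_mix(fam, M=np.inf, sigma_eta=0.0)
        assert tau_star == fam["tau_f"].max()

    def test_single_sample_favors_interior_or_type_b(self):
        fam = self._family()
        tau_star, _ = optimal_depression_mix(fam, M=1, sigma_eta=0.0)
        assert tau_star < fam["tau_f"].max()

    def test_optimum_nondecreasing_in_samples(self):
        fam = self._family()
        taus = [optimal_depression_mix(fam, M=m, sigma_eta=0.05)[0] for m in (1, 8, 64)]
        assert taus[0] <= taus[1] <= taus[2]


class TestCountFeatures:
    def test_count_vectors_match_dataset_counts(self):
        ds = generate(
            FixtureSpec(
                "odor-separable-panel",
                {"n_odors": 2, "n_pns": 3, "n_trials": 4},
                seed=0,
            )
        )
        X, y, trials = count_features(ds, [0, 1, 2], (0.0, ds.horizon))
        assert X.shape == (8, 3)
        assert set(y) == {"odor0", "odor1"}
        total = ds.spikes.groupby(["odor", "trial"]).size().sum()
        assert X.sum() == total
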