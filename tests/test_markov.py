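"""Discrete-state ORN-LNI network: operators, equilibrium, expansion."""

import numpy as np
import pytest

from flyal.markov import (
    MarkovNet,
    build_full_operator,
    equilibrium,
    er_ncrit,
    iso_rate_direction,
    pair_transition_matrix,
    rate_and_isi,
    sensitivity,
    subnetwork_expansion,
    _iso_rate_var,
)


def single_pair(lam=0.3, autapse=0.0, **kw):
    return MarkovNet(lambdas=np.array([lam]), A=np.array([[autapse]]), **kw)


class TestPairTransitions:
    def test_rows_stochastic_over_random_draws(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            net = single_pair(
                lam=rng.uniform(0, 1),
                autapse=rng.uniform(0, 2),
                p=rng.uniform(0, 1),
                S=rng.uniform(0, 2),
                P0=rng.uniform(0.1, 1),
            )
            M = pair_transition_matrix(net, 0, rng.uniform(0, 3))
            assert np.allclose(M.sum(axis=1), 1.0, atol=1e-12)
            assert M.min() >= 0

    def test_no_vesicle_strength_keeps_d_at_zero(self):
        net = single_pair(p=0.0)
        M = pair_transition_matrix(net, 0, 1.0)
        # from any state with d = 0, probability of d' = 1 is zero
        for s in (0, 1, 4, 5):  # d-bit clear
            assert M[s, [2, 3, 6, 7]].sum() == 0.0

    def test_no_drive_keeps_a_dynamics_isolated(self):
        net = single_pair(S=0.0)
        M0 = pair_transition_matrix(net, 0, 0.0)
        M5 = pair_transition_matrix(net, 0, 5.0)
        assert np.allclose(M0, M5)  # S = 0: neighbors are invisible
        for s in range(4):  # a-bit clear
            assert M0[s, 4:].sum() == 0.0


class TestFullOperator:
    def test_single_pair_reduces_to_pair_matrix(self):
        net = single_pair(autapse=0.0, S=0.5)
        assert np.allclose(build_full_operator(net), pair_transition_matrix(net, 0, 0.0))

    def test_uncoupled_operator_factorizes_as_tensor_product(self):
        net = MarkovNet(
            lambdas=np.array([0.5, 0.4]), A=np.array([[0, 1.0], [1.0, 0]]), S=0.0
        )
        full = build_full_operator(net)
        m0 = pair_transition_matrix(single_pair(0.5), 0, 0.0)
        m1 = pair_transition_matrix(single_pair(0.4), 0, 0.0)
        assert np.abs(full - np.kron(m1, m0)).max() < 1e-12

    def test_size_cap_suggests_simulation(self):
        net = MarkovNet(lambdas=np.full(5, 0.5), A=np.zeros((5, 5)))
        with pytest.raises(ValueError, match="simulation"):
            build_full_operator(net)

    def test_equilibrium_matches_long_chain_simulation(self):
        net = single_pair(lam=0.5, autapse=1.0, S=0.5, p=0.3)
        M = build_full_operator(net)
        rho = equilibrium(M)
        assert np.abs(rho @ M - rho).max() < 1e-10
        rng = np.random.default_rng(1)
        cum = np.cumsum(M, axis=1)
        s, T = 0, 500_000
        counts = np.zeros(8)
        draws = rng.random(T)
        for t in range(T):
            s = int(np.searchsorted(cum[s], draws[t]))
            counts[s] += 1
        emp = counts / T
        se = np.sqrt(np.maximum(rho, 1e-12) / T)
        assert np.all(np.abs(emp - rho) < 4 * se + 5e-4)

    def test_doubly_stochastic_matrix_has_uniform_equilibrium(self):
        M = np.full((4, 4), 0.25)
        assert np.allclose(equilibrium(M), 0.25)


class TestRateAndISI:
    def test_isi_distribution_normalizes(self):
        net = single_pair(lam=0.4, S=0.0)
        f, probs, var = rate_and_isi(net, 0)
        assert probs.sum() == pytest.approx(1.0, abs=1e-10)
        assert f > 0 and var > 0

    def test_uncoupled_pair_isi_matches_chain_simulation(self):
        net = single_pair(lam=0.4, S=0.0, p=0.3)
        f, probs, var = rate_and_isi(net, 0)
        M = build_full_operator(net)
        cum = np.cumsum(M, axis=1)
        rng = np.random.default_rng(2)
        s, T = 0, 400_000
        fire_times = []
        draws = rng.random(T)
        for t in range(T):
            s = int(np.searchsorted(cum[s], draws[t]))
            if s & 1:
                fire_times.append(t)
        isis = np.diff(fire_times)
        emp_f = len(fire_times) / T
        assert emp_f == pytest.approx(f, rel=0.02)
        assert isis.mean() == pytest.approx(1.0 / f, rel=0.02)
        assert isis.var() == pytest.approx(var, rel=0.05)

    def test_engineered_deterministic_cycle_single_atom(self):
        # lam=1, P0=1, tau_on=1 and no depression: fire, refract 1 step, fire
        net = single_pair(lam=1.0, p=0.0, S=0.0, P0=1.0, tau_on=1.0)
        f, probs, var = rate_and_isi(net, 0)
        assert var == pytest.approx(0.0, abs=1e-12)
        assert probs[1] == pytest.approx(1.0)  # every ISI equals 2 steps


class TestDerivatives:
    def test_sensitivity_positive_and_matches_analytic_slope(self):
        net = single_pair(lam=0.3, S=0.0, p=0.3)
        s = sensitivity(net, 0)
        assert s > 0
        # cross-check against a coarse secant over a wider interval
        from dataclasses import replace

        def f_at(lam):
            from flyal.markov import _rate_from_operator

            return _rate_from_operator(
                build_full_operator(replace(net, lambdas=np.array([lam]))), 1, 0
            )

        coarse = (f_at(0.32) - f_at(0.28)) / 0.04
        assert s == pytest.approx(coarse, rel=1e-3)

    def test_sensitivity_saturates_at_high_input_rates(self):
        # with long firing persistence, f_k -> tau_on/(tau_on + 1/(lam P0))
        # and the marginal effect of extra input collapses
        hi = sensitivity(single_pair(lam=0.9, S=0.0, p=0.0, P0=1.0, tau_on=10.0), 0)
        lo = sensitivity(single_pair(lam=0.1, S=0.0, p=0.0, P0=1.0, tau_on=10.0), 0)
        assert hi < 0.2 * lo

    def test_iso_rate_direction_negative_with_both_partials(self):
        net = MarkovNet(
            lambdas=np.array([0.3, 0.3]),
            A=np.array([[0, 1.0], [0, 0]]),
            S=0.3,
            p=0.3,
        )
        direction = iso_rate_direction(net, 1)
        assert direction < 0  # trading vesicle depletion for presyn inhibition

    def test_iso_rate_direction_matches_grid_contour(self):
        from flyal.analysis import iso_rate_contours
        from dataclasses import replace
        from flyal.markov import _rate_from_operator

        net = MarkovNet(
            lambdas=np.array([0.3, 0.3]),
            A=np.array([[0, 1.0], [0, 0]]),
            S=0.3,
            p=0.3,
        )
        p_grid = np.linspace(0.2, 0.4, 9)
        S_grid = np.linspace(0.2, 0.4, 9)
        fmap = np.array(
            [
                [
                    _rate_from_operator(
                        build_full_operator(replace(net, p=p, S=S)), 2, 1
                    )
                    for S in S_grid
                ]
                for p in p_grid
            ]
        )
        f0 = _rate_from_operator(build_full_operator(net), 2, 1)
        cont = iso_rate_contours(fmap, p_grid, S_grid, [f0])[f0][0]
        # slope dp/dS of the contour near the operating point
        k = np.argmin(np.abs(cont[:, 1] - 0.3))
        lo, hi = max(k - 2, 0), min(k + 3, len(cont))
        slope = np.polyfit(cont[lo:hi, 1], cont[lo:hi, 0], 1)[0]
        assert iso_rate_direction(net, 1) == pytest.approx(slope, rel=0.1)


class TestSubnetworkExpansion:
    def test_uncoupled_network_keeps_only_zeroth_term(self):
        net = single_pair(lam=0.3, autapse=0.0, S=0.3)
        terms = subnetwork_expansion(net, 0, order=2)
        _, _, var0 = rate_and_isi(net, 0)
        assert terms.first == {} and terms.second == {}
        assert terms.var0 == pytest.approx(var0, rel=1e-8)

    def test_expansion_error_scales_as_third_order(self):
        net = MarkovNet(
            lambdas=np.array([0.3, 0.3]),
            A=np.array([[0, 1.0], [0, 0]]),
            S=1.0,
            p=0.3,
        )
        terms = subnetwork_expansion(net, 1, order=2)
        scales = np.array([0.2, 0.1, 0.05, 0.025])
        errs = []
        for s in scales:
            exact, _ = _iso_rate_var(
                MarkovNet(
                    lambdas=net.lambdas, A=net.A, S=0.0, p=net.p
                ),
                1,
                s,
            )
            errs.append(abs(exact - terms.predict_var(scale=s)))
        slopes = np.diff(np.log(errs)) / np.diff(np.log(scales))
        assert slopes.mean() >= 2.7

    def test_autapse_lowers_and_in_edge_raises_isi_variance(self):
        aut = subnetwork_expansion(
            single_pair(lam=0.3, autapse=1.0, S=0.3, p=0.3), 0, order=1
        )
        ine = subnetwork_expansion(
            MarkovNet(
                lambdas=np.array([0.3, 0.3]),
                A=np.array([[0, 1.0], [0, 0]]),
                S=0.3,
                p=0.3,
            ),
            1,
            order=1,
        )
        assert aut.first[(0, 0)]["motif"] == "autapse"
        assert aut.first[(0, 0)]["dvar"] < 0
        assert ine.first[(0, 1)]["motif"] == "in-edge"
        assert ine.first[(0, 1)]["dvar"] > 0

    def test_two_edge_terms_dwarfed_by_one_edge_terms_at_small_coupling(self):
        net = MarkovNet(
            lambdas=np.array([0.3, 0.3, 0.3]),
            A=np.array([[0, 0, 1.0], [0, 0, 1.0], [0, 0, 0]]),
            S=0.05,
            p=0.3,
        )
        terms = subnetwork_expansion(net, 2, order=2)
        first_mag = sum(abs(t["dvar"] * t["u"]) for t in terms.first.values())
        second_mag = sum(
            (0.5 if e == f else 1.0) * abs(t["d2var"] * t["u"][0] * t["u"][1])
            for (e, f), t in terms.second.items()
        )
        assert second_mag < first_mag

    def test_order_cap(self):
        with pytest.raises(ValueError):
            subnetwork_expansion(single_pair(), 0, order=3)


class TestErNcrit:
    def test_no_in_edges_means_unreachable(self):
        template = single_pair(lam=0.3, S=0.3, p=0.3)
        out = er_ncrit(template, sparsity=1e-6)
        assert out["N_crit"] > 1e4 or np.isinf(out["N_crit"])

    def test_ncrit_nonincreasing_in_sparsity(self):
        template = single_pair(lam=0.3, S=0.1, p=0.3)
        ns = [er_ncrit(template, k)["N_crit"] for k in (0.25, 0.5, 0.9)]
        assert ns[0] >= ns[1] >= ns[2]

    def test_motif_magnitudes_reported_with_signs(self):
        template = single_pair(lam=0.3, S=0.1, p=0.3)
        out = er_ncrit(template, 0.5)
        assert out["b_autapse"] < 0 < out["b_in_edge"]
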