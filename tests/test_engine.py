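"""Full-network trial orchestration, benchmark protocols, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from flyal.analysis import psth, rank_correlation_histograms, rate_table
from flyal.datasets import SpikeDataset
from flyal.engine import (
    attenuation_time,
    epsc_attenuation_protocol,
    run_panel,
    run_trial,
    shielded_suppression_protocol,
    trial_seed,
)
from flyal.network import ArchitectureConfig, build_network
from flyal.odors import OdorSpec, background_odor


class TestRunTrial:
    def test_zero_input_network_is_silent(self, desk_network):
        from flyal.engine import SimParams

        quiet = background_odor(2, background_rate=0.0)
        res = run_trial(
            desk_network, quiet, 300.0, seed=0, sim=SimParams(init_jitter=0.0)
        )
        assert len(res.spikes) == 0

    def test_identical_seed_is_bit_identical(self, desk_network):
        odor = OdorSpec(rates=np.array([2000.0, 0.0]), t_on=100.0, t_off=400.0)
        a = run_trial(desk_network, odor, 400.0, seed=5)
        b = run_trial(desk_network, odor, 400.0, seed=5)
        assert np.array_equal(
            a.spikes["spike_time_ms"].values, b.spikes["spike_time_ms"].values
        )
        assert np.array_equal(a.spikes["neuron_id"].values, b.spikes["neuron_id"].values)

    def test_different_seed_differs(self, desk_network):
        odor = OdorSpec(rates=np.array([2000.0, 0.0]), t_on=100.0, t_off=400.0)
        a = run_trial(desk_network, odor, 400.0, seed=5)
        c = run_trial(desk_network, odor, 400.0, seed=6)
        assert len(a.spikes) != len(c.spikes) or not np.array_equal(
            a.spikes["spike_time_ms"].values, c.spikes["spike_time_ms"].values
        )

    def test_channel_mismatch_rejected(self, desk_network):
        with pytest.raises(ValueError, match="channels"):
            run_trial(desk_network, background_odor(5), 100.0, seed=0)

    def test_background_rates_low_but_nonzero(
        self, background_dataset, driven_dataset, desk_network
    ):
        bg = background_dataset.spikes
        dur_s = 2.8
        orn_bg = ((bg["cls"] == "ORN") & (bg["spike_time_ms"] > 200)).sum() / 120 / dur_s
        pn_bg = ((bg["cls"] == "PN") & (bg["spike_time_ms"] > 200)).sum() / 12 / dur_s
        assert 0 < orn_bg < 20
        assert 0 < pn_bg < 25
        dr = driven_dataset.spikes
        sel = (
            (dr["cls"] == "PN")
            & (dr["glomerulus"] == 0)
            & dr["spike_time_ms"].between(500, 900)
        )
        pn_driven = sel.sum() / 6 / 0.4 / len(driven_dataset.trials)
        assert pn_bg < 0.2 * pn_driven
        orn_sel = (
            (dr["cls"] == "ORN")
            & (dr["glomerulus"] == 0)
            & dr["spike_time_ms"].between(900, 1500)
        )
        orn_driven = orn_sel.sum() / 60 / 0.6 / len(driven_dataset.trials)
        assert orn_bg < 0.2 * orn_driven


class TestRunPanel:
    def test_counts_and_seed_structure(self, desk_network):
        odors = [
            OdorSpec(rates=np.array([1000.0, 0.0]), t_on=50.0, t_off=250.0, name="pa"),
            OdorSpec(rates=np.array([0.0, 1000.0]), t_on=50.0, t_off=250.0, name="pb"),
        ]
        ds = run_panel(desk_network, odors, n_trials=2, horizon=300.0, base_seed=31)
        assert set(ds.odors) == {"pa", "pb"}
        assert ds.trials == [0, 1]
        seeds = {trial_seed(31, o.name, t) for o in odors for t in range(2)}
        assert len(seeds) == 4  # all distinct

    def test_seed_keyed_by_odor_name_not_position(self, desk_network):
        odors = [
            OdorSpec(rates=np.array([1000.0, 0.0]), t_on=50.0, t_off=250.0, name="pa"),
            OdorSpec(rates=np.array([0.0, 1000.0]), t_on=50.0, t_off=250.0, name="pb"),
        ]
        ds1 = run_panel(desk_network, odors, n_trials=1, horizon=300.0, base_seed=31)
        ds2 = run_panel(desk_network, odors[::-1], n_trials=1, horizon=300.0, base_seed=31)
        for name in ("pa", "pb"):
            a = ds1.spikes[ds1.spikes["odor"] == name]["spike_time_ms"].values
            b = ds2.spikes[ds2.spikes["odor"] == name]["spike_time_ms"].values
            assert np.array_equal(np.sort(a), np.sort(b))

    def test_streams_to_disk(self, desk_network, tmp_path):
        odor = OdorSpec(rates=np.array([1000.0, 0.0]), t_on=50.0, t_off=250.0)
        path = tmp_path / "spikes.tsv"
        ds = run_panel(
            desk_network, [odor], n_trials=1, horizon=300.0, base_seed=1, out_path=path
        )
        on_disk = SpikeDataset.load(path)
        assert len(on_disk.spikes) == len(ds.spikes)
        assert on_disk.horizon == 300.0


class TestStimulusBenchmarks:
    def test_pn_peaks_before_orn_and_is_more_reliable(self, driven_dataset, desk_network):
        pn_ids = desk_network.ids_of("PN", 0)
        orn_ids = desk_network.ids_of("ORN", 0)
        pn_peaks, pn_cvs = [], []
        for pid in pn_ids[:4]:
            p = psth(driven_dataset, [pid], 50.0, window=(300.0, 1800.0))
            stim = (p.bin_centers >= 600) & (p.bin_centers < 1500)
            pn_peaks.append(p.peak_time())
            pn_cvs.append(np.nanmean(p.cv[stim]))
        orn_peaks, orn_cvs = [], []
        for oid in orn_ids[:8]:
            p = psth(driven_dataset, [oid], 50.0, window=(300.0, 1800.0))
            stim = (p.bin_centers >= 600) & (p.bin_centers < 1500)
            orn_peaks.append(p.peak_time())
            orn_cvs.append(np.nanmean(p.cv[stim]))
        assert np.mean(pn_peaks) < np.mean(orn_peaks)
        assert np.mean(pn_cvs) < np.mean(orn_cvs)

    def test_pn_orn_rate_relation_saturates(self, mixed_panel_dataset):
        rt = rate_table(mixed_panel_dataset, window=(500.0, 1200.0))
        orn = rt[rt.cls == "ORN"].groupby(["glomerulus", "odor"]).rate_hz.mean()
        pn = rt[rt.cls == "PN"].groupby(["glomerulus", "odor"]).rate_hz.mean()
        sc = pd.concat([orn.rename("orn"), pn.rename("pn")], axis=1).sort_values("orn")
        x, y = sc["orn"].values, sc["pn"].values
        n = len(x) // 3
        gain_lo = np.polyfit(x[: n + 1], y[: n + 1], 1)[0]
        gain_hi = np.polyfit(x[-n - 1 :], y[-n - 1 :], 1)[0]
        assert gain_hi < 0.25 * gain_lo

    def test_no_spontaneous_network_oscillation(self, background_dataset):
        spikes = background_dataset.spikes
        pn_t = spikes[spikes["cls"] == "PN"]["spike_time_ms"].values
        counts, _ = np.histogram(pn_t, bins=np.arange(200.0, 3000.0, 5.0))
        x = counts - counts.mean()
        spec = np.abs(np.fft.rfft(x)) ** 2
        spec = spec[1:]  # drop DC
        # no single frequency should dominate the summed PN activity
        assert spec.max() < 10.0 * np.median(spec) * np.log(len(spec))

    def test_pns_respond_more_broadly_than_their_orn_class(self, three_glom_network):
        # lateral connectivity broadens PN tuning: the PNs of an undriven
        # glomerulus respond to an odor driving the other glomeruli, while
        # their own ORNs stay at background
        odor = OdorSpec(
            rates=np.array([3500.0, 2500.0, 0.0]), t_on=300.0, t_off=1000.0, name="lat"
        )
        res = run_trial(three_glom_network, odor, 1000.0, seed=11)
        bg = run_trial(three_glom_network, background_odor(3), 1000.0, seed=11)
        pn2 = three_glom_network.ids_of("PN", 2)
        orn2 = three_glom_network.ids_of("ORN", 2)

        def rate(r, ids):
            sp = r.spikes
            hits = sp[sp["neuron_id"].isin(ids) & sp["spike_time_ms"].between(300, 1000)]
            return len(hits) / len(ids) / 0.7

        assert rate(res, pn2) > 1.2 * rate(bg, pn2)
        assert rate(res, orn2) == pytest.approx(rate(bg, orn2), abs=2.0)

    def test_same_glomerulus_pns_share_odor_rank_structure(self, three_glom_network):
        levels = [
            (3500, 1200, 0),
            (3500, 0, 1200),
            (1200, 3500, 0),
            (0, 3500, 1200),
            (1200, 0, 3500),
            (0, 1200, 3500),
        ]
        panel = [
            OdorSpec(
                rates=np.array(lv, dtype=float),
                t_on=300.0,
                t_off=1000.0,
                name=f"rc{k}",
            )
            for k, lv in enumerate(levels)
        ]
        ds = run_panel(three_glom_network, panel, n_trials=3, horizon=1000.0, base_seed=41)
        rt = rate_table(ds, window=(300.0, 1000.0))
        out = rank_correlation_histograms(rt)
        # PNs of one glomerulus respond to largely the same odors
        assert out["pn_pn_mean"] > 0.5
        assert len(out["pn_pn"]) > 0 and len(out["pn_orn"]) > 0


class TestEPSCAttenuation:
    def test_no_depression_flat_envelope(self, desk_config):
        from dataclasses import replace

        net = build_network(replace(desk_config, p_ves=0.0, s_pre=0.0))
        out = epsc_attenuation_protocol(net, [20.0])
        assert np.allclose(out[20.0]["envelope"], 1.0)

    def test_higher_frequency_attenuates_faster(self, desk_network):
        out = epsc_attenuation_protocol(desk_network, [10.0, 20.0, 40.0])
        times = [attenuation_time(out[f]["envelope"], out[f]["t"]) for f in (10.0, 20.0, 40.0)]
        assert times[0] > times[1] > times[2]

    def test_steady_state_matches_averaging_fixed_point(self, desk_network):
        p = desk_network.config.p_ves
        tau = 300.0
        out = epsc_attenuation_protocol(desk_network, [20.0, 40.0])
        for f in (20.0, 40.0):
            predicted = p * (f / 1000.0) * tau / (1.0 + p * (f / 1000.0) * tau)
            assert out[f]["D_ss"] == pytest.approx(predicted, rel=0.05)

    def test_invalid_frequency(self, desk_network):
        with pytest.raises(ValueError):
            epsc_attenuation_protocol(desk_network, [-5.0])


class TestShieldedSuppression:
    @pytest.fixture(scope="class")
    def suppression_tables(self, three_glom_network):
        from dataclasses import replace

        panel = [
            OdorSpec(
                rates=np.array([float(a), float(b), 0.0]),
                t_on=300.0,
                t_off=900.0,
                name=f"sh{k}",
            )
            for k, (a, b) in enumerate([(1000, 0), (3000, 800), (6000, 3000)])
        ]
        tables = {}
        for s_pre in (0.0, 2.0, 4.0):
            cfg = replace(three_glom_network.config, s_pre=s_pre)
            net = build_network(cfg)
            tables[s_pre] = shielded_suppression_protocol(
                net, panel, shielded_glomerulus=2, horizon=900.0, base_seed=3
            )
        return tables

    def test_no_presynaptic_route_no_suppression(self, suppression_tables):
        assert np.allclose(suppression_tables[0.0]["suppression"], 0.0, atol=1e-9)

    def test_suppression_tracks_total_orn_activity(self, suppression_tables):
        df = suppression_tables[2.0]
        rho = spearmanr(df["total_orn_spikes"], df["suppression"]).statistic
        assert rho > 0

    def test_doubling_strength_never_reduces_suppression(self, suppression_tables):
        lo = suppression_tables[2.0]["suppression"].values
        hi = suppression_tables[4.0]["suppression"].values
        assert np.all(hi >= lo - 1e-9)

    def test_driving_the_shielded_glomerulus_is_an_error(self, three_glom_network):
        bad = OdorSpec(rates=np.array([0.0, 0.0, 1000.0]), name="bad")
        with pytest.raises(ValueError, match="shield"):
            shielded_suppression_protocol(
                three_glom_network, [bad], shielded_glomerulus=2
            )


class TestDatasetRoundTrip:
    def test_save_load_preserves_spikes_and_metadata(self, tmp_path, desk_network):
        odor = OdorSpec(rates=np.array([1500.0, 0.0]), t_on=50.0, t_off=250.0)
        ds = run_panel(desk_network, [odor], n_trials=1, horizon=300.0, base_seed=2)
        path = tmp_path / "ds.tsv"
        ds.save(path)
        back = SpikeDataset.load(path)
        assert back.horizon == ds.horizon
        assert len(back.spikes) == len(ds.spikes)
        assert back.metadata["base_seed"] == "2"
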