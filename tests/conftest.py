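"""Shared fixtures: reduced antennal-lobe networks and pre-run simulations.

The heavy HH simulations are session-scoped so that engine invariants and
the hypothesis-level checks can share trials instead of re-integrating the
network per test.  All randomness is seed-pinned.
"""

import numpy as np
import pytest

from flyal.engine import run_panel
from flyal.network import ArchitectureConfig, build_network
from flyal.odors import OdorSpec


@pytest.fixture(scope="session")
def desk_config():
    """Two-glomerulus network at full ORN convergence (desk-scale default)."""
    return ArchitectureConfig(
        n_glomeruli=2, n_orn=60, n_pn=6, n_lne=6, n_lni=6, seed=1
    )


@pytest.fixture(scope="session")
def desk_network(desk_config):
    return build_network(desk_config)


@pytest.fixture(scope="session")
def driven_dataset(desk_network):
    """Six trials of one strong odor on the desk network (shared spikes)."""
    odor = OdorSpec(
        rates=np.array([4000.0, 0.0]), t_on=500.0, t_off=1500.0, name="strong0"
    )
    return run_panel(desk_network, [odor], n_trials=6, horizon=1800.0, base_seed=11)


@pytest.fixture(scope="session")
def mixed_panel_dataset(desk_network):
    """A graded 8-odor panel spanning weak to saturating drive, 3 trials."""
    levels = [
        (300, 0),
        (800, 150),
        (1500, 400),
        (3000, 800),
        (6000, 1500),
        (500, 3000),
        (1200, 600),
        (0, 1000),
    ]
    panel = [
        OdorSpec(
            rates=np.array([float(a), float(b)]),
            t_on=500.0,
            t_off=1500.0,
            name=f"graded{k}",
        )
        for k, (a, b) in enumerate(levels)
    ]
    return run_panel(desk_network, panel, n_trials=3, horizon=1500.0, base_seed=21)


@pytest.fixture(scope="session")
def background_dataset(desk_network):
    """Background-only activity (no odor) on the desk network."""
    from flyal.odors import background_odor

    bg = background_odor(2, name="background")
    return run_panel(desk_network, [bg], n_trials=1, horizon=3000.0, base_seed=7)


@pytest.fixture(scope="session")
def three_glom_network():
    from flyal.network import ArchitectureConfig, build_network

    return build_network(
        ArchitectureConfig(n_glomeruli=3, n_orn=60, n_pn=4, n_lne=4, n_lni=4, seed=2)
    )


@pytest.fixture(scope="session")
def depression_grid(desk_config):
    """Simulations over the 3x3 (p_ves, s_pre) grid with matched seeds.

    Two similar odors, 8 trials each, per grid point; returns the PN
    count tensors plus leave-one-trial-out 2-way accuracies at a long
    (400 ms) and a short (80 ms) observation window.
    """
    from flyal.discrimination import count_features, loto_accuracy
    from flyal.network import build_network, iso_rate_family

    p_grid = np.array([0.1, 0.3, 0.5])
    s_grid = np.array([0.0, 6.0, 12.0])
    family = iso_rate_family(desk_config, p_grid, s_grid)
    odors = [
        OdorSpec(rates=np.array([4000.0, 1000.0]), t_on=300.0, t_off=900.0, name="simA"),
        OdorSpec(rates=np.array([3600.0, 1250.0]), t_on=300.0, t_off=900.0, name="simB"),
    ]
    n_trials = 8
    shape = (3, 3)
    counts = np.zeros(shape + (len(odors), n_trials))
    acc_long = np.zeros(shape)
    acc_short = np.zeros(shape)
    for i, row in enumerate(family):
        for j, cfg in enumerate(row):
            net = build_network(cfg)
            ds = run_panel(net, odors, n_trials=n_trials, horizon=800.0, base_seed=23)
            pn_ids = list(net.ids_of("PN"))
            pn0 = net.ids_of("PN", 0)
            tab = ds.counts(pn0, window=(300.0, 700.0))
            for o, odor in enumerate(odors):
                for t in range(n_trials):
                    sel = (tab["odor"] == odor.name) & (tab["trial"] == t)
                    counts[i, j, o, t] = tab[sel]["count"].mean()
            Xl, y, tr = count_features(ds, pn_ids, (300.0, 700.0))
            Xs, _, _ = count_features(ds, pn_ids, (300.0, 380.0))
            acc_long[i, j] = loto_accuracy(Xl, y, tr)
            acc_short[i, j] = loto_accuracy(Xs, y, tr)
    return {
        "p_grid": p_grid,
        "s_grid": s_grid,
        "counts": counts,
        "acc_long": acc_long,
        "acc_short": acc_short,
    }
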