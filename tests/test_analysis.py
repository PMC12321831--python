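import numpy as np
import networkx as nx
import pandas as pd
import pytest

from restdp import make_fixture
from restdp.analysis import (active_neuron_counts, firing_rates, graph_metrics,
                             memory_alive, nonfilopodia_spacing,
                             potentiation_efficacy, survival_curves,
                             weight_histogram)

from conftest import tiny_network


# ----------------------------------------------------------------- firing rates
def test_firing_rate_count_over_window():
    raster = pd.DataFrame({"time_ms": [5, 20, 40, 60, 95.0], "neuron": [0] * 5})
    rates = firing_rates(raster, window=100.0, n_neurons=2, t_stop=100.0)
    assert rates.iloc[0, 0] == pytest.approx(50.0)  # 5 spikes / 100 ms
    assert rates.iloc[0, 1] == 0.0


def test_firing_rate_empty_raster():
    raster = pd.DataFrame({"time_ms": [], "neuron": []})
    rates = firing_rates(raster, 100.0, 3, 500.0)
    assert (rates.to_numpy() == 0).all()
    with pytest.raises(ValueError):
        firing_rates(raster, 0.0, 3, 500.0)


def test_firing_rate_regular_train():
    t = np.arange(10.0, 1000.0, 10.0)  # 100 Hz
    raster = pd.DataFrame({"time_ms": t, "neuron": np.zeros(t.size, int)})
    rates = firing_rates(raster, 100.0, 1, 1000.0)
    interior = rates.iloc[1:-1, 0]
    assert np.allclose(interior, 100.0)


# -------------------------------------------------------------------- efficacy
def test_potentiation_efficacy_ratio_and_filtering():
    ev = pd.DataFrame({
        "direction": [1, 1, 1, -1, 1],
        "requested": [0.5, 1.0, 0.8, 0.3, 0.0],
        "granted": [0.25, 1.0, 0.0, 0.3, 0.0],
    })
    eff = potentiation_efficacy(ev)
    assert eff.tolist() == [50.0, 100.0, 0.0]  # depression & zero-request excluded
    with pytest.raises(ValueError):
        potentiation_efficacy(ev.iloc[:0])


# --------------------------------------------------------------------- spacing
@pytest.mark.parametrize("positions, expected", [
    ({0, 3}, 3.0),
    ({0, 1, 2, 3, 4, 5}, 1.0),
    ({0, 1, 4}, 5.0 / 3.0),
])
def test_nonfilopodia_spacing_enumeration(positions, expected):
    w = [1.0 if q in positions else 0.0 for q in range(6)]
    net = tiny_network(7, {6: list(range(6))}, w, pools=np.zeros(7))
    assert nonfilopodia_spacing(net) == pytest.approx(expected)


def test_spacing_undefined_without_two_spines():
    net = tiny_network(7, {6: list(range(6))}, [1, 0, 0, 0, 0, 0.0],
                       pools=np.zeros(7))
    assert nonfilopodia_spacing(net) is None


def test_spacing_weakly_increases_when_interior_spine_silenced():
    w = [1.0, 1.0, 1.0, 0.0, 1.0, 0.0]
    net = tiny_network(7, {6: list(range(6))}, w, pools=np.zeros(7))
    before = nonfilopodia_spacing(net)
    net.w[net.aff_ptr[6] + 1] = 0.0
    assert nonfilopodia_spacing(net) >= before
    assert nonfilopodia_spacing(net) >= 1.0


# ---------------------------------------------------------------- graph metrics
def test_graph_metrics_empty_graph():
    net = make_fixture("chain3").network
    net.w[:] = 0.0
    g = graph_metrics(net)
    assert g["mean_in_degree"] == 0.0
    assert g["mean_out_closeness"] == 0.0


def test_chain3_closeness_bruteforce():
    net = make_fixture("chain3").network  # 0 ->(2ms) 1 ->(2ms) 2
    g = graph_metrics(net)
    assert g["mean_in_degree"] == pytest.approx(2 / 3)
    assert g["out_closeness"][0] == pytest.approx(2 / (2 + 4))
    assert g["out_closeness"][1] == pytest.approx(1 / 2)
    assert g["out_closeness"][2] == 0.0
    assert g["in_closeness"][2] == pytest.approx(2 / (2 + 4))
    # longer delays shrink closeness
    net.delay_steps[:] = 40  # 4 ms
    g2 = graph_metrics(net)
    assert g2["mean_out_closeness"] < g["mean_out_closeness"]


def test_closeness_matches_networkx_on_random_graph(rng):
    n = 12
    from restdp.network import NetworkParams, build_network
    net = build_network(NetworkParams(n_exc=n, n_in=2, p_rec=1.0, rng_seed=8))
    net.w[:] = (rng.random(net.n_rec) < 0.4) * 1.0
    g = graph_metrics(net)
    G = nx.DiGraph()
    G.add_nodes_from(range(n))
    for s, t, d, wt in zip(net.src, net.tgt, net.delay_steps * net.dt, net.w):
        if wt > 0:
            G.add_edge(int(s), int(t), delay=float(d))
    for u in range(n):
        lengths = nx.single_source_dijkstra_path_length(G, u, weight="delay")
        lengths.pop(u, None)
        expect = (len(lengths) / sum(lengths.values())) if lengths else 0.0
        assert g["out_closeness"][u] == pytest.approx(expect, rel=1e-9)


def test_complete_graph_closeness_symmetric():
    from restdp.network import NetworkParams, build_network
    net = build_network(NetworkParams(n_exc=5, n_in=2, p_rec=1.0, rng_seed=1))
    net.w[:] = 1.0
    net.delay_steps[:] = 10
    g = graph_metrics(net)
    assert np.allclose(g["out_closeness"], g["out_closeness"][0])
    assert np.allclose(g["in_closeness"], g["out_closeness"])


# ------------------------------------------------------------- survival curves
def test_survival_normalization_and_monotonicity():
    trace = pd.DataFrame({
        "time_ms": np.arange(0, 1000.0, 100.0),
        "weight_sum": [0, 5, 10, 9, 8, 6, 4, 2, 1, 0.0],
    })
    raster = pd.DataFrame({"time_ms": [150.0, 250, 350, 450],
                           "neuron": [0, 1, 0, 1]})
    sc = survival_curves(trace, raster)
    assert sc["weight_sum_pct"].max() == 100.0
    assert sc["weight_sum_pct"].iloc[2] == 100.0
    after_max = sc["weight_sum_pct"].iloc[2:]
    assert np.all(np.diff(after_max) <= 0)
    assert sc["active_neurons_pct"].max() == 100.0


def test_survival_all_zero_trace():
    trace = pd.DataFrame({"time_ms": [0.0, 100.0], "weight_sum": [0.0, 0.0]})
    raster = pd.DataFrame({"time_ms": [], "neuron": []})
    sc = survival_curves(trace, raster)
    assert (sc["weight_sum_pct"] == 0).all()
    assert (sc["active_neurons_pct"] == 0).all()


# ---------------------------------------------------------------- memory_alive
def test_memory_alive_boundaries():
    raster = pd.DataFrame({"time_ms": [100.0, 600.0], "neuron": [0, 1]})
    assert memory_alive(raster, 600.0, 500.0) is True  # spike at t included
    assert memory_alive(raster, 1100.0, 500.0) is False  # t-qw excluded (half-open)
    assert memory_alive(raster, 1099.9, 500.0) is True
    assert memory_alive(pd.DataFrame({"time_ms": [], "neuron": []}),
                        500.0, 500.0) is False
    with pytest.raises(ValueError):
        memory_alive(raster, 400.0, 500.0)


def test_weight_histogram_mass():
    net = make_fixture("dendrite6").network
    counts, _ = weight_histogram(net, bins=10)
    assert counts.sum() == net.n_alive
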