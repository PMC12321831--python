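import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import restdp
from restdp import (STDPParams, depress, make_fixture, neighbor_share,
                    potentiate, stdp_window)
from restdp.dynamics import Simulator
from restdp.plasticity import decay_pools


# ----------------------------------------------------------------- STDP window
@pytest.mark.parametrize("tau, w, expected", [
    (0.0, 0.0, 1.0),
    (0.0, 5.0, 1.0),
    (20.0, 0.3, math.exp(-1.0)),
    (40.0, 1.0, math.exp(-2.0)),
    (-20.0, 1.0, 0.18 * math.exp(-1.0)),
    (-20.0, 0.0, 0.0),
    (-1e-9, 2.0, pytest.approx(0.36, abs=1e-6)),
])
def test_stdp_window_closed_form(tau, w, expected):
    assert stdp_window(tau, w) == pytest.approx(expected, rel=1e-12)


@given(tau=st.floats(-500, 500), w=st.floats(0, 100))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_stdp_window_nonnegative_and_weight_scaling(tau, w):
    out = stdp_window(tau, w)
    assert out >= 0.0
    if tau < 0:
        assert out == pytest.approx(w * stdp_window(tau, 1.0), rel=1e-12)


def test_stdp_window_rejects_nonfinite():
    with pytest.raises(ValueError):
        stdp_window(math.nan, 1.0)
    with pytest.raises(ValueError):
        stdp_window(1.0, -0.5)


# ------------------------------------------------------------- neighbor kernel
def test_neighbor_share_values():
    denom = 2 * sum(math.exp(-k) for k in (1, 2, 3))
    assert neighbor_share(1) == pytest.approx(math.exp(-1) / denom, rel=1e-14)
    assert neighbor_share(1) == pytest.approx(0.33265, abs=5e-5)
    assert neighbor_share(-2) == neighbor_share(2)
    assert neighbor_share(0) == 0.0 and neighbor_share(4) == 0.0
    total = sum(neighbor_share(k) for k in (-3, -2, -1, 1, 2, 3))
    assert total == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------- potentiation scenarios
def dendrite(weights, pool):
    fx = make_fixture("dendrite6")
    net = fx.network
    net.w[:] = weights
    net.pool[7] = pool
    return net


CENTER = 3  # position (== synapse offset on the canonical dendrite)


def test_ample_neighbors_fund_exactly_by_share():
    net = dendrite([1.0] * 7, pool=5.0)
    j = net.aff_ptr[7] + CENTER
    ev = potentiate(net, 7, j, 0.6)
    assert ev.granted == pytest.approx(0.6, abs=1e-12)
    assert ev.from_pool == pytest.approx(0.0, abs=1e-12)
    for k in (1, 2, 3):
        for q in (CENTER - k, CENTER + k):
            lost = 1.0 - net.w[net.aff_ptr[7] + q]
            assert lost == pytest.approx(0.6 * neighbor_share(k), rel=1e-12)
    assert net.w[j] == pytest.approx(1.6, rel=1e-12)


def test_silent_neighbors_fall_back_to_pool():
    net = dendrite([0.0] * 7, pool=5.0)
    j = net.aff_ptr[7] + CENTER
    ev = potentiate(net, 7, j, 0.8)
    assert ev.granted == 0.8 and ev.from_neighbors == 0.0
    assert net.pool[7] == pytest.approx(4.2)
    assert net.w[j] == 0.8


def test_depleted_pool_grants_what_remains_and_zeroes_pool():
    net = dendrite([0.0] * 7, pool=0.4)
    j = net.aff_ptr[7] + CENTER
    ev = potentiate(net, 7, j, 0.8)
    assert ev.granted == 0.4
    assert net.pool[7] == 0.0  # exact depletion
    assert net.w[j] == 0.4


def test_partial_neighbor_funding_topped_up_from_pool():
    # neighbors jointly hold half the request; pool covers the rest
    weights = [0.0] * 7
    request = 0.6
    for k in (1, 2, 3):
        for q in (CENTER - k, CENTER + k):
            weights[q] = 0.5 * request * neighbor_share(k)
    net = dendrite(weights, pool=5.0)
    j = net.aff_ptr[7] + CENTER
    ev = potentiate(net, 7, j, request)
    assert ev.granted == pytest.approx(request, rel=1e-12)
    assert ev.from_neighbors == pytest.approx(request / 2, rel=1e-12)
    assert ev.from_pool == pytest.approx(request / 2, rel=1e-12)
    assert np.all(net.w[np.arange(7) != CENTER] == 0.0)  # neighbors drained


def test_everything_depleted_no_potentiation():
    net = dendrite([0.0] * 7, pool=0.0)
    j = net.aff_ptr[7] + CENTER
    before = net.w.copy()
    ev = potentiate(net, 7, j, 1.0)
    assert ev.granted == 0.0
    assert np.array_equal(net.w, before)


def test_edge_synapse_kernel_renormalized():
    # position 0 has neighbors only at +1, +2, +3
    net = dendrite([1.0] * 7, pool=0.0)
    j = net.aff_ptr[7] + 0
    total_before = net.w.sum() + net.pool[7]
    ev = potentiate(net, 7, j, 0.3)
    assert ev.granted == pytest.approx(0.3, rel=1e-12)
    shares = np.array([math.exp(-k) for k in (1, 2, 3)])
    shares /= shares.sum()
    for k in (1, 2, 3):
        lost = 1.0 - net.w[net.aff_ptr[7] + k]
        assert lost == pytest.approx(0.3 * shares[k - 1], rel=1e-12)
    assert net.w.sum() + net.pool[7] == pytest.approx(total_before, abs=1e-12)


def test_unknown_synapse_rejected():
    net = dendrite([1.0] * 7, pool=1.0)
    with pytest.raises(KeyError):
        potentiate(net, 7, 99, 0.1)
    with pytest.raises(KeyError):
        depress(net, 0, 0, 0.1)  # synapse 0 lives on neuron 7, not 0


# ------------------------------------------------------------------ depression
@pytest.mark.parametrize("w0, req, w1, moved", [
    (0.5, 0.2, 0.3, 0.2),
    (0.1, 0.2, 0.0, 0.1),  # relocate everything, weight exactly zero
    (0.0, 0.2, 0.0, 0.0),
])
def test_depress_relocates_to_pool(w0, req, w1, moved):
    net = dendrite([w0] + [0.0] * 6, pool=1.0)
    j = net.aff_ptr[7] + 0
    ev = depress(net, 7, j, req)
    assert net.w[j] == pytest.approx(w1, abs=1e-15)
    assert ev.granted == pytest.approx(moved, abs=1e-15)
    assert net.pool[7] == pytest.approx(1.0 + moved, rel=1e-15)


# ------------------------------------------------------------------ pool decay
def test_pool_decay_closed_form():
    p = np.array([2.0, 0.0])
    dt, t_total = 0.1, 10_000.0
    for _ in range(int(t_total / dt)):
        decay_pools(p, dt)
    assert p[0] == pytest.approx(2 * math.exp(-1.0), rel=1e-4)
    assert p[1] == 0.0


# ------------------------------------------------- conservation property tests
@given(data=st.data())
@settings(max_examples=100, deadline=None, derandomize=True)
def test_event_conservation_and_bounds(data):
    """Any sequence of plasticity events conserves sum(w)+pool per neuron
    to 1e-12, never drives anything negative, and grants at most the request."""
    weights = data.draw(st.lists(st.floats(0, 3), min_size=7, max_size=7))
    pool = data.draw(st.floats(0, 5))
    net = dendrite(weights, pool)
    ops = data.draw(st.lists(st.tuples(
        st.sampled_from(["pot", "dep"]),
        st.integers(0, 6),
        st.floats(0, 2)), max_size=12))
    for kind, q, amount in ops:
        total_before = net.w.sum() + net.pool[7]
        j = net.aff_ptr[7] + q
        ev = (potentiate if kind == "pot" else depress)(net, 7, j, amount)
        assert net.w.sum() + net.pool[7] == pytest.approx(total_before, abs=1e-12)
        assert net.w.min() >= 0.0 and net.pool[7] >= 0.0
        assert 0.0 <= ev.granted <= ev.requested + 1e-12
        if kind == "pot":
            assert ev.from_neighbors + ev.from_pool == ev.granted


def test_grant_equals_request_when_resources_ample():
    net = dendrite([2.0] * 7, pool=10.0)
    for q in range(7):
        ev = potentiate(net, 7, net.aff_ptr[7] + q, 0.9)
        assert ev.granted == pytest.approx(0.9, rel=1e-12)


# --------------------------------------- nearest-spike pairing vs enumeration
def enumerate_pairings(arrival_steps, post_steps, dt, p: STDPParams, w0, pool0):
    """Explicit pair-enumeration oracle for one synapse: replay all arrival
    and post-spike events in time order, pairing each with its most recent
    partner, and integrate the weight/pool updates (pool for this neuron
    only; no neighbors on the pair fixture's single-synapse dendrite).
    Pool decay is ignored, so only short scripts should be compared."""
    events = sorted([(k, "arr") for k in arrival_steps] +
                    [(k, "post") for k in post_steps],
                    key=lambda e: (e[0], e[1] == "post"))  # arrivals first
    w, pool = w0, pool0
    last_arr = last_post = None
    out = []
    for k, kind in events:
        if kind == "arr":
            if last_post is not None and last_post < k:
                tau = (last_post - k) * dt
                req = p.depression_multiple * math.exp(tau / p.tau_stdp) * w
                if req > 0.0:  # silent synapses see no depression
                    moved = min(req, w)
                    w -= moved
                    pool += moved
                    out.append(("dep", k, req, moved))
            last_arr = k
        else:
            if last_arr is not None:
                tau = (k - last_arr) * dt
                req = math.exp(-tau / p.tau_stdp)
                granted = min(req, pool)
                pool -= granted
                w += granted
                out.append(("pot", k, req, granted))
            last_post = k
    return w, out


def test_nearest_spike_pairing_matches_enumeration_oracle():
    fx = make_fixture("pair")
    net = fx.network
    net.pool[:] = [0.0, 50.0]  # ample: grants are never resource-limited
    sim = Simulator(net, trace_interval=0, snapshot_interval=0)
    # script: pre spikes (train 0 -> neuron 0), post spikes (train 1 -> neuron 1)
    # timed to produce pre-before-post and post-before-pre pairings
    pre_in = [0, 400, 800, 1200]
    post_in = [150, 500, 520, 1500]
    ev_steps = np.array(sorted(pre_in + post_in), dtype=np.int64)
    ev_trains = np.array([0 if s in pre_in else 1 for s in ev_steps], np.int32)
    sim.set_input_events(ev_steps, ev_trains)
    sim.run(200.0)

    raster = sim.raster()
    pre_spikes = raster[raster.neuron == 0]["time_ms"].to_numpy()
    post_spikes = raster[raster.neuron == 1]["time_ms"].to_numpy()
    arrivals = np.round(pre_spikes / net.dt).astype(int) + int(net.delay_steps[0])
    posts = np.round(post_spikes / net.dt).astype(int)
    w_expected, pairs = enumerate_pairings(arrivals, posts, net.dt,
                                           STDPParams(), 0.0, 50.0)

    log = sim.events()
    assert len(log) == len(pairs)
    for (kind, k, req, amt), (_, row) in zip(pairs, log.iterrows()):
        assert row.direction == (1 if kind == "pot" else -1)
        assert row.time_ms == pytest.approx(k * net.dt, abs=1e-9)
        assert row.requested == pytest.approx(req, rel=1e-9)
        assert row.granted == pytest.approx(amt, rel=1e-9, abs=1e-12)
    assert net.w[0] == pytest.approx(w_expected, rel=1e-9)
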