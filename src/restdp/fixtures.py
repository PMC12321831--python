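"""Tiny deterministic networks with scripted spikes, for tests and examples.

Three named fixtures:

``pair``
    One presynaptic and one postsynaptic neuron joined by a single plastic
    synapse — for probing the STDP window with scripted spike timings.
``dendrite6``
    One target neuron with seven afferents on one dendrite; the centre
    synapse (position 3) has the full set of six neighbors, so potentiating
    it exercises the exact heterosynaptic kernel shares.
``chain3``
    Three neurons in a directed chain with 2 ms delays — the smallest graph
    with distinct closeness values.

All fixtures are fully deterministic and run in well under a second.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import Network

__all__ = ["Fixture", "make_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = ("pair", "dendrite6", "chain3")


@dataclass
class Fixture:
    name: str
    network: Network
    notes: str
    #: scripted presynaptic spikes as (time_ms, train) input events
    input_events: list[tuple[float, int]] = field(default_factory=list)


def _net(n_neurons, n_trains, src, tgt, pos, delay_steps, w, pool,
         in_src=(), in_tgt=(), in_delay=(), in_w=(), dt=0.1) -> Network:
    order = np.lexsort((pos, tgt))
    return Network(
        n_neurons=n_neurons, n_trains=n_trains, dt=dt,
        src=np.asarray(src, np.int32)[order],
        tgt=np.asarray(tgt, np.int32)[order],
        pos=np.asarray(pos, np.int32)[order],
        delay_steps=np.asarray(delay_steps, np.int32)[order],
        w=np.asarray(w, np.float64)[order],
        alive=np.ones(len(src), bool),
        in_src=np.asarray(in_src, np.int32),
        in_tgt=np.asarray(in_tgt, np.int32),
        in_delay_steps=np.asarray(in_delay, np.int32),
        in_w=np.asarray(in_w, np.float64),
        pool=np.asarray(pool, np.float64),
    )


def make_fixture(name: str) -> Fixture:
    if name == "pair":
        # neuron 0 -> neuron 1, one synapse at position 0, 1 ms delay;
        # one strong input synapse onto each neuron so spikes can be scripted
        net = _net(2, 2, src=[0], tgt=[1], pos=[0], delay_steps=[10],
                   w=[0.0], pool=[2.0, 2.0],
                   in_src=[0, 1], in_tgt=[0, 1], in_delay=[10, 10],
                   in_w=[3.0, 3.0])
        return Fixture("pair", net,
                       "single plastic synapse for STDP-window pairing tests")
    if name == "dendrite6":
        # seven afferents (neurons 0..6) onto neuron 7; centre at position 3
        src = list(range(7))
        net = _net(8, 1, src=src, tgt=[7] * 7, pos=list(range(7)),
                   delay_steps=[10] * 7, w=[1.0] * 7,
                   pool=[0.0] * 7 + [2.0])
        return Fixture("dendrite6", net,
                       "centre synapse (position 3) has six neighbors; "
                       "neighbor losses follow the exponential kernel exactly")
    if name == "chain3":
        # 0 -> 1 -> 2, delays 2 ms (20 steps), unit weights
        net = _net(3, 1, src=[0, 1], tgt=[1, 2], pos=[0, 0],
                   delay_steps=[20, 20], w=[1.0, 1.0], pool=[0.0] * 3)
        return Fixture("chain3", net,
                       "directed chain with 2 ms delays for closeness tests")
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
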