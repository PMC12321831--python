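import numpy as np
import pytest

from restdp.network import Network


def tiny_network(n_neurons, positions_by_target, weights, pools, *,
                 delay_steps=10, dt=0.1, sources=None,
                 in_syn=()):  # in_syn: iterable of (train, tgt, delay, w)
    """Hand-build a small Network from explicit per-target dendrite layouts.

    ``positions_by_target``: {target: [position, ...]}; ``weights`` flat list
    in the same (target, position) iteration order.  Sources default to
    cycling over the other neurons.
    """
    src, tgt, pos = [], [], []
    for t, plist in positions_by_target.items():
        others = [n for n in range(n_neurons) if n != t]
        for i, q in enumerate(plist):
            s = sources[len(src)] if sources is not None else others[i % len(others)]
            src.append(s)
            tgt.append(t)
            pos.append(q)
    order = np.lexsort((pos, tgt))
    in_syn = list(in_syn)
    return Network(
        n_neurons=n_neurons,
        n_trains=max([i[0] for i in in_syn], default=-1) + 1,
        dt=dt,
        src=np.asarray(src, np.int32)[order],
        tgt=np.asarray(tgt, np.int32)[order],
        pos=np.asarray(pos, np.int32)[order],
        delay_steps=np.full(len(src), delay_steps, np.int32),
        w=np.asarray(weights, np.float64)[order],
        alive=np.ones(len(src), bool),
        in_src=np.asarray([i[0] for i in in_syn], np.int32),
        in_tgt=np.asarray([i[1] for i in in_syn], np.int32),
        in_delay_steps=np.asarray([i[2] for i in in_syn], np.int32),
        in_w=np.asarray([i[3] for i in in_syn], np.float64),
        pool=np.asarray(pools, np.float64),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
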