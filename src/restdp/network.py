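"""Random recurrent network construction: topology, delays, weights, resource pools.

The model network is a pool of excitatory leaky integrate-and-fire neurons,
recurrently connected by *plastic* synapses (initial weight 0, i.e. a newly
formed network of silent synapses), driven by independent Poisson spike
trains through *static* input synapses with uniform-random weights.  Every
connection carries an axonal conduction delay drawn uniformly from
[delay_min, delay_max] and rounded onto the integration grid.

Each recurrent synapse occupies a *dendritic position* on its target neuron:
an integer slot 0..m-1 along a one-dimensional dendrite.  Heterosynaptic
plasticity acts between synapses at nearby positions.  Each neuron also owns
a resource pool ``p`` (log-normally initialized) that exchanges resources
with its afferent synaptic weights.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkParams",
    "Network",
    "build_network",
    "init_resource_pools",
    "save_network",
    "load_network",
]


@dataclass
class NetworkParams:
    """Topology and initialization parameters.

    Defaults are the published model values: 200 excitatory neurons with 25 %
    recurrent connection probability, 50 Poisson input trains connecting with
    10 % probability, axonal delays uniform on [1, 5] ms, resource pools
    ``pool_scale * exp(xi)`` with standard-normal ``xi``.
    """

    n_exc: int = 200
    n_in: int = 50
    p_rec: float = 0.25
    p_in: float = 0.10
    delay_min: float = 1.0  # ms
    delay_max: float = 5.0  # ms
    pool_scale: float = 2.0  # resource units; median of the log-normal pool
    dt: float = 0.1  # ms, forward-Euler step
    rng_seed: int = 0
    dendrite_order: str = "by_source"  # or "random"

    def validate(self) -> None:
        if self.n_exc <= 0 or self.n_in <= 0:
            raise ValueError("neuron/train counts must be positive")
        if not (0.0 < self.p_rec <= 1.0) or not (0.0 < self.p_in <= 1.0):
            raise ValueError("connection probabilities must lie in (0, 1]")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.delay_min < self.dt:
            raise ValueError("delay_min must be at least one time step")
        if self.delay_max < self.delay_min:
            raise ValueError("delay_max must be >= delay_min")
        if self.pool_scale <= 0:
            raise ValueError("pool_scale must be positive")
        if self.dendrite_order not in ("by_source", "random"):
            raise ValueError("dendrite_order must be 'by_source' or 'random'")


@dataclass
class Network:
    """Static topology plus mutable weights and per-neuron resource pools.

    Recurrent synapses are stored in canonical order: sorted by
    (target, dendritic position).  ``aff_ptr`` is the CSR row pointer of that
    ordering, so the afferent synapses of neuron ``n`` are the ids
    ``aff_ptr[n]:aff_ptr[n+1]`` and the synapse at position ``q`` on ``n``
    (if it exists and is alive) is id ``aff_ptr[n] + q``.  ``eff_ptr`` /
    ``eff_syn`` index the same synapses grouped by source neuron.
    """

    n_neurons: int
    n_trains: int
    dt: float
    # recurrent synapses (canonical (target, position) order)
    src: np.ndarray  # int32
    tgt: np.ndarray  # int32
    pos: np.ndarray  # int32 dendritic slot on target
    delay_steps: np.ndarray  # int32
    w: np.ndarray  # float64, >= 0
    alive: np.ndarray  # bool (False once deleted)
    # input synapses
    in_src: np.ndarray  # int32 train index
    in_tgt: np.ndarray  # int32
    in_delay_steps: np.ndarray  # int32
    in_w: np.ndarray  # float64 fixed weights
    # per-neuron resource pools
    pool: np.ndarray  # float64, >= 0
    # indexes (derived)
    aff_ptr: np.ndarray = field(default=None)  # int64, len n_neurons+1
    eff_ptr: np.ndarray = field(default=None)
    eff_syn: np.ndarray = field(default=None)
    in_eff_ptr: np.ndarray = field(default=None)
    in_eff_syn: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.aff_ptr is None:
            self.rebuild_indexes()

    @property
    def n_rec(self) -> int:
        return self.src.size

    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def rebuild_indexes(self) -> None:
        """(Re)derive CSR indexes; synapse arrays must already be in
        canonical (target, position) order with contiguous positions."""
        n = self.n_neurons
        counts = np.bincount(self.tgt, minlength=n)
        self.aff_ptr = np.concatenate(([0], np.cumsum(counts))).astype(np.int64)
        order = np.argsort(self.src, kind="stable")
        self.eff_syn = order.astype(np.int64)
        counts_e = np.bincount(self.src, minlength=n)
        self.eff_ptr = np.concatenate(([0], np.cumsum(counts_e))).astype(np.int64)
        order_i = np.argsort(self.in_src, kind="stable")
        self.in_eff_syn = order_i.astype(np.int64)
        counts_i = np.bincount(self.in_src, minlength=self.n_trains)
        self.in_eff_ptr = np.concatenate(([0], np.cumsum(counts_i))).astype(np.int64)

    def afferents(self, n: int) -> np.ndarray:
        """Synapse ids afferent to neuron ``n`` in ascending dendritic position."""
        return np.arange(self.aff_ptr[n], self.aff_ptr[n + 1], dtype=np.int64)

    def synapse_at(self, n: int, q: int) -> int:
        """Synapse id at dendritic position ``q`` on neuron ``n`` or -1."""
        m = self.aff_ptr[n + 1] - self.aff_ptr[n]
        if 0 <= q < m:
            j = int(self.aff_ptr[n] + q)
            if self.alive[j]:
                return j
        return -1

    def total_resources(self, n: int | None = None) -> float:
        """Sum of afferent weights plus pool, per neuron or whole network."""
        if n is None:
            return float(self.w[self.alive].sum() + self.pool.sum())
        lo, hi = self.aff_ptr[n], self.aff_ptr[n + 1]
        wseg = self.w[lo:hi][self.alive[lo:hi]]
        return float(wseg.sum() + self.pool[n])

    def copy(self) -> "Network":
        kw = {}
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            kw[f.name] = v.copy() if isinstance(v, np.ndarray) else v
        return Network(**kw)


def init_resource_pools(n: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` log-normal pool values ``scale * exp(xi)``, xi ~ N(0, 1).

    The median is ``scale`` (2 resource units by default); the skewed
    distribution mirrors the log-normal statistics widely reported for
    synaptic and neuronal quantities.
    """
    if n < 1:
        raise ValueError("need at least one pool")
    if scale <= 0:
        raise ValueError("scale must be positive")
    return scale * np.exp(rng.standard_normal(n))


def _draw_delays(n: int, params: NetworkParams, rng: np.random.Generator) -> np.ndarray:
    d = rng.uniform(params.delay_min, params.delay_max, size=n)
    steps = np.rint(d / params.dt).astype(np.int32)
    return np.maximum(steps, 1)


def build_network(params: NetworkParams) -> Network:
    """Construct the random network of the model.

    Each ordered neuron pair (i != j) is connected independently with
    probability ``p_rec`` (no self-connections); each (train, neuron) pair
    with probability ``p_in``.  Recurrent weights start at 0; input weights
    are uniform on (0, 1).  Dendritic positions on each target are assigned
    in ascending presynaptic-source order by default (``dendrite_order =
    "random"`` applies a seeded permutation instead).  Fully reproducible
    from ``params.rng_seed``.
    """
    params.validate()
    ss = np.random.SeedSequence(params.rng_seed)
    rng_topo, rng_in, rng_pool = (np.random.default_rng(s) for s in ss.spawn(3))
    n, n_in = params.n_exc, params.n_in

    adj = rng_topo.random((n, n)) < params.p_rec
    np.fill_diagonal(adj, False)
    src_r, tgt_r = np.nonzero(adj)  # row-major: sorted by src then tgt

    # canonical order: (target, position); positions along each dendrite
    order = np.argsort(tgt_r, kind="stable")  # within a target, ascending src
    src = src_r[order].astype(np.int32)
    tgt = tgt_r[order].astype(np.int32)
    counts = np.bincount(tgt, minlength=n)
    pos = (np.arange(src.size) - np.repeat(np.concatenate(([0], np.cumsum(counts)))[:-1], counts)).astype(np.int32)
    if params.dendrite_order == "random":
        starts = np.concatenate(([0], np.cumsum(counts)))[:-1]
        for t in range(n):
            m = counts[t]
            if m > 1:
                pos[starts[t]:starts[t] + m] = rng_topo.permutation(m).astype(np.int32)
        # re-sort into canonical (target, position) order
        order2 = np.lexsort((pos, tgt))
        src, tgt, pos = src[order2], tgt[order2], pos[order2]
    delay_steps = _draw_delays(src.size, params, rng_topo)

    adj_in = rng_in.random((n_in, n)) < params.p_in
    in_src_a, in_tgt_a = np.nonzero(adj_in)
    in_w = rng_in.uniform(0.0, 1.0, size=in_src_a.size)
    in_delay = _draw_delays(in_src_a.size, params, rng_in)

    pool = init_resource_pools(n, params.pool_scale, rng_pool)

    return Network(
        n_neurons=n,
        n_trains=n_in,
        dt=params.dt,
        src=src,
        tgt=tgt,
        pos=pos,
        delay_steps=delay_steps,
        w=np.zeros(src.size, dtype=np.float64),
        alive=np.ones(src.size, dtype=bool),
        in_src=in_src_a.astype(np.int32),
        in_tgt=in_tgt_a.astype(np.int32),
        in_delay_steps=in_delay,
        in_w=in_w.astype(np.float64),
        pool=pool.astype(np.float64),
    )


_REC_COLS = ("source", "target", "position", "delay_steps", "weight", "alive")
_IN_COLS = ("train", "target", "delay_steps", "weight")


def save_network(net: Network, directory: str | Path) -> None:
    """Write a network as plain columnar text: one synapse per row."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rec = np.column_stack(
        [net.src, net.tgt, net.pos, net.delay_steps, net.w, net.alive.astype(int)]
    )
    hdr = f"n_neurons={net.n_neurons} n_trains={net.n_trains} dt={net.dt!r}\n" + "\t".join(_REC_COLS)
    np.savetxt(d / "recurrent_synapses.tsv", rec, fmt=["%d", "%d", "%d", "%d", "%.17g", "%d"],
               delimiter="\t", header=hdr)
    inp = np.column_stack([net.in_src, net.in_tgt, net.in_delay_steps, net.in_w])
    np.savetxt(d / "input_synapses.tsv", inp, fmt=["%d", "%d", "%d", "%.17g"],
               delimiter="\t", header="\t".join(_IN_COLS))
    np.savetxt(d / "pools.tsv", net.pool, fmt="%.17g", header="pool")


def load_network(directory: str | Path) -> Network:
    d = Path(directory)
    with open(d / "recurrent_synapses.tsv") as fh:
        meta = fh.readline().lstrip("# ").split()
        kv = dict(item.split("=") for item in meta)
        rec = np.loadtxt(io.StringIO(fh.read()), ndmin=2)
    inp = np.loadtxt(d / "input_synapses.tsv", ndmin=2)
    pool = np.atleast_1d(np.loadtxt(d / "pools.tsv"))
    return Network(
        n_neurons=int(kv["n_neurons"]),
        n_trains=int(kv["n_trains"]),
        dt=float(kv["dt"]),
        src=rec[:, 0].astype(np.int32),
        tgt=rec[:, 1].astype(np.int32),
        pos=rec[:, 2].astype(np.int32),
        delay_steps=rec[:, 3].astype(np.int32),
        w=rec[:, 4].astype(np.float64),
        alive=rec[:, 5].astype(bool),
        in_src=inp[:, 0].astype(np.int32) if inp.size else np.zeros(0, np.int32),
        in_tgt=inp[:, 1].astype(np.int32) if inp.size else np.zeros(0, np.int32),
        in_delay_steps=inp[:, 2].astype(np.int32) if inp.size else np.zeros(0, np.int32),
        in_w=inp[:, 3].astype(np.float64) if inp.size else np.zeros(0, np.float64),
        pool=pool.astype(np.float64),
    )
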