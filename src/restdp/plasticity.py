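"""Resource-dependent STDP with heterosynaptic neighbor depression.

The learning rule extends pair-based STDP with an explicit resource economy.
A pre/post spike pair separated by ``tau = t_post - t_pre`` requests a weight
change

    f(tau) = exp(-tau / tau_stdp)            for tau >= 0   (potentiation)
    f(tau) = c_dep * exp(tau / tau_stdp) * w  for tau <  0   (depression)

with ``tau_stdp = 20 ms`` and the depression multiple ``c_dep = 0.18`` that
balances potentiation against the extra depression the heterosynaptic
mechanism introduces.  Depression is weight-dependent and the requested
amount is *relocated* into the neuron's resource pool rather than lost.

Potentiation must be *funded*: the requested amount is drawn first from the
weights of dendritic neighbors (positions +-1..3, exponentially weighted by
distance — heterosynaptic depression), then from the neuron's pool.  Each
supplier is capped at what it holds, so the granted change can fall short of
the request ("potentiation efficacy" < 100 %) or be zero outright when both
neighbors and pool are depleted.  Every individual event conserves the sum
of afferent weights plus pool on the neuron exactly; the only resource sink
is the slow exponential decay of the pool (``tau_pool = 10 s``).

These functions are the reference (pure NumPy/Python) implementation used
directly on small networks and fixtures; :mod:`restdp.dynamics` runs the
same arithmetic in compiled form inside the closed-loop simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .network import Network

__all__ = [
    "STDPParams",
    "PlasticityEvent",
    "stdp_window",
    "neighbor_share",
    "neighbor_shares_for",
    "potentiate",
    "depress",
    "decay_pools",
]


@dataclass
class STDPParams:
    """Plasticity parameters (defaults are the published model values)."""

    tau_stdp: float = 20.0  # ms, STDP window time constant
    depression_multiple: float = 0.18  # dimensionless scaling of depression
    max_neighbor_distance: int = 3  # dendritic positions
    tau_pool: float = 10_000.0  # ms (10 s), resource pool decay constant

    def validate(self) -> None:
        if min(self.tau_stdp, self.depression_multiple, self.tau_pool) <= 0:
            raise ValueError("STDP parameters must be positive")
        if self.max_neighbor_distance < 1:
            raise ValueError("max_neighbor_distance must be >= 1")


@dataclass
class PlasticityEvent:
    """Record of a single pairing: what was asked for and what was granted."""

    time: float  # ms
    synapse: int
    tau: float  # ms, post minus pre
    direction: int  # +1 potentiation, -1 depression
    requested: float
    granted: float
    from_neighbors: float = 0.0  # resources drawn from neighbor weights
    from_pool: float = 0.0  # drawn from (+) or returned to the pool

    def as_tuple(self):
        return (self.time, self.synapse, self.tau, self.direction,
                self.requested, self.granted, self.from_neighbors, self.from_pool)


def stdp_window(tau: float, w: float, params: STDPParams | None = None) -> float:
    """Requested |dw| for a spike pair with lag ``tau`` (ms) at weight ``w``.

    ``tau >= 0`` (pre before or simultaneous with post) requests
    potentiation ``exp(-tau/tau_stdp)``; ``tau < 0`` requests the
    weight-dependent depression ``0.18 * exp(tau/tau_stdp) * w``.
    """
    p = params or STDPParams()
    if not math.isfinite(tau):
        raise ValueError("tau must be finite")
    if w < 0:
        raise ValueError("weight must be non-negative")
    if tau >= 0:
        return math.exp(-tau / p.tau_stdp)
    return p.depression_multiple * math.exp(tau / p.tau_stdp) * w


def neighbor_share(k: int, max_distance: int = 3) -> float:
    """Fraction of a potentiation request drawn from the neighbor at offset +-k.

    Shares follow a decaying exponential of dendritic distance, normalized so
    the full set of 2*max_distance neighbors sums to exactly 1:
    ``share(k) = exp(-k) / (2 * sum_{k'=1..K} exp(-k'))``.  Zero outside the
    neighborhood.
    """
    k = abs(int(k))
    if k < 1 or k > max_distance:
        return 0.0
    denom = 2.0 * sum(math.exp(-kk) for kk in range(1, max_distance + 1))
    return math.exp(-k) / denom


def neighbor_shares_for(net: Network, n: int, j: int,
                        max_distance: int = 3) -> list[tuple[int, float]]:
    """Existing (alive) neighbors of synapse ``j`` on neuron ``n`` with their shares.

    Neighbors are the synapses at dendritic positions ``pos(j) +- k`` for
    ``k = 1..max_distance``.  At dendrite edges, or where deletion has left a
    gap, the exponential kernel is renormalized over the neighbors that exist
    so that the shares still sum to 1 (keeping neighbor-funded potentiation
    resource-conserving).  Returned in canonical draw order: distance 1..K,
    minus side before plus side.
    """
    q = int(net.pos[j])
    found: list[tuple[int, int]] = []  # (k, synapse id)
    for k in range(1, max_distance + 1):
        for sgn in (-1, +1):
            nb = net.synapse_at(n, q + sgn * k)
            if nb >= 0:
                found.append((k, nb))
    total = sum(math.exp(-k) for k, _ in found)
    if total <= 0.0:
        return []
    return [(nb, math.exp(-k) / total) for k, nb in found]


def potentiate(net: Network, n: int, j: int, requested: float,
               params: STDPParams | None = None, *, time: float = 0.0,
               tau: float = 0.0) -> PlasticityEvent:
    """Fund and apply a requested potentiation of synapse ``j`` on neuron ``n``.

    Resources are drawn neighbors-first (each capped at its current weight),
    any shortfall from the pool (capped at the pool level); the granted
    amount is the total actually drawn, so the event conserves
    ``sum(w) + pool`` on the neuron exactly.
    """
    p = params or STDPParams()
    if requested < 0:
        raise ValueError("requested potentiation must be non-negative")
    if not (0 <= j < net.n_rec) or not net.alive[j] or net.tgt[j] != n:
        raise KeyError(f"synapse {j} is not an alive recurrent synapse on neuron {n}")
    from_neighbors = 0.0
    for nb, share in neighbor_shares_for(net, n, j, p.max_neighbor_distance):
        supply = min(requested * share, net.w[nb])
        net.w[nb] -= supply
        from_neighbors += supply
    shortfall = max(requested - from_neighbors, 0.0)  # shares can overshoot by ulps
    from_pool = min(shortfall, net.pool[n])
    net.pool[n] -= from_pool
    granted = from_neighbors + from_pool
    net.w[j] += granted
    return PlasticityEvent(time, j, tau, +1, requested, granted,
                           from_neighbors, from_pool)


def depress(net: Network, n: int, j: int, requested: float,
            params: STDPParams | None = None, *, time: float = 0.0,
            tau: float = 0.0) -> PlasticityEvent:
    """Depress synapse ``j``, relocating the removed resources into the pool."""
    if requested < 0:
        raise ValueError("requested depression must be non-negative")
    if not (0 <= j < net.n_rec) or not net.alive[j] or net.tgt[j] != n:
        raise KeyError(f"synapse {j} is not an alive recurrent synapse on neuron {n}")
    moved = min(requested, net.w[j])
    net.w[j] -= moved
    net.pool[n] += moved
    return PlasticityEvent(time, j, tau, -1, requested, moved, 0.0, moved)


def decay_pools(pools: np.ndarray, dt: float,
                params: STDPParams | None = None) -> np.ndarray:
    """One forward-Euler step of the exponential pool decay (in place)."""
    p = params or STDPParams()
    pools *= 1.0 - dt / p.tau_pool
    return pools
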