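"""The two experiments: learning under stimulation, and progressive
synaptic degeneration with or without resource replenishment.

*Learning*: independent 50 Hz Poisson trains drive the network for the
first 20 s; plasticity is on throughout.  A subset of neurons typically
keeps firing after stimulation ends — a learned, self-sustained memory.

*Degeneration*: after the learning phase, surviving recurrent synapses are
deleted one at a time, uniformly at random, at a constant interval chosen so
that all would be gone by ``total_duration``.  With replenishment a deleted
synapse's resources return to its target neuron's pool (enabling
compensatory potentiation of surviving synapses); without, they are
discarded.  The protocol records when network activity ceases (no spike for
``quiet_window`` ms) and what fraction of the original connections remained
at that moment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import NeuronParams, Simulator, poisson_events
from .network import Network, NetworkParams, build_network
from .plasticity import STDPParams

__all__ = ["ProtocolConfig", "SimulationResult", "DegenerationResult",
           "run_learning", "run_degeneration", "delete_synapse"]


@dataclass
class ProtocolConfig:
    """Stimulation / degeneration protocol parameters.

    ``deletion_interval = None`` selects the default schedule: the interval
    that removes every initial recurrent synapse exactly once between
    ``degeneration_start`` and ``total_duration``.
    """

    input_rate: float = 50.0  # Hz
    input_duration: float = 20_000.0  # ms
    total_duration: float = 40_000.0  # ms (learning); degeneration uses 100 s
    degeneration_start: float = 40_000.0  # ms
    deletion_interval: float | None = None  # ms between deletions
    replenish_on_delete: bool = True
    snapshot_interval: float = 100.0  # ms, scalar trace sampling
    weight_snapshot_interval: float = 1000.0  # ms, full weight snapshots
    quiet_window: float = 500.0  # ms without any spike = activity ceased
    rng_seed: int = 0

    def validate(self) -> None:
        if self.input_rate < 0:
            raise ValueError("input_rate must be >= 0")
        if self.total_duration <= 0 or self.input_duration < 0:
            raise ValueError("durations must be positive")
        if self.degeneration_start < self.input_duration:
            raise ValueError("degeneration must start after stimulation ends")
        if self.deletion_interval is not None and self.deletion_interval <= 0:
            raise ValueError("deletion_interval must be positive")
        if self.quiet_window <= 0 or self.snapshot_interval <= 0:
            raise ValueError("windows must be positive")


@dataclass
class SimulationResult:
    """Raster, periodic traces/snapshots and event log of one closed-loop run."""

    config: ProtocolConfig
    network: Network  # final state (mutated in place during the run)
    raster: pd.DataFrame
    trace: pd.DataFrame
    events: pd.DataFrame
    snapshot_times: np.ndarray  # ms
    snapshot_weights: np.ndarray  # (n_snapshots, n_rec)
    snapshot_pools: np.ndarray  # (n_snapshots, n_neurons)
    pool_decay_total: float
    deleted_weight_total: float


@dataclass
class DegenerationResult:
    """Learning run + progressive-deletion phase bookkeeping."""

    sim: SimulationResult
    deletion_times: np.ndarray  # ms, one per deleted synapse
    deletion_order: np.ndarray  # synapse ids
    replenish: bool
    cessation_time: float | None  # ms; None if activity never ceased
    remaining_fraction_at_cessation: float | None  # of original connections
    initial_count: int = 0

    @property
    def remaining_percent(self) -> float | None:
        f = self.remaining_fraction_at_cessation
        return None if f is None else 100.0 * f


def _spawn_rngs(seed: int) -> dict[str, np.random.Generator]:
    """One master seed -> independent substreams per randomness source."""
    ss = np.random.SeedSequence(seed)
    names = ("topology", "input", "deletion")
    return {n: np.random.default_rng(s) for n, s in zip(names, ss.spawn(len(names)))}


def _make_sim(config: ProtocolConfig,
              net_params: NetworkParams | None,
              neuron: NeuronParams | None,
              stdp: STDPParams | None,
              record_events: bool) -> tuple[Simulator, dict]:
    config.validate()
    rngs = _spawn_rngs(config.rng_seed)
    params = net_params or NetworkParams()
    params.rng_seed = int(rngs["topology"].integers(2**31))
    net = build_network(params)
    sim = Simulator(net, neuron, stdp, record_events=record_events,
                    trace_interval=config.snapshot_interval,
                    snapshot_interval=config.weight_snapshot_interval)
    n_in_steps = int(round(config.input_duration / net.dt))
    steps, trains = poisson_events(config.input_rate, net.dt, n_in_steps,
                                   net.n_trains, rngs["input"])
    sim.set_input_events(steps, trains)
    return sim, rngs


def _result(sim: Simulator, config: ProtocolConfig) -> SimulationResult:
    t, w, p = sim.snapshots()
    return SimulationResult(
        config=config, network=sim.net, raster=sim.raster(),
        trace=sim.trace(), events=sim.events(),
        snapshot_times=t, snapshot_weights=w, snapshot_pools=p,
        pool_decay_total=float(sim.acc[0]),
        deleted_weight_total=float(sim.acc[1]),
    )


def run_learning(config: ProtocolConfig | None = None, *,
                 net_params: NetworkParams | None = None,
                 neuron: NeuronParams | None = None,
                 stdp: STDPParams | None = None,
                 record_events: bool = True) -> SimulationResult:
    """Run the stimulation/learning experiment end to end."""
    config = config or ProtocolConfig()
    sim, _ = _make_sim(config, net_params, neuron, stdp, record_events)
    sim.run(config.total_duration)
    return _result(sim, config)


def delete_synapse(net: Network, j: int, replenish: bool) -> Network:
    """Remove recurrent synapse ``j``; with ``replenish`` its resources move
    to the target neuron's pool, otherwise they are lost.  Dendritic
    positions of the remaining synapses are unchanged (the gap persists, so
    neighbor distances grow)."""
    if not (0 <= j < net.n_rec) or not net.alive[j]:
        raise KeyError(f"no alive recurrent synapse {j}")
    net.alive[j] = False
    if replenish:
        net.pool[net.tgt[j]] += net.w[j]
    net.w[j] = 0.0
    return net


def _cessation(raster: pd.DataFrame, start_ms: float, end_ms: float,
               quiet_window: float) -> float | None:
    """First time t in (start, end] with no spike in (t - quiet_window, t]."""
    times = raster["time_ms"].to_numpy()
    times = times[times > start_ms - quiet_window]
    t_prev = start_ms - quiet_window  # pretend a spike at window edge
    for t in times:
        if t - t_prev > quiet_window:
            break
        t_prev = t
    t_cease = t_prev + quiet_window
    return float(t_cease) if t_cease <= end_ms else None


def run_degeneration(config: ProtocolConfig | None = None, *,
                     net_params: NetworkParams | None = None,
                     neuron: NeuronParams | None = None,
                     stdp: STDPParams | None = None,
                     record_events: bool = False) -> DegenerationResult:
    """Learning phase followed by progressive random synaptic deletion.

    Deletion targets are a uniformly random permutation of the recurrent
    synapses (drawn from the ``deletion`` substream of the protocol seed, so
    replenish-on/off runs with the same seed delete the same synapses at the
    same times).  The simulation always runs to ``total_duration``; activity
    cessation is detected afterwards from the raster.
    """
    config = config or ProtocolConfig(total_duration=100_000.0)
    if config.total_duration <= config.degeneration_start:
        raise ValueError("total_duration must exceed degeneration_start")
    sim, rngs = _make_sim(config, net_params, neuron, stdp, record_events)
    net = sim.net
    m0 = net.n_rec
    order = rngs["deletion"].permutation(m0)
    interval = config.deletion_interval
    if interval is None:
        interval = (config.total_duration - config.degeneration_start) / m0
    times = config.degeneration_start + interval * np.arange(len(order))
    steps = np.round(times / net.dt).astype(np.int64)
    keep = steps < int(round(config.total_duration / net.dt))
    sim.schedule_deletions(steps[keep], order[keep], config.replenish_on_delete)
    sim.run(config.total_duration)
    res = _result(sim, config)

    t_cease = _cessation(res.raster, config.degeneration_start,
                         config.total_duration, config.quiet_window)
    if t_cease is None:
        frac = None
    else:
        n_deleted = int(np.searchsorted(times[keep], t_cease, side="right"))
        frac = (m0 - n_deleted) / m0
    return DegenerationResult(
        sim=res, deletion_times=times[keep], deletion_order=order[keep],
        replenish=config.replenish_on_delete, cessation_time=t_cease,
        remaining_fraction_at_cessation=frac, initial_count=m0,
    )
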