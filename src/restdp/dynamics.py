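"""Neuron/synapse dynamics and the closed-loop forward-Euler simulator.

Membrane potentials follow leaky integrate-and-fire dynamics in threshold
units (theta = 1, tau_v = 25 ms) driven by the refractory-gated sum of
synaptic currents:

    tau_v dv/dt = -v + r * (sum_i s_i + sum_j s_j),   v -> 0 when v >= theta.

A spike triggers a 3 ms absolute refractory period (v clamped at 0,
threshold test disabled; currents and the refractory gain keep integrating)
followed by relative refractoriness: the gain ``r`` is reset to 0 at a spike
and recovers as ``tau_r dr/dt = 1 - r`` with tau_r = 5 ms.

Each synapse contributes a double-exponential current: a presynaptic arrival
increments the rise variable ``s'`` which feeds the output current ``s``:

    tau_sr ds'/dt = -s' + g * I * w,    tau_sf ds/dt = -s + s'

with tau_sr = 2.6 ms, tau_sf = 31.3 ms.  ``I`` is the binary per-step spike
indicator and ``g`` an injection gain.  Under forward Euler a presynaptic
arrival therefore increments ``s'`` by ``g * w * dt / tau_sr``; the package
parametrizes this directly as ``impulse_gain = g * dt / tau_sr``, the
per-arrival increment of ``s'`` in units of the synaptic weight (a
delta-impulse convention, independent of the step size).  The default
``impulse_gain = 12`` is the excitability calibration of the model: the
smallest scanned value at which stimulation-driven learning reliably leaves
a persistently firing assembly after the input is switched off, which is the
calibration criterion the model's resource scale was chosen by.

Because all synapses on a neuron share the same time constants, the
simulator integrates the per-neuron *sums* of ``s'`` and ``s``; individual
synaptic currents are never needed by the model equations.

Spikes propagate along axons with per-synapse integer-step delays through a
ring buffer; spike-pair plasticity (see :mod:`restdp.plasticity`) is applied
event-locally: depression when a presynaptic arrival finds an earlier
postsynaptic spike, potentiation over all afferents when a neuron fires,
pairing each spike with the most recent partner (nearest-spike scheme, ties
``tau = 0`` counted as potentiation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .network import Network
from .plasticity import STDPParams

__all__ = ["NeuronParams", "poisson_input", "poisson_events",
           "double_exp_peak_time", "Simulator", "EVENT_COLUMNS"]


@dataclass
class NeuronParams:
    """Membrane, refractory and synaptic-current parameters (paper defaults)."""

    tau_v: float = 25.0  # ms, membrane time constant
    theta: float = 1.0  # firing threshold (dimensionless)
    tau_r: float = 5.0  # ms, relative-refractoriness recovery
    abs_refractory: float = 3.0  # ms, absolute refractory period
    tau_sr: float = 2.6  # ms, synaptic current rise
    tau_sf: float = 31.3  # ms, synaptic current decay
    impulse_gain: float = 12.0  # s' increment per arrival, in units of w

    def validate(self) -> None:
        if min(self.tau_v, self.tau_r, self.tau_sr, self.tau_sf) <= 0:
            raise ValueError("time constants must be positive")
        if self.abs_refractory < 0:
            raise ValueError("absolute refractory period must be >= 0")
        if self.impulse_gain <= 0:
            raise ValueError("impulse_gain must be positive")


def poisson_input(rate: float, dt: float, n_steps: int, n_trains: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli-thinned Poisson trains as a (n_steps, n_trains)
    boolean spike-indicator array; per-step spike probability ``rate * dt``.

    ``rate`` in Hz, ``dt`` in ms.  Rejects ``rate * dt >= 1`` (step too
    coarse to approximate a Poisson process).
    """
    if rate < 0:
        raise ValueError("rate must be non-negative")
    p = rate * dt * 1e-3
    if p >= 1.0:
        raise ValueError("rate * dt >= 1: time step too coarse for this rate")
    out = np.zeros((n_steps, n_trains), dtype=bool)
    if p == 0.0 or n_steps == 0:
        return out
    chunk = max(1, min(n_steps, 200_000 // max(n_trains, 1) * 50))
    for k0 in range(0, n_steps, chunk):
        k1 = min(n_steps, k0 + chunk)
        out[k0:k1] = rng.random((k1 - k0, n_trains)) < p
    return out


def poisson_events(rate: float, dt: float, n_steps: int, n_trains: int,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Poisson input as sorted event arrays (step, train)."""
    ind = poisson_input(rate, dt, n_steps, n_trains, rng)
    steps, trains = np.nonzero(ind)  # row-major -> sorted by step
    return steps.astype(np.int64), trains.astype(np.int32)


def double_exp_peak_time(tau_sr: float = 2.6, tau_sf: float = 31.3) -> float:
    """Time (ms) after arrival at which the double-exponential current peaks."""
    return tau_sr * tau_sf / (tau_sf - tau_sr) * math.log(tau_sf / tau_sr)


EVENT_COLUMNS = ["time_ms", "synapse", "tau_ms", "direction",
                 "requested", "granted", "from_neighbors", "from_pool"]


class Simulator:
    """Closed-loop simulator: dynamics + plasticity + resource-pool decay.

    Wraps the compiled kernel; owns all state arrays and the output buffers
    (spike raster, periodic scalar trace, periodic weight/pool snapshots and
    the plasticity-event log).  The network object is mutated in place
    (weights, pools, alive flags).

    Parameters
    ----------
    net : Network
        Network in canonical (target, position) synapse order.
    neuron, stdp : parameter bundles (paper defaults when omitted).
    record_events : bool
        Keep the per-pairing plasticity-event log (memory-heavy for long
        runs; the scalar trace is always recorded).
    trace_interval, snapshot_interval : float
        Sampling periods in ms for the scalar trace and for full
        weight/pool snapshots (0 disables).
    """

    def __init__(self, net: Network, neuron: NeuronParams | None = None,
                 stdp: STDPParams | None = None, *, record_events: bool = True,
                 trace_interval: float = 100.0,
                 snapshot_interval: float = 1000.0):
        self.net = net
        self.neuron = neuron or NeuronParams()
        self.stdp = stdp or STDPParams()
        self.neuron.validate()
        self.stdp.validate()
        self.dt = net.dt
        M = net.n_rec
        if M and not np.array_equal(net.aff_ptr[net.tgt] + net.pos,
                                    np.arange(M)):
            raise ValueError("network synapses must be in canonical "
                             "(target, position) order with contiguous positions")
        N = net.n_neurons
        self.k = 0
        # neuron state
        self.v = np.zeros(N)
        self.r = np.ones(N)
        self.refrac = np.zeros(N, dtype=np.int32)
        self.last_post = np.full(N, -1, dtype=np.int64)
        self.sp = np.zeros(N)  # summed synaptic rise variable s'
        self.s = np.zeros(N)  # summed synaptic output current s
        self.last_arr = np.full(M, -1, dtype=np.int64)
        # delivery ring buffer
        dmax = int(net.delay_steps.max(initial=0))
        if net.in_delay_steps.size:
            dmax = max(dmax, int(net.in_delay_steps.max()))
        self._H = dmax + 1
        self._rb = np.zeros((self._H, M + net.in_w.size), dtype=np.int64)
        self._rb_cnt = np.zeros(self._H, dtype=np.int64)
        # pending external events
        self._ev_step = np.zeros(0, dtype=np.int64)
        self._ev_train = np.zeros(0, dtype=np.int32)
        self._ev_ptr = np.zeros(1, dtype=np.int64)
        self._del_step = np.zeros(0, dtype=np.int64)
        self._del_syn = np.zeros(0, dtype=np.int64)
        self._del_ptr = np.zeros(1, dtype=np.int64)
        self._replenish = True
        # outputs
        self.record_events = bool(record_events)
        self.trace_interval = trace_interval
        self.snapshot_interval = snapshot_interval
        self._trace_every = int(round(trace_interval / self.dt)) if trace_interval else 0
        self._wsnap_every = int(round(snapshot_interval / self.dt)) if snapshot_interval else 0
        self._raster_chunks: list[tuple[np.ndarray, np.ndarray]] = []
        self._event_chunks: list[np.ndarray] = []
        self._trace_chunks: list[np.ndarray] = []
        self._snap_steps: list[int] = []
        self._snap_w: list[np.ndarray] = []
        self._snap_pool: list[np.ndarray] = []
        self.acc = np.zeros(2)  # [pool decay total, discarded deleted weight]
        self._spike_scratch = np.zeros(N, dtype=np.int64)

    # ------------------------------------------------------------------ inputs
    def set_input_spikes(self, indicators: np.ndarray, offset_steps: int = 0) -> None:
        """Provide input-train spikes as a boolean (n_steps, n_trains) array
        starting at step ``offset_steps`` (absolute)."""
        steps, trains = np.nonzero(indicators)
        self.set_input_events(steps + offset_steps, trains)

    def set_input_events(self, steps: np.ndarray, trains: np.ndarray) -> None:
        steps = np.asarray(steps, dtype=np.int64)
        trains = np.asarray(trains, dtype=np.int32)
        if steps.size and steps.min() < self.k:
            raise ValueError("input events lie in the past")
        if np.any(np.diff(steps) < 0):
            raise ValueError("input events must be sorted by step")
        self._ev_step = steps
        self._ev_train = trains
        self._ev_ptr[0] = 0

    def schedule_deletions(self, steps: np.ndarray, synapses: np.ndarray,
                           replenish: bool) -> None:
        """Schedule synapse deletions: synapse ``synapses[i]`` is removed at
        step ``steps[i]``; with ``replenish`` its weight moves to the target
        neuron's pool, otherwise it is discarded."""
        steps = np.asarray(steps, dtype=np.int64)
        if np.any(np.diff(steps) < 0):
            raise ValueError("deletion schedule must be sorted by step")
        self._del_step = steps
        self._del_syn = np.asarray(synapses, dtype=np.int64)
        self._del_ptr[0] = 0
        self._replenish = bool(replenish)

    # --------------------------------------------------------------------- run
    def run(self, duration: float) -> None:
        """Advance the simulation by ``duration`` ms."""
        n_steps = int(round(duration / self.dt))
        if n_steps <= 0:
            return
        k_stop = self.k + n_steps
        nrn = self.neuron
        abs_steps = int(round(nrn.abs_refractory / self.dt))
        c_inj = nrn.impulse_gain
        net = self.net
        N, M = net.n_neurons, net.n_rec

        cap_r = N * (n_steps // (abs_steps + 1) + 2)
        raster_step = np.zeros(cap_r, dtype=np.int64)
        raster_neuron = np.zeros(cap_r, dtype=np.int64)
        raster_cnt = np.zeros(1, dtype=np.int64)

        ev_cap = max(2 * (2 * M + net.in_w.size), 1_000_000) if self.record_events else 8
        ev_buf = np.zeros((ev_cap, 8))
        ev_cnt = np.zeros(1, dtype=np.int64)

        def n_hits(every):
            if not every:
                return 1
            f = lambda x: (x + every - 1) // every
            return int(f(k_stop) - f(self.k)) + 1

        trace_buf = np.zeros((n_hits(self._trace_every), 5))
        trace_cnt = np.zeros(1, dtype=np.int64)
        wsnap_rows = n_hits(self._wsnap_every) if self._wsnap_every else 1
        wsnap_w = np.zeros((wsnap_rows, M))
        wsnap_pool = np.zeros((wsnap_rows, N))
        wsnap_cnt = np.zeros(1, dtype=np.int64)
        snap_k0 = self.k

        k = self.k
        while k < k_stop:
            k, status = _kernels.run_window(
                k, k_stop,
                self.dt, nrn.theta, abs_steps,
                self.dt / nrn.tau_v, self.dt / nrn.tau_r,
                self.dt / nrn.tau_sf, self.dt / nrn.tau_sr,
                self.dt / self.stdp.tau_pool, c_inj,
                self.stdp.tau_stdp, self.stdp.depression_multiple,
                self.stdp.max_neighbor_distance,
                net.tgt, net.delay_steps, net.w, net.alive,
                net.aff_ptr, net.eff_ptr, net.eff_syn,
                net.in_tgt, net.in_delay_steps, net.in_w,
                net.in_eff_ptr, net.in_eff_syn,
                self.v, self.r, self.refrac, self.last_post, net.pool,
                self.sp, self.s, self.last_arr,
                self._rb, self._rb_cnt,
                self._ev_step, self._ev_train, self._ev_ptr,
                self._del_step, self._del_syn, self._del_ptr, self._replenish,
                raster_step, raster_neuron, raster_cnt,
                self.record_events, ev_buf, ev_cnt,
                self._trace_every, trace_buf, trace_cnt,
                self._wsnap_every, wsnap_w, wsnap_pool, wsnap_cnt,
                self.acc, self._spike_scratch,
            )
            if status == _kernels.EVENTS_FULL:
                self._event_chunks.append(ev_buf[:ev_cnt[0]].copy())
                ev_cnt[0] = 0
            elif status == _kernels.RASTER_FULL:
                self._raster_chunks.append((raster_step[:raster_cnt[0]].copy(),
                                            raster_neuron[:raster_cnt[0]].copy()))
                raster_cnt[0] = 0
            elif status == _kernels.NONFINITE:
                raise FloatingPointError(
                    f"non-finite network state at t = {k * self.dt:.1f} ms")

        self.k = k_stop
        self._raster_chunks.append((raster_step[:raster_cnt[0]].copy(),
                                    raster_neuron[:raster_cnt[0]].copy()))
        if self.record_events and ev_cnt[0]:
            self._event_chunks.append(ev_buf[:ev_cnt[0]].copy())
        tr = trace_buf[:trace_cnt[0]]
        self._trace_chunks.append(tr.copy())
        self._trace_chunks.append(self._current_trace_row())
        if self._wsnap_every:
            ks = np.arange(wsnap_cnt[0]) * self._wsnap_every
            first = ((snap_k0 + self._wsnap_every - 1) // self._wsnap_every) * self._wsnap_every
            self._snap_steps.extend((first + ks).tolist())
            self._snap_w.extend(list(wsnap_w[:wsnap_cnt[0]]))
            self._snap_pool.extend(list(wsnap_pool[:wsnap_cnt[0]]))
        self._snap_steps.append(k_stop)
        self._snap_w.append(net.w.copy())
        self._snap_pool.append(net.pool.copy())

    def step(self) -> None:
        """Advance by a single time step."""
        self.run(self.dt)

    def _current_trace_row(self) -> np.ndarray:
        net = self.net
        wal = net.w[net.alive]
        return np.array([[self.k, wal.sum(), (wal > 0).sum(),
                          net.pool.sum(), net.alive.sum()]], dtype=float)

    # ----------------------------------------------------------------- outputs
    @property
    def time(self) -> float:
        """Current simulation time in ms."""
        return self.k * self.dt

    def raster(self) -> pd.DataFrame:
        """Spike raster: one row per spike (time_ms, neuron)."""
        if self._raster_chunks:
            steps = np.concatenate([c[0] for c in self._raster_chunks])
            nrn = np.concatenate([c[1] for c in self._raster_chunks])
        else:
            steps = np.zeros(0, dtype=np.int64)
            nrn = steps
        return pd.DataFrame({"time_ms": steps * self.dt,
                             "neuron": nrn.astype(np.int64)})

    def events(self) -> pd.DataFrame:
        """Plasticity-event log (empty if ``record_events`` is off)."""
        if self._event_chunks:
            buf = np.concatenate(self._event_chunks)
        else:
            buf = np.zeros((0, 8))
        df = pd.DataFrame(buf, columns=EVENT_COLUMNS)
        df["synapse"] = df["synapse"].astype(np.int64)
        df["direction"] = df["direction"].astype(np.int64)
        return df

    def trace(self) -> pd.DataFrame:
        """Periodic scalar trace: weight sum, nonzero count, pool sum, alive count."""
        buf = np.concatenate(self._trace_chunks) if self._trace_chunks else np.zeros((0, 5))
        df = pd.DataFrame(buf, columns=["step", "weight_sum", "n_nonzero",
                                        "pool_sum", "n_alive"])
        df = df.drop_duplicates(subset="step", keep="first")
        df.insert(0, "time_ms", df.pop("step") * self.dt)
        with np.errstate(invalid="ignore", divide="ignore"):
            df["mean_nonfilopodia_w"] = np.where(
                df["n_nonzero"] > 0, df["weight_sum"] / df["n_nonzero"], np.nan)
        return df.reset_index(drop=True)

    def snapshots(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(times_ms, weights, pools): periodic full weight/pool snapshots."""
        steps = np.asarray(self._snap_steps, dtype=np.int64)
        w = np.asarray(self._snap_w)
        p = np.asarray(self._snap_pool)
        _, keep = np.unique(steps, return_index=True)
        return steps[keep] * self.dt, w[keep], p[keep]
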