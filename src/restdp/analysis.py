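"""Metrics characterizing learned networks and degeneration compensation.

Firing rates, weight statistics, potentiation efficacy, dendritic spacing of
nonfilopodia spines (synapses with non-zero weight), delay-weighted graph
metrics and survival curves.  All operate on the plain containers produced
by :mod:`restdp.protocols` (DataFrames and NumPy arrays), so they can
equally be applied to externally loaded rasters or weight tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sps
from scipy.sparse.csgraph import dijkstra

from .network import Network

__all__ = ["firing_rates", "potentiation_efficacy", "nonfilopodia_spacing",
           "graph_metrics", "survival_curves", "active_neuron_counts",
           "memory_alive", "weight_histogram"]


def firing_rates(raster: pd.DataFrame, window: float, n_neurons: int,
                 t_stop: float, t_start: float = 0.0) -> pd.DataFrame:
    """Per-neuron firing-rate series: spike counts in consecutive windows
    divided by the window length.

    Parameters are in ms; rates are returned in Hz, one row per window
    (indexed by window-start time) and one column per neuron.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    edges = np.arange(t_start, t_stop + window, window)
    t = raster["time_ms"].to_numpy()
    n = raster["neuron"].to_numpy()
    counts, _, _ = np.histogram2d(
        t, n, bins=[edges, np.arange(n_neurons + 1) - 0.5])
    rates = counts / (window * 1e-3)
    return pd.DataFrame(rates, index=edges[:-1], columns=np.arange(n_neurons))


def potentiation_efficacy(events: pd.DataFrame) -> np.ndarray:
    """Granted potentiation as a percentage of the STDP-window request,
    one value per potentiation event (requests of 0 are excluded)."""
    if events.empty:
        raise ValueError("event log is empty")
    pot = events[(events["direction"] > 0) & (events["requested"] > 0)]
    return 100.0 * pot["granted"].to_numpy() / pot["requested"].to_numpy()


def nonfilopodia_spacing(net: Network, weights: np.ndarray | None = None,
                         alive: np.ndarray | None = None) -> float | None:
    """Mean dendritic nearest-neighbor distance between nonfilopodia spines.

    For every synapse with w > 0, the distance (in position units) to the
    closest other w > 0 synapse on the same dendrite; averaged over spines
    within a neuron, then over neurons with at least two such spines.
    ``None`` when no neuron qualifies.  Pass ``weights`` (and optionally
    ``alive``) to evaluate a snapshot instead of the network's current state.
    """
    w = net.w if weights is None else weights
    al = net.alive if alive is None else alive
    per_neuron = []
    for n in range(net.n_neurons):
        lo, hi = net.aff_ptr[n], net.aff_ptr[n + 1]
        mask = (w[lo:hi] > 0) & al[lo:hi]
        ppos = np.sort(net.pos[lo:hi][mask])
        if ppos.size < 2:
            continue
        gaps = np.diff(ppos)
        nn = np.empty(ppos.size)
        nn[0] = gaps[0]
        nn[-1] = gaps[-1]
        if ppos.size > 2:
            nn[1:-1] = np.minimum(gaps[:-1], gaps[1:])
        per_neuron.append(nn.mean())
    return float(np.mean(per_neuron)) if per_neuron else None


def graph_metrics(net: Network, weight_threshold: float = 0.0,
                  weights: np.ndarray | None = None,
                  alive: np.ndarray | None = None) -> dict:
    """Mean in/out degree and mean delay-weighted in/out closeness of the
    directed graph whose edges are recurrent synapses with w > threshold.

    Closeness of a node is (number of reachable nodes) divided by the sum of
    shortest-path lengths to them, where path length is the summed axonal
    delay in ms; 0 for nodes that reach (or are reached by) nothing.
    Out-closeness follows outgoing edges; in-closeness incoming ones.
    """
    w = net.w if weights is None else weights
    al = net.alive if alive is None else alive
    mask = (w > weight_threshold) & al
    n = net.n_neurons
    delays = net.delay_steps[mask] * net.dt
    g = sps.csr_matrix((delays, (net.src[mask], net.tgt[mask])), shape=(n, n))
    n_edges = int(mask.sum())

    def _closeness(graph):
        d = dijkstra(graph, directed=True)
        np.fill_diagonal(d, np.inf)
        reach = np.isfinite(d)
        cnt = reach.sum(axis=1)
        tot = np.where(reach, d, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.where(cnt > 0, cnt / np.where(tot > 0, tot, np.inf), 0.0)
        return c

    out_c = _closeness(g)
    in_c = _closeness(g.T)
    return {
        "n_edges": n_edges,
        "mean_in_degree": n_edges / n,
        "mean_out_degree": n_edges / n,
        "mean_out_closeness": float(out_c.mean()),
        "mean_in_closeness": float(in_c.mean()),
        "out_closeness": out_c,
        "in_closeness": in_c,
    }


def active_neuron_counts(raster: pd.DataFrame, window: float,
                         t_stop: float) -> pd.Series:
    """Number of distinct neurons spiking in consecutive windows (ms)."""
    edges = np.arange(0.0, t_stop + window, window)
    t = raster["time_ms"].to_numpy()
    n = raster["neuron"].to_numpy()
    idx = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
    counts = [np.unique(n[idx == i]).size for i in range(len(edges) - 1)]
    return pd.Series(counts, index=edges[:-1])


def survival_curves(trace: pd.DataFrame, raster: pd.DataFrame,
                    window: float = 100.0) -> pd.DataFrame:
    """Weight-sum and active-neuron-count traces, each normalized to its own
    maximum (in %), on the trace's time grid."""
    t = trace["time_ms"].to_numpy()
    wsum = trace["weight_sum"].to_numpy()
    w_max = wsum.max()
    w_pct = 100.0 * wsum / w_max if w_max > 0 else np.zeros_like(wsum)
    act = active_neuron_counts(raster, window, t_stop=float(t[-1]) if t.size else window)
    a = np.interp(t, act.index.to_numpy() + window / 2.0, act.to_numpy(),
                  left=act.iloc[0] if len(act) else 0.0,
                  right=act.iloc[-1] if len(act) else 0.0)
    a_max = a.max()
    a_pct = 100.0 * a / a_max if a_max > 0 else np.zeros_like(a)
    return pd.DataFrame({"time_ms": t, "weight_sum_pct": w_pct,
                         "active_neurons_pct": a_pct})


def memory_alive(raster: pd.DataFrame, t: float, quiet_window: float) -> bool:
    """True iff at least one spike occurred in the half-open window
    (t - quiet_window, t]."""
    if t < quiet_window:
        raise ValueError("t must be at least quiet_window")
    times = raster["time_ms"].to_numpy()
    return bool(np.any((times > t - quiet_window) & (times <= t)))


def weight_histogram(net: Network, bins: int | np.ndarray = 50,
                     weights: np.ndarray | None = None,
                     alive: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of alive recurrent weights; mass equals the synapse count."""
    w = net.w if weights is None else weights
    al = net.alive if alive is None else alive
    return np.histogram(w[al], bins=bins)
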