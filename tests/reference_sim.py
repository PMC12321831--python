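"""Brute-force scalar reference simulator used as an independent oracle.

Re-simulates the full model — delayed delivery, refractory LIF dynamics and
the resource-dependent plasticity rule — in plain Python with explicit
per-event bookkeeping (dicts and lists, one pending-arrival record per
spike), independently of the package's compiled kernel and array layout.
Feasible only for a handful of neurons and a few hundred steps, which is
exactly its job.
"""

from __future__ import annotations

import math
from collections import defaultdict


def run_reference(*, n_neurons, dt,
                  syn,  # list of dicts: src, tgt, pos, delay_steps, w
                  pools,  # list of per-neuron pool values
                  in_syn,  # list of dicts: train, tgt, delay_steps, w
                  input_events,  # list of (step, train), sorted by step
                  n_steps,
                  deletions=(),  # list of (step, synapse index), sorted
                  replenish=True,
                  tau_v=25.0, theta=1.0, tau_r=5.0, abs_refractory=3.0,
                  tau_sr=2.6, tau_sf=31.3, impulse_gain=12.0,
                  tau_stdp=20.0, dep_mult=0.18, max_nb=3, tau_pool=10_000.0):
    """Returns (weights, pools, raster, events); raster is [(step, neuron)],
    events are dicts mirroring the package's plasticity-event log."""
    syn = [dict(s) for s in syn]
    pools = list(pools)
    alive = [True] * len(syn)
    # synapse lookup by (target, position) for the neighbor kernel
    at = {(s["tgt"], s["pos"]): j for j, s in enumerate(syn)}
    # afferents of each neuron in ascending dendritic position
    aff = defaultdict(list)
    for j, s in sorted(enumerate(syn), key=lambda t: (t[1]["tgt"], t[1]["pos"])):
        aff[s["tgt"]].append(j)
    eff = defaultdict(list)
    for j, _ in sorted(enumerate(syn), key=lambda t: (t[1]["tgt"], t[1]["pos"])):
        eff[syn[j]["src"]].append(j)
    in_eff = defaultdict(list)
    for i, s in enumerate(in_syn):
        in_eff[s["train"]].append(i)

    v = [0.0] * n_neurons
    r = [1.0] * n_neurons
    refrac = [0] * n_neurons
    last_post = [None] * n_neurons
    sp = [0.0] * n_neurons
    s_cur = [0.0] * n_neurons
    last_arr = [None] * len(syn)
    pending = defaultdict(list)  # arrival step -> [("rec"/"in", index)]
    raster, events = [], []
    abs_steps = int(round(abs_refractory / dt))
    c_v, c_r = dt / tau_v, dt / tau_r
    c_sf, c_sr, c_pool = dt / tau_sf, dt / tau_sr, dt / tau_pool

    ev_i = del_i = 0
    for k in range(n_steps):
        while del_i < len(deletions) and deletions[del_i][0] <= k:
            _, j = deletions[del_i]
            del_i += 1
            if alive[j]:
                alive[j] = False
                if replenish:
                    pools[syn[j]["tgt"]] += syn[j]["w"]
                syn[j]["w"] = 0.0
                last_arr[j] = None
        while ev_i < len(input_events) and input_events[ev_i][0] == k:
            tr = input_events[ev_i][1]
            ev_i += 1
            for i in in_eff[tr]:
                pending[k + in_syn[i]["delay_steps"]].append(("in", i))
        for kind, idx in pending.pop(k, ()):
            if kind == "in":
                s0 = in_syn[idx]
                sp[s0["tgt"]] += impulse_gain * s0["w"]
            else:
                j = idx
                if not alive[j]:
                    continue
                n = syn[j]["tgt"]
                sp[n] += impulse_gain * syn[j]["w"]
                if last_post[n] is not None:
                    tau = (last_post[n] - k) * dt
                    req = dep_mult * math.exp(tau / tau_stdp) * syn[j]["w"]
                    if req > 0.0:
                        moved = min(req, syn[j]["w"])
                        syn[j]["w"] -= moved
                        pools[n] += moved
                        events.append(dict(time_ms=k * dt, synapse=j, tau_ms=tau,
                                           direction=-1, requested=req,
                                           granted=moved, from_neighbors=0.0,
                                           from_pool=moved))
                last_arr[j] = k
        spikes = []
        for n in range(n_neurons):
            s_old, r_old = s_cur[n], r[n]
            if refrac[n] > 0:
                refrac[n] -= 1
                v[n] = 0.0
            else:
                v[n] = v[n] + c_v * (-v[n] + r_old * s_old)
                if v[n] >= theta:
                    spikes.append(n)
            r[n] = r_old + c_r * (1.0 - r_old)
            s_cur[n] = s_old + c_sf * (sp[n] - s_old)
            sp[n] -= sp[n] * c_sr
            loss = pools[n] * c_pool
            pools[n] -= loss
        for n in spikes:
            v[n] = 0.0
            refrac[n] = abs_steps
            r[n] = 0.0
            last_post[n] = k
            raster.append((k, n))
            for j in eff[n]:
                if alive[j]:
                    pending[k + syn[j]["delay_steps"]].append(("rec", j))
            for j in aff[n]:
                if not alive[j] or last_arr[j] is None:
                    continue
                tau = (k - last_arr[j]) * dt
                req = math.exp(-tau / tau_stdp)
                if req <= 0.0:
                    continue
                total = 0.0
                nbs = []
                for kk in range(1, max_nb + 1):
                    for sgn in (-1, 1):
                        nb = at.get((n, syn[j]["pos"] + sgn * kk))
                        if nb is not None and alive[nb]:
                            total += math.exp(-kk)
                            nbs.append((kk, nb))
                from_nb = 0.0
                if total > 0.0:
                    for kk, nb in nbs:
                        supply = min(req * (math.exp(-kk) / total), syn[nb]["w"])
                        syn[nb]["w"] -= supply
                        from_nb += supply
                shortfall = max(req - from_nb, 0.0)
                from_pool = min(shortfall, pools[n])
                pools[n] -= from_pool
                granted = from_nb + from_pool
                syn[j]["w"] += granted
                events.append(dict(time_ms=k * dt, synapse=j, tau_ms=tau,
                                   direction=1, requested=req, granted=granted,
                                   from_neighbors=from_nb, from_pool=from_pool))
    return [s["w"] for s in syn], pools, raster, events
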