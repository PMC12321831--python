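"""Numba-compiled inner loop of the closed-loop simulator.

One call advances the network over ``[k_start, k_stop)`` forward-Euler steps,
mutating the state arrays in place.  The function returns early (with a
status code) when an output buffer is close to full so the Python wrapper
can flush and resume; all loop state lives in the passed arrays, which makes
the kernel re-entrant.

Arithmetic here mirrors :mod:`restdp.plasticity` operation for operation and
in the same floating-point order, so the compiled path and the pure-Python
reference path produce bit-identical weights.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

#: status codes returned by :func:`run_window`
DONE = 0
EVENTS_FULL = 1
RASTER_FULL = 2
NONFINITE = 3


@njit(cache=True)
def run_window(k_start, k_stop,
               dt, theta, abs_steps,
               c_v, c_r, c_sf, c_sr, c_pool, c_inj,
               tau_stdp, dep_mult, max_nb,
               tgt, delay_steps, w, alive,
               aff_ptr, eff_ptr, eff_syn,
               in_tgt, in_delay_steps, in_w, in_eff_ptr, in_eff_syn,
               v, r, refrac, last_post, pool, sp, s, last_arr,
               rb, rb_cnt,
               ev_step, ev_train, ev_ptr,
               del_step, del_syn, del_ptr, replenish,
               raster_step, raster_neuron, raster_cnt,
               log_on, ev_buf, ev_cnt,
               trace_every, trace_buf, trace_cnt,
               wsnap_every, wsnap_w, wsnap_pool, wsnap_cnt,
               acc, spike_scratch):
    M = w.size
    Mi = in_w.size
    H = rb.shape[0]
    N = v.size
    for k in range(k_start, k_stop):
        # chunk-boundary checks, before any side effect of step k
        if log_on and ev_cnt[0] + (2 * M + Mi) > ev_buf.shape[0]:
            return k, EVENTS_FULL
        if raster_cnt[0] + N > raster_step.size:
            return k, RASTER_FULL

        # record the state entering step k
        if trace_every > 0 and k % trace_every == 0:
            sw = 0.0
            nz = 0
            na = 0
            for j in range(M):
                if alive[j]:
                    na += 1
                    sw += w[j]
                    if w[j] > 0.0:
                        nz += 1
            pt = 0.0
            for n in range(N):
                pt += pool[n]
            if not math.isfinite(sw + pt):
                return k, NONFINITE
            i = trace_cnt[0]
            trace_buf[i, 0] = k
            trace_buf[i, 1] = sw
            trace_buf[i, 2] = nz
            trace_buf[i, 3] = pt
            trace_buf[i, 4] = na
            trace_cnt[0] = i + 1
        if wsnap_every > 0 and k % wsnap_every == 0:
            i = wsnap_cnt[0]
            wsnap_w[i, :] = w
            wsnap_pool[i, :] = pool
            wsnap_cnt[0] = i + 1

        # scheduled synapse deletions (degeneration protocol)
        while del_ptr[0] < del_step.size and del_step[del_ptr[0]] <= k:
            j = del_syn[del_ptr[0]]
            del_ptr[0] += 1
            if alive[j]:
                alive[j] = False
                if replenish:
                    pool[tgt[j]] += w[j]
                else:
                    acc[1] += w[j]
                w[j] = 0.0
                last_arr[j] = -1

        # input-train spikes emitted this step -> enqueue delayed arrivals
        while ev_ptr[0] < ev_step.size and ev_step[ev_ptr[0]] == k:
            tr = ev_train[ev_ptr[0]]
            ev_ptr[0] += 1
            for ii in range(in_eff_ptr[tr], in_eff_ptr[tr + 1]):
                i = in_eff_syn[ii]
                slot = (k + in_delay_steps[i]) % H
                rb[slot, rb_cnt[slot]] = M + i
                rb_cnt[slot] += 1

        # deliver arrivals due at step k
        slot = k % H
        for a in range(rb_cnt[slot]):
            sid = rb[slot, a]
            if sid >= M:  # static input synapse
                i = sid - M
                sp[in_tgt[i]] += c_inj * in_w[i]
            else:  # plastic recurrent synapse
                j = sid
                if not alive[j]:
                    continue
                n = tgt[j]
                sp[n] += c_inj * w[j]
                # pre-after-post pairing: depression, resources -> pool
                if last_post[n] >= 0:
                    tau = (last_post[n] - k) * dt
                    req = dep_mult * math.exp(tau / tau_stdp) * w[j]
                    if req > 0.0:
                        moved = min(req, w[j])
                        w[j] -= moved
                        pool[n] += moved
                        if log_on:
                            e = ev_cnt[0]
                            ev_buf[e, 0] = k * dt
                            ev_buf[e, 1] = j
                            ev_buf[e, 2] = tau
                            ev_buf[e, 3] = -1.0
                            ev_buf[e, 4] = req
                            ev_buf[e, 5] = moved
                            ev_buf[e, 6] = 0.0
                            ev_buf[e, 7] = moved
                            ev_cnt[0] = e + 1
                last_arr[j] = k
        rb_cnt[slot] = 0

        # forward-Euler update of membrane, refractory gain, currents, pools
        nspk = 0
        for n in range(N):
            s_old = s[n]
            r_old = r[n]
            if refrac[n] > 0:
                refrac[n] -= 1
                v[n] = 0.0
            else:
                vn = v[n] + c_v * (-v[n] + r_old * s_old)
                v[n] = vn
                if vn >= theta:
                    spike_scratch[nspk] = n
                    nspk += 1
            r[n] = r_old + c_r * (1.0 - r_old)
            s[n] = s_old + c_sf * (sp[n] - s_old)
            sp[n] -= sp[n] * c_sr
            loss = pool[n] * c_pool
            pool[n] -= loss
            acc[0] += loss

        # spike handling: reset, raster, delayed delivery, potentiation
        for qn in range(nspk):
            n = spike_scratch[qn]
            v[n] = 0.0
            refrac[n] = abs_steps
            r[n] = 0.0
            last_post[n] = k
            rc = raster_cnt[0]
            raster_step[rc] = k
            raster_neuron[rc] = n
            raster_cnt[0] = rc + 1
            for jj in range(eff_ptr[n], eff_ptr[n + 1]):
                j = eff_syn[jj]
                if alive[j]:
                    slot2 = (k + delay_steps[j]) % H
                    rb[slot2, rb_cnt[slot2]] = j
                    rb_cnt[slot2] += 1
            # potentiate afferents in ascending dendritic position
            base = aff_ptr[n]
            m = aff_ptr[n + 1] - base
            for q in range(m):
                j = base + q
                if not alive[j] or last_arr[j] < 0:
                    continue
                tau = (k - last_arr[j]) * dt
                req = math.exp(-tau / tau_stdp)
                if req <= 0.0:
                    continue
                # exponential kernel over existing neighbors, renormalized
                total = 0.0
                for kk in range(1, max_nb + 1):
                    for sgn in (-1, 1):
                        q2 = q + sgn * kk
                        if 0 <= q2 < m and alive[base + q2]:
                            total += math.exp(-kk)
                from_nb = 0.0
                if total > 0.0:
                    for kk in range(1, max_nb + 1):
                        for sgn in (-1, 1):
                            q2 = q + sgn * kk
                            if 0 <= q2 < m and alive[base + q2]:
                                nb = base + q2
                                supply = min(req * (math.exp(-kk) / total), w[nb])
                                w[nb] -= supply
                                from_nb += supply
                shortfall = max(req - from_nb, 0.0)
                from_pool = min(shortfall, pool[n])
                pool[n] -= from_pool
                granted = from_nb + from_pool
                w[j] += granted
                if log_on:
                    e = ev_cnt[0]
                    ev_buf[e, 0] = k * dt
                    ev_buf[e, 1] = j
                    ev_buf[e, 2] = tau
                    ev_buf[e, 3] = 1.0
                    ev_buf[e, 4] = req
                    ev_buf[e, 5] = granted
                    ev_buf[e, 6] = from_nb
                    ev_buf[e, 7] = from_pool
                    ev_cnt[0] = e + 1
    return k_stop, DONE
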