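"""Minimal (unstyled) plots of a learning run: raster, weight histogram,
weight/pool traces.  Writes PNGs into ./plots/.

Requires matplotlib (`pip install restdp[plot]`).
"""

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from restdp import NetworkParams
from restdp.protocols import ProtocolConfig, run_learning

out = Path("plots")
out.mkdir(exist_ok=True)

cfg = ProtocolConfig(rng_seed=7, input_duration=5000.0, total_duration=10_000.0,
                     degeneration_start=10_000.0)
res = run_learning(cfg, net_params=NetworkParams(n_exc=60, n_in=20),
                   record_events=False)

fig, ax = plt.subplots()
ax.plot(res.raster.time_ms / 1000, res.raster.neuron, ".", ms=1)
ax.axvline(5.0, ls="--")
ax.set(xlabel="time (s)", ylabel="neuron", title="spike raster (input off at 5 s)")
fig.savefig(out / "raster.png", dpi=120)

fig, ax = plt.subplots()
ax.hist(res.network.w[res.network.alive], bins=50)
ax.set(xlabel="weight", ylabel="synapses", yscale="log",
       title="final weights: silent-synapse peak + long tail")
fig.savefig(out / "weights.png", dpi=120)

fig, ax = plt.subplots()
t = res.trace.time_ms / 1000
ax.plot(t, res.trace.weight_sum, label="sum of weights")
ax.plot(t, res.trace.pool_sum, label="sum of pools")
ax.set(xlabel="time (s)", ylabel="resource units")
ax.legend()
fig.savefig(out / "resources.png", dpi=120)
print(f"wrote {len(list(out.glob('*.png')))} figures to {out}/")
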