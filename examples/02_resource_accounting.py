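"""Resource conservation in single plasticity events.

Uses the `dendrite6` fixture (one neuron, seven afferent synapses on one
dendrite) to walk through the funding scenarios of the rule: ample
neighbors, silent neighbors with a pool fallback, partial grants when
everything is scarce, and depression relocating resources into the pool.
"""

import numpy as np

from restdp import depress, make_fixture, potentiate

CENTER = 3


def show(net, label):
    w = ", ".join(f"{x:.3f}" for x in net.w)
    print(f"  {label}: w = [{w}], pool = {net.pool[7]:.3f}, "
          f"total = {net.w.sum() + net.pool[7]:.12f}")


net = make_fixture("dendrite6").network
net.w[:] = 1.0
net.pool[7] = 2.0
j = int(net.aff_ptr[7] + CENTER)
print("Ample neighbors fund the whole request (pool untouched):")
show(net, "before")
ev = potentiate(net, 7, j, 0.6)
show(net, "after ")
print(f"  requested {ev.requested:.3f}, granted {ev.granted:.3f} "
      f"({ev.from_neighbors:.3f} from neighbors, {ev.from_pool:.3f} from pool)\n")

net = make_fixture("dendrite6").network
net.w[:] = 0.0  # an entirely silent dendrite
net.pool[7] = 0.4
j = int(net.aff_ptr[7] + CENTER)
print("Silent neighbors, depleted pool: the grant is capped and the pool zeroed:")
show(net, "before")
ev = potentiate(net, 7, j, 1.0)
show(net, "after ")
print(f"  requested {ev.requested:.3f}, granted {ev.granted:.3f} "
      f"-> potentiation efficacy {100 * ev.granted / ev.requested:.0f} %\n")

print("Depression relocates resources into the pool (nothing is lost):")
show(net, "before")
ev = depress(net, 7, j, 0.25)
show(net, "after ")
print(f"  moved {ev.granted:.3f} from the synapse into the pool")
print("\nEvery event leaves sum(w) + pool unchanged; the only sink is the")
print("pool's slow exponential decay (tau_p = 10 s) between events.")
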