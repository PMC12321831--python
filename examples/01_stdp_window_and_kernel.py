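"""The STDP window and the heterosynaptic distance kernel, by the numbers.

Evaluates the pair-based learning window f(tau) — exponential potentiation
for causal pairs (tau >= 0), weight-dependent depression scaled by 0.18 for
acausal ones — and the exponential distance kernel that decides how much of
a potentiation request each dendritic neighbor funds.
"""

from restdp import neighbor_share, stdp_window

print("STDP window (tau_stdp = 20 ms):")
for tau in (0.0, 10.0, 20.0, 40.0):
    print(f"  tau = {tau:+6.1f} ms -> requested potentiation {stdp_window(tau, 1.0):.5f}")
for tau in (-10.0, -20.0):
    for w in (1.0, 0.5, 0.0):
        print(f"  tau = {tau:+6.1f} ms, w = {w:.1f} -> requested depression "
              f"{stdp_window(tau, w):.5f}")

print("\nHeterosynaptic neighbor shares (sum over all six = 1):")
total = 0.0
for k in (1, 2, 3):
    s = neighbor_share(k)
    total += 2 * s
    print(f"  distance +-{k}: share {s:.5f} each")
print(f"  total {total:.12f}")
print("\nA potentiation request is funded neighbors-first by these shares,")
print("capped at each neighbor's weight; any shortfall comes from the pool.")
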