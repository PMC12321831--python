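# restdp — resource-dependent heterosynaptic STDP in recurrent spiking networks

`restdp` simulates learning in a recurrent network of leaky integrate-and-fire
neurons whose synapses obey a *resource-conserving* variant of spike-timing-
dependent plasticity (STDP).  It is written for computational neuroscientists
who want to study how a purely local resource economy — rather than global
weight normalization or an imposed weight cap — can stabilize Hebbian learning,
produce realistic synaptic weight statistics (a silent-synapse peak with a
long-tailed distribution, non-potentiable synapses, spatially dispersed
spines), and endow an innate compensatory response to progressive synaptic
degeneration of the kind seen in neurodegenerative disease.

## The model

Membrane potentials (threshold units, θ = 1) follow

    τ_v dv_n/dt = −v_n + r_n (Σ_i s_i + Σ_j s_j),     v_n → 0 if v_n ≥ θ,

with τ_v = 25 ms, a 3 ms absolute refractory period, and a relative
refractory gain r_n that resets to 0 at a spike and recovers with
τ_r = 5 ms (τ_r dr_n/dt = 1 − r_n).  Synaptic currents are double
exponentials (τ_sr = 2.6 ms rise, τ_sf = 31.3 ms fall) driven by delayed
presynaptic spikes scaled by the weight w.  Axonal delays are uniform on
[1, 5] ms; integration is forward Euler at dt = 0.1 ms.

A spike pair with lag τ = t_post − t_pre requests a weight change

    f(τ) = exp(−τ/τ_STDP)             τ ≥ 0   (potentiation)
    f(τ) = 0.18 · exp(τ/τ_STDP) · w   τ < 0   (depression)

with τ_STDP = 20 ms.  What makes the rule different is that potentiation
must be *funded*: the request is drawn first from the weights of dendritic
neighbors (positions ±1..3, shares ∝ e^−k, normalized to 1 — heterosynaptic
depression), then from a per-neuron resource pool p_n that is log-normally
initialized (p_n = 2 e^ξ, ξ ~ N(0,1)) and decays with τ_p = 10 s.  Each
supplier is capped at what it holds, so grants can fall short of requests
("potentiation efficacy" < 100 %).  Depression relocates weight into the
pool instead of destroying it.  Every plasticity event exactly conserves
Σw + p on the neuron; the pool's slow decay is the only resource sink.

Two experiments are built in: **learning** (200 neurons, 50 Hz Poisson input
from 50 trains for 20 s, then free running — a subset of neurons keeps
firing, a learned memory) and **degeneration** (from 40 s, surviving
recurrent synapses are deleted one by one at random; deleted resources
either replenish the pool or are discarded).

## A worked example

```bash
python examples/03_learning_small_network.py
```

```
synapses: 835 recurrent, 99 input
during stimulation: 41 of 60 neurons fire (100.1 Hz network mean)
after stimulation (last 1 s): 37 neurons still fire (the learned, self-sustained memory)

weights: 639 exactly silent of 835 (77 % — the silent-synapse peak)
nonzero weights: median 0.215, max 11.309 (unimodal with a long tail)

potentiation efficacy: 9 % of events fully granted; 4 % granted (almost) nothing ...
nonzero-weight graph: mean in-degree 3.27, mean delay-weighted out-closeness 0.0984 /ms
```

Stimulation drives most of the small network; after the input stops a
self-sustained assembly remains.  Three quarters of the synapses hold
exactly zero resources (silent), the rest form a long-tailed distribution,
and many potentiation events were only partially granted — each synapse runs
into its own resource-set ceiling.  `examples/04_degeneration_compensation.py`
continues into the degeneration experiment:

```
with replenishment   : activity ceased at t = 36.5 s, with 11.7 % of connections remaining; mean surviving weight rose x3.45 during deletion
without replenishment: activity ceased at t = 25.0 s, with 50.1 % of connections remaining; mean surviving weight rose x1.38 during deletion
```

The other examples print the STDP window/kernel values and the per-event
resource accounting; `examples/plot_learning.py` makes minimal figures.

The same experiments are available from the shell:

```bash
restdp simulate   --seed 1 --out runs/learn                 # learning protocol
restdp degenerate --seed 1 --no-replenish --out runs/deg    # degeneration protocol
restdp analyze    --run runs/learn                          # metrics from a saved run
```

Every run writes a `manifest.json` (config + seed + version) that reproduces
it bit-identically.

## Layout

- `src/restdp/network.py` — topology, delays, pools (`build_network`)
- `src/restdp/plasticity.py` — the rule itself, as pure-Python reference ops
- `src/restdp/dynamics.py` + `_kernels.py` — the compiled closed-loop simulator
- `src/restdp/protocols.py` — learning and degeneration experiments
- `src/restdp/analysis.py` — rates, efficacy, spacing, graph metrics, survival
- `src/restdp/config.py`, `cli.py`, `fixtures.py` — YAML config, CLI, fixtures
- `docs/methods.md` — modeling choices, defaults, and limitations
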