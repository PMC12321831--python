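# Methods

## Model overview

The simulated system is a recurrent pool of N_exc = 200 excitatory,
refractory leaky integrate-and-fire neurons.  Ordered neuron pairs are
connected independently with probability 0.25 by *plastic* synapses whose
weights start at exactly 0 (a newly formed network of silent synapses /
filopodia).  N_in = 50 independent Poisson spike trains project onto the
pool with probability 0.10 through *static* synapses with weights drawn
uniformly from (0, 1).  All connections carry axonal delays drawn uniformly
from [1, 5] ms and rounded to the integration grid.  There is no inhibition
and no structural spinogenesis; activity is shaped entirely by excitation,
refractoriness, and the resource economy of the learning rule.

Integration is forward Euler with dt = 0.1 ms throughout.  All tunable
parameters, with units and defaults:

| parameter | default | meaning |
|---|---|---|
| τ_v | 25 ms | membrane time constant (threshold θ = 1, reset to 0) |
| abs. refractory | 3 ms | v clamped at 0, threshold disabled; currents still integrate |
| τ_r | 5 ms | recovery of the relative-refractory gain r ∈ [0, 1]; r → 0 at a spike |
| τ_sr, τ_sf | 2.6 ms, 31.3 ms | rise/fall of the double-exponential synaptic current |
| impulse_gain | 12 | increment of the current rise variable per arrival, in units of w (see below) |
| τ_STDP | 20 ms | STDP window time constant |
| depression multiple | 0.18 | scaling of (weight-dependent) depression |
| neighbor distance | 3 | heterosynaptic kernel reach, in dendritic positions |
| pool scale | 2 | median of the log-normal pool init p = 2 e^ξ |
| τ_p | 10 s | resource-pool decay |
| input | 50 Hz, 20 s | Poisson stimulation rate and duration |

## The plasticity rule and its bookkeeping

Pairing is *nearest-spike with reuse*.  Each recurrent synapse remembers the
time its last presynaptic spike arrived (arrival = emission + axonal delay;
plasticity is local to the synapse, so τ uses arrival time, not emission
time).  When an arrival finds an earlier postsynaptic spike it triggers
depression against that most recent spike (τ < 0); when the neuron fires,
*every* afferent with a recorded arrival is potentiated with
τ = t_post − t_arrival ≥ 0.  Simultaneous arrival and spike (τ = 0) counts
as potentiation.  A recorded arrival is not consumed by pairing: it keeps
pairing with later postsynaptic spikes at exponentially decaying amplitude.

Potentiation is funded in two stages, applied per event:

1. **Neighbors.** Existing synapses at dendritic positions ±1..3 contribute
   `request · share(k)` each, capped at their current weight, with
   `share(k) ∝ e^−k` normalized so all *existing* neighbors sum to 1.  At
   dendrite edges and across deletion gaps the kernel is renormalized over
   the neighbors that remain, so neighbor-funded potentiation stays exactly
   resource-conserving.  A neighbor drained to its cap ends at exactly 0.
2. **Pool.** Any shortfall is drawn from the neuron's pool, capped at the
   pool level (which can end at exactly 0).  If both stages come up empty
   the grant is 0 and the synapse stays silent.

Depression moves `min(request, w)` from the synapse into the pool.  Resource
transfers are instantaneous within a time step; the pool decays
exponentially between events.  Consequently Σw + p on a neuron is conserved
by every event to machine precision, and over a whole simulation the initial
resources equal the final resources plus the integrated pool decay (plus
discarded deleted weight, when replenishment is blocked) — both identities
are asserted in the test suite, which also pins the compiled kernel
bit-for-bit against a brute-force scalar re-simulation.

Within a step the order is: scheduled deletions → input-spike enqueue →
delivery of due arrivals (current injection with the pre-depression weight,
then the depression pairing) → Euler update of all states → threshold test →
spike handling (reset, delayed delivery, potentiation of afferents in
ascending dendritic position, neurons in ascending index).  Ordering matters
only when resources are scarce; it is deterministic and seed-stable.
Dendritic positions are assigned in ascending presynaptic-source order by
default (a seeded random permutation is available) — the layout is a free
choice of the model, as only distances enter the rule.

## Excitability calibration (impulse_gain)

The synaptic drive equation τ_sr ds′/dt = −s′ + g·I·w treats presynaptic
spikes as events on the Euler grid.  Read literally with a binary per-step
indicator I, an arrival increments s′ by w·dt/τ_sr ≈ 0.04 w, which injects
so little charge that the default network never reaches threshold at all
(mean drive ~10⁻³ of θ).  The package therefore parametrizes the injection
directly as `impulse_gain`: the per-arrival increment of s′ in units of w,
independent of dt (a delta-impulse convention).  Its default, 12, was
calibrated the same way the model's resource scale was originally set: it is
the smallest scanned value at which stimulation-driven learning left a
persistently firing assembly after input offset in all ten calibration seeds
(3/10 at gain 5, 9/10 at 10, 10/10 at 12).  All other constants are the
model's published values and were not adjusted.

## Protocols

**Learning** (default 40 s): 50 Hz Poisson input for the first 20 s, then
free running.  With the defaults, most neurons fire during stimulation
(network mean ≈ 30–50 Hz, individual rates beyond 100 Hz) and an assembly of
roughly 100–160 neurons keeps firing afterwards — the learned memory.

**Degeneration** (default 100 s): after 40 s, surviving recurrent synapses
are deleted one at a time, uniformly at random, at a constant interval
chosen so every synapse would be deleted by the end of the run (≈ 6 ms for
the default network; the interval and the schedule are config-exposed).  The
deletion permutation comes from its own seed substream, so replenish-on/off
runs with the same protocol seed delete the same synapses at the same times.
Input synapses are never deleted.  Deleted positions leave gaps: neighbor
distances grow, positions are not re-packed.

Activity cessation is detected as the first moment with no network spike for
500 ms (config-exposed; far beyond the largest delay plus synaptic decay),
and the surviving-connection fraction is read off at that moment.  The
"time for the weight-sum trace to reach zero" is operationalized as the
trace (as % of its maximum) first dropping below 1 % — below that the curve
is indistinguishable from zero at the trace's resolution, while tiny
residues of multiplicative depression would otherwise never reach exact 0.

## Synthetic inputs and what the tests show

All inputs are generated internally: Bernoulli-thinned Poisson trains
(p = rate·dt per step), random topology, log-normal pools.  The generator
reproduces the *protocol* of the modeled experiments, not biological
recordings: there are no input correlations, no inhibitory circuit, no
neuromodulation, and deletion is uniformly random rather than activity- or
region-dependent.  Passing tests therefore demonstrate the claimed
properties of the learning rule under its stated conditions — conservation,
silent-synapse statistics, memory persistence, degeneration compensation —
and not quantitative agreement with any biological dataset.

## Numerical choices

- Forward Euler at dt = 0.1 ms; the linear subsystems are also verified
  against closed forms at dt = 0.01 ms (errors shrink ~10×).
- Spikes are timestamped at the step whose update crossed threshold; ties
  (v = θ exactly) spike.
- The simulator integrates per-neuron *sums* of s′ and s (all synapses share
  time constants, so the sum obeys the same ODE); per-synapse currents are
  never needed by the model equations.
- Event logs, rasters and traces stream through pre-sized buffers; the
  compiled kernel is re-entrant, so runs of any length use bounded memory.
- Neighbor shares can overshoot a request by a few ulps when summed; the
  pool draw clamps the shortfall at 0 so grants never exceed requests by
  more than rounding noise, and conservation is exact by construction.

## Known limitations and sensitivity

- **Pairing-with-reuse spreads resources.**  Because every postsynaptic
  spike re-potentiates all previously active afferents, small pool grants
  reach many co-active synapses early in learning.  At full scale this
  yields ≈ 1400 nonzero recurrent synapses (mean degree ≈ 8) rather than a
  sparser graph; a pairing scheme that consumes arrivals would concentrate
  resources further.  The choice is deliberate (it follows the rule's
  stated event semantics) but the degree of sparsity is sensitive to it.
- **The deletion schedule shapes survival measures.**  With the default
  constant-interval schedule the weight-sum trace in *both* replenishment
  conditions persists until the last nonzero synapses are deleted, so the
  paired time-to-zero ratio is ≈ 1 even though the with-replenishment
  network stays *active* to a ~3× smaller surviving fraction and grows its
  surviving weights ~2× during deletion.  Schedules that delete a fixed
  fraction of survivors per interval would separate the curves further; the
  schedule is config-exposed.
- No inhibition means stability rests entirely on refractoriness and the
  resource economy; very large `impulse_gain` values saturate the network at
  the refractory-limited rate.
- Heterosynaptic interactions use integer dendritic positions on a 1-D
  dendrite; no diffusion time constants, no multi-compartment structure, no
  molecular identities.
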