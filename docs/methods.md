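# Methods

## Model

### Neuron dynamics

Each neuron follows the two-variable quadratic model

    v' = 0.04 v^2 + 5 v + 140 - u + I        (mV, ms)
    u' = a (b v - u)

with after-spike resetting `v <- c`, `u <- u + d` at the +30 mV peak cutoff.
Presets: RS (a=0.02, b=0.2, c=-65, d=8) for the 80% excitatory pyramidal
population; FS (a=0.1, b=0.2, c=-65, d=2) for the 20% fast-spiking
interneurons. With b=0.2 both have an exact resting point at v=-70,
u=-14, and an unstable threshold branch near -55 mV. Integration uses a
1 ms global step with two 0.5 ms substeps for `v` and one Euler step for
`u`; synaptic input is applied inside the derivative over its arrival
millisecond. Under this scheme a summed input of 16 mV (two maximal
synapses) leaves a resting RS neuron subthreshold while 24 mV (three)
fires it — the network's basic coincidence requirement. State is
initialized at the exact resting point.

### Connectivity and synaptic drive

1000 neurons, each ordered pair connected independently with probability
0.1; excitatory delays uniform integer 1–20 ms, inhibitory 1 ms. Delay
bookkeeping is exact integer arithmetic (a ring buffer of per-millisecond
delivery lists), so delivery time − emission time always equals the synapse
delay. Weights: plastic E→E in [0, 8] mV; E→I fixed at 8 mV; I→* fixed at
−30 mV. The strong inhibitory weight is a deliberate stabilization choice:
with weaker inhibition the recurrent excitatory coincidence structure makes
the cue-triggered elevated state self-sustaining network-wide (an
epileptic-like regime), while −30 mV clamps disordered elevated activity
yet spares the engineered groups' coherent waves, whose members receive
several coincident strong inputs at once.

Two initial-weight presets exist. `mature` emulates an STDP-shaped network:
each E→E weight is at the 8 mV ceiling with probability 0.25, else at a
1 mV floor (an all-at-ceiling network is epileptic; a plasticity-evolved
weight distribution is bimodal). `growth` draws weak random weights
(uniform on [0, 1] mV) and is the base for inserted-group experiments,
where the engineered synapses supply the only strong E→E structure.

### Background drive (minis)

Every neuron receives independent Poisson "minis": somatic current pulses
of 12 mV at 7.2 events/s. A single mini is subthreshold (it leaves the
membrane hovering a few mV below threshold for some milliseconds); pairs
within a couple of milliseconds fire. The pair (rate, amplitude) was
calibrated once so the mature network's background excitatory multiunit
rate is ~0.30 Hz; `calibrate_minis` re-derives the rate for other
configurations. The fluctuation regime matters beyond the mean rate: a
recent mini plus a single facilitated strong arrival is suprathreshold,
which is the main ignition channel for spontaneous group reactivations.

### Plasticity

All timing rules act on presynaptic **arrival** times (emission + delay).
Long-term STDP: Δw = A₊ e^(−Δt/τ₊) (arrival before postsynaptic spike) or
−A₋ e^(−Δt/τ₋); A₊=0.1, A₋=0.12, τ₊=τ₋=20 ms, w ∈ [0, 8] mV, all-pairs via
exponential traces (nearest-neighbor available as an option). A
neuromodulator schedule multiplies the rates (default elevated gain 5).
Long-term STDP is off by default in working-memory trials and on in
novel-cue experiments.

Short-term STDP applies the same window to a per-synapse scaling `sd`
(effective weight `w (1 + sd)`), ceiling +1 (a +100% transmission gain,
reached by ten optimally timed pre-then-post pairs at s₊=0.1), floor −0.5,
relaxing to 0 with τ_sd = 5 s. The depression magnitude is s₋ = 0.2 —
deliberately about twice the potentiation. Ordered replay (arrival a few ms
before the spike) still nets strong potentiation, but temporally disordered
activity nets depression; this asymmetry is what keeps a maintained group
from gradually entraining the other groups it shares neurons with. At the
symmetric magnitudes of the long-term rule the maintained state spread
epidemically through the overlapping group battery.

NMDA mode: per-synapse activation `g` (+1 per arrival, τ=250 ms decay) with
a hysteretic up-state — entered when `g > 1.9` coincident with a
postsynaptic spike (three arrivals anywhere within the 250 ms window exceed
the threshold), left when `g < 0.475`, transmission ×10 while up. The
compartment demo integrates a passive dendrite with AMPA and NMDA
conductances; the magnesium-block nonlinearity B(V) is piecewise linear
(0 at/below −60 mV, 1 at/above 0 mV), which makes the compartment cleanly
bistable: presynaptic input alone yields small EPSPs, pre-then-post pairing
latches a plateau. The maximal NMDA conductance is pinned by the 9:1
NMDA:AMPA current ratio at full depolarization.

## Engineered groups

`insert_pngs` wires 100 groups of 40 excitatory members spanning 200 ms:
three anchors fire simultaneously, and each later member receives three
synapses from its most recent predecessors whose delays make the arrivals
coincide 3 ms before its scheduled firing time (3 ms is the measured
integrate-to-spike lag at ~3 coincident maximal EPSPs; without this
correction the designed and realized chain times drift apart link by link
and cascades die), plus `redundancy` extra near-coincident synapses with
delays capped at 20 ms for noise robustness. Inserted weights default to
w_max. Templates are realized by a structural probe — a noise-free cascade
with only the group's own synapses active, facilitated, and inhibition
silent — so each template is exactly the group's own 40-neuron pattern.

Discovery (`find_pngs`) enumerates, per target neuron, sets of three strong
(≥95% of w_max) excitatory afferents, fires the anchors so their spikes
arrive simultaneously, and keeps noise-free cascades reaching `min_size`
distinct neurons; near-identical templates (≥90% of events coinciding
within ±1 ms after the best shift) are deduplicated. The search is bounded
by a per-target combination cap and an overall group cap: full enumeration
over an evolved 1000-neuron network is a cluster-scale computation, and the
statistics obtained under a desk-scale budget (hundreds of mostly small
groups) undercount the evolved network's thousands.

Detection aligns candidate onsets at every spike of a template's earliest
20% of neurons and reports an activation when strictly more than 25% of
members spike within ±5 ms of their expected times; overlapping candidates
are merged to the best-matching onset. Time-inverted rasters serve as the
significance surrogate.

## Working-memory experiments

A cue presents the first 80% of the template's pattern ten times within
1 s (pattern starts every 100 ms) as suprathreshold current injections,
each injection kept with `response_probability`. After the cue the group's
`sd` sits around 0.5 and the trial dynamics are self-sustaining: minis
ignite partial replays (~several per second), each replay re-potentiates
the group, and the intra-group multiunit rate stays near 4 Hz for tens of
seconds (median last reactivation ≈ 18 s across seeds at the default
conditions). Erasure suppresses short-term increments from a chosen time
(the neuromodulator schedule with short-term gain 0), after which `sd`
relaxes with τ_sd and reactivations cease. Neuromodulator cueing (gain 5)
reaches maintenance with a single presentation, which fails at gain 1.

The standard preparation is 100 groups over the 760 non-anchor excitatory
neurons, i.e. each neuron belongs to ~5 groups. Cued-group maintenance is
selective in detections (cued template detected ≥5× any non-cued one) and
in `sd` (background synapses do not potentiate), but the non-member
excitatory rate during maintenance rises to ~2–3 Hz rather than staying at
the 0.3 Hz background: partial entrainment of overlapping groups through
shared members is a known limitation of the homogeneous engineered battery
(the published evolved network, with its diverse weights and delays, is
reported not to show it). The NMDA mechanism yields cue-evoked patterned
reactivations (single-group preparation, inserted weight 1.7 mV so that the
10× up-state sits at the single-arrival firing threshold), but its 250 ms
memory constant keeps maintenance much shorter-lived than the 5 s
short-term STDP trace; ten-second maintenance is only achieved with the
STDP mechanism.

The novel-cue experiment presents a random 60-neuron pattern (spread over
100 ms, ten times within 1 s, every 15 s for 90 s) with both plasticity
rules active on the mature network. A template forms — the pattern recruits
~25–50 non-stimulated neurons with delay-compatible convergent strong
inputs, identified by probing the evolved weights with the cue pattern —
and is detected at every presentation. Spontaneous between-presentation
replay of the new group, however, requires delay-matched convergent chains
among the stimulated/recruited set, which a random-delay network of this
size essentially lacks (~0.2 matched convergent afferents per stimulated
member against the ≥3 needed); the measured spontaneous reactivation rate
is therefore ~0 at this scale.

## Numerical and design notes

* All times live on the 1 ms grid; sub-millisecond jitter is not modeled.
* Simultaneous arrival and postsynaptic spike (Δt = 0) counts as
  potentiation (arrival-before-fire reading); within a step, deliveries are
  processed before spikes, so the tie is resolved structurally.
* Lazy exponential decay: per-synapse traces store a last-touch time and
  decay on access, keeping the per-millisecond cost proportional to spike
  traffic, not synapse count. Runs are bit-for-bit reproducible for a given
  seed; one generator drives minis and stimulus subsampling.
* Default analysis bins: 100 ms for rate curves, 1 ms for
  cross-correlograms (±50 ms window); ISI statistics over the first 20 s
  after cue offset. CV is std(ISI)/mean(ISI); CV2 averages
  2|ISIᵢ₊₁−ISIᵢ|/(ISIᵢ₊₁+ISIᵢ) and is robust to the nonstationarity that
  inflates CV during maintenance.
* Problem sizes in the test-suite experiments (16–21 s trials, 13 s
  capacity runs, 31–46 s novel-cue runs, bounded discovery) are the
  package's default desk-scale settings; the full published-scale versions
  (5 simulated hours of evolution, exhaustive discovery) are cluster-scale
  and are not attempted here.

## Known limitations

* The engineered-group battery partially entrains non-cued overlapping
  groups during maintenance (non-member rate ~2–3 Hz instead of 0.3 Hz).
* NMDA-mode maintenance is short-lived (sub-second to a few seconds) in
  stable regimes; stronger up-state transmission produces relay runaway.
* Novel-cue learning forms a detectable template but no spontaneous replay
  at desk scale (see above).
* Discovery statistics depend strongly on the search budget; counts are
  lower bounds.
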