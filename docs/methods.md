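# Methods

This note documents the models implemented in `stdebg`, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not establish.

## The plasticity framework

A cortico-striatal synapse's plasticity depends on three factors: the
postsynaptic neuron type (D1- or D2-receptor expressing MSN), the dopamine
level `D`, and the sign of the pre/post spike-pair timing
`Δt = t_post − t_pre`.

**Kernels.** At the extremes of the dopamine scale the rule is pair-based
STDP with exponential kernels `f(Δt) = A·exp(−|Δt|/τ±)`; one amplitude `A`
per (type, dopamine extreme, timing sign) — eight in total. τ± = 20 ms.
Exactly coincident pairs (Δt = 0) contribute nothing: the kernel is
discontinuous there and the underlying biology is unresolved; this is
configurable only in the sense that the engine's time resolution defines
coincidence (one 0.025 ms step).

**Mixing.** Intermediate dopamine levels blend the extreme amplitudes
linearly through a Naka-Rushton function
`m(D) = M·D^n/(D^n + θ^n)` (D1: n = 1.2, θ = 6.0, M = 1.2; D2: n = 1.4,
θ = 1.8, M = 1.0). The blended amplitude `P(D) = m·A_hi + (1−m)·A_lo` is
the *plasticity factor*. `M > 1` (D1) deliberately lets the blend
extrapolate beyond `A_hi` at very high `D`. Nothing hinges on the
Naka-Rushton form beyond rapid rise, saturation and monotonicity.

**Eligibility (STDE).** Each pair deposits its unit-normalised kernel value
`exp(−|Δt|/τ±)` into one of two per-synapse eligibility traces (`c+` for
positive, `c−` for negative timing), which decay with τe = 300 ms — long
enough to bridge the 150 ms delay to the reinforcement-locked phasic
dopamine signal. The weight integrates

    dw/dt = (α/τe) · [ P+(D(t))·c+(t) + P−(D(t))·c−(t) ],    α = 0.65.

The dopamine-dependent amplitude enters only at integration time; this is
the unique factorisation under which the rule reduces exactly to STDP for
constant dopamine (the reduction theorem), including for dopamine changes
that arrive after the pair. The α/τe scaling makes the reduction exact
because a single deposited kernel integrates to `f̂·τe`.

**Pairing scheme.** All-to-all pairing is implemented with presynaptic
traces (decay τ+) and a postsynaptic trace (decay τ−); a postsynaptic spike
deposits the pre-trace into `c+` of every synapse, a presynaptic spike
deposits the post-trace into `c−`. This is mathematically the all-to-all
sum with no timing cutoff (pairs beyond ~5τ contribute < 0.7% and fade
smoothly rather than being truncated).

**Default coefficients.** The in-vitro-derived sign pattern constrains six of
the eight amplitudes (standard STDP holds only for D2 at high dopamine;
D1-hi/negative and D2-lo/negative are unconstrained). Within that pattern
the shipped values are calibrated model values, selected the same way the
coefficient search selects them, under three conditions:

1. *Sign pattern* as above.
2. *Tonic balance*: at tonic dopamine both types express standard STDP
   whose LTP and LTD sides cancel for background activity. Because driven
   firing is causal, the positive-timing eligibility slightly exceeds the
   negative (measured ratio R ≈ 1.15 for D1, ≈ 1.19 for D2 at baseline
   state), so the balance condition is `P−(3) ≈ −R·P+(3)`, not symmetric
   amplitudes. The smaller the tonic factors, the less sensitive the flat
   epochs are to the state dependence of R; the D2 floor is set by the
   theta-burst replication, which needs `A+hi ≳ 0.37·|A−hi|` to express
   LTP against the burst geometry's negative cross-pairs.
3. *Profile directions* over the operant experiment (below), verified on
   ten-repeat runs at several independent seeds.

Shipped values (hi+, hi−, lo+, lo−): D1 (0.7, −0.2602, −0.3928, 0.14);
D2 (0.026, −0.0616, 0.065, −0.016). Amplitude units are nS of AMPA
conductance change per unit eligibility.

## The spiking MSN

Biophysical Izhikevich form with C = 15.2 pF, vr = −80 mV, vt = −29.7 mV,
vpeak = 40 mV, vreset = −55 mV, k = 1, a = 0.01 /ms, b = −20, d = 91.
Note that b < 0 places the rheobase near 230 pA (the recovery variable
amplifies depolarisation), which constrains the synaptic scale below.

200 excitatory synapses (AMPA + NMDA) and 84 GABAa synapses; single
exponential channels with τ = 6/160/4 ms, reversals 0/0/−60 mV; NMDA gated
by the Jahr–Stevens magnesium block at 1 mM. Initial AMPA conductances are
Gaussian, mean 0.458 nS, CV 0.1, negatives clipped to zero, with a hard
ceiling of 2.0 nS throughout learning. Fixed NMDA and GABA conductances
are tied to the AMPA scale by ratios 0.2 and 1.4. The NMDA ratio is a
model choice: with the background and salient input rates used here,
ratios near 1 or above drive the neuron into continuous firing; 0.2 yields
the intended regime of sparse baseline firing (~13 spikes per 2.4 s trial
for D1, ~5 for D2) and salience-locked responses.

Dopamine receptor occupancies follow `φ(D) = D²/(D² + 0.6²)`, ≈ 0.96 at
tonic `D = 3` and ≈ 0.99 at the phasic peak. A D1 MSN scales
vr ← vr(1 + 0.0289 φ1) (KIR), d ← d(1 − 0.331 φ1) (L-type Ca²⁺) and NMDA
efficacy ← (1 + 0.5 φ1); a D2 MSN scales k ← k(1 − 0.032 φ2) (A-type K⁺)
and AMPA efficacy ← (1 − 0.215 φ2). The β values are model defaults
(configurable); the dip-induced *release* of the AMPA attenuation is the
main route by which phasic dips transiently raise D2 excitability.

**Integration.** Forward Euler at dt = 0.025 ms. At this step, halving dt
changes fixed-input per-trial spike counts by < 2%; at 0.1 ms the counts
are still ~4–5% from converged (the NMDA-driven fluctuation regime is the
sensitive part), so the coarser step is not used as the default. The trial
engine is event-driven where possible: per-receptor weighted conductance
sums decay analytically; eligibility and weight integrals use exact
piecewise-exponential segments accumulated per chunk (1 s) so no
cancellation occurs over long protocols; per-synapse state is touched only
at spike events. Weight changes accumulate during a trial and are applied
(with floor 0 and the ceiling) at segment boundaries; the within-trial
change is a fraction of a percent of the conductance, far below the
trial-to-trial noise.

## The operant experiment

155 trials of 2.4 s in epochs baseline/learning/intermission/extinction/
post-extinction (15/40/30/40/30). Each trial has a 0.4 s salient bout
(onset at 1.0 s) driving a 50-synapse subset S at 25 spikes/s; background
is 3 spikes/s everywhere, including the GABA synapses. S is fixed during
learning and extinction and redrawn uniformly each trial elsewhere.

Dopamine is tonic at 3 except on reinforced (learning) or
reinforcement-omitted (extinction) trials, where a phasic event starts
150 ms after the bout with onset amplitude ~ N(Γ, 0.55) and decays with
20 ms. The across-trial envelope Γ decays from +3 (bursts peak at D = 6)
over learning and rises from −6 (deep dips clip D at 0) over extinction,
both with τ_Γ = 20.8 s, leaving the envelope just below 1% of its maximum
at the end of the 96 s learning epoch. Γ is evaluated at trial onset.

Repeats of the experiment use independent schedule realisations,
deterministic in (seed, repeat); D1 and D2 runs at the same seed share
schedules. This matters for the flatness statistics: a schedule shared
across repeats makes subset-draw trends common mode and biases the
across-repeat slope test.

**What the generator emulates and what it does not.** The task is
open-loop: action choice does not feed back into the schedule, context is
carried entirely by which afferents are salient, and cortical inputs are
homogeneous Poisson with two rates. Real cortical drive has structured
rate distributions, temporal correlations, and closed-loop contingencies;
passing the directional tests here shows the plasticity rules produce the
required single-neuron trajectories under the stylised conditions, not
that they would do so under arbitrary natural statistics.

## The basal ganglia network and the selection assay

Six leaky-integrator channels per nucleus (D1/D2 striatum, STN, GPe,
GPi/SNr), τ = 25 ms, piecewise-linear outputs clipped to [0, 1], negative
thresholds (−0.25 STN, −0.2 GPe/GPi) giving tonic output; striatal
threshold 0.2. Salience enters D1 (facilitated by 1 + λ1), D2 (attenuated
by 1 − λ2, λ = 0.2) and STN; D1 inhibits GPi channel-wise; D2 inhibits
GPe; STN excites GPe and GPi diffusely (0.9); GPe inhibits STN (1.0) and
GPi. Integration uses Euler at 5 ms: at the model family's customary 10 ms step
the discrete map of the STN–GPe loop (diffuse gain ≈ 5.4) is oscillatory
even though the ODE converges; at 5 ms equilibria agree with 10× finer
steps to 10⁻⁹ and are independent of τ.

Two wiring values and the readout threshold are not inherited: GPe→GPi
0.5, D2→GPe 0.8, θ_sel = 0.1. These were chosen, within the same
architecture, as the values at which the network simultaneously exhibits
all the qualitative selection phenomena the assays test: within-channel
D1/D2 antagonism; best selection at D1 responsiveness above D2 with
strictly positive D2; best suppression at D2 responsiveness above D1, with
near-maximal matches persisting down to ~1:1 D1. With the classic
GPe→GPi = 0.3 and D2→GPe = 1.0, raising a channel's D2 weight silences its
GPe, and the resulting diffuse STN surge blocks the *competing* channel —
suppression then always looks best with no D2 at all. The stronger GPe→GPi
compensation cancels most of the surge and restores the trade-off.

Sweeps fold the dopamine efficacy factors into the weights network-wide
(responsiveness is the net input:output ratio) and disable the saturation
of the experimental channel's MSN outputs. The default sweep range is
[1, 2]: the assay probes a trained channel, whose D1 responsiveness stays
at or above the untrained 1:1 ratio.

Trained spiking MSNs enter the network by measuring their normalised
input–output curve (output 1 ≡ 40 spikes/s; input 1 ≡ all 50 salient
afferents at 40 spikes/s) and least-squares fitting `y = max(0, w·x − ε)`.
Behavioural performance is the number of salience pairs (of 100, over the
[0.1, 1.0] 10×10 grid) at which the key channel is selected.

## Induction replication

Theta-burst induction at a single plastic AMPA synapse, membrane held at
−70 mV by injected current (computed from the modulated nullclines so the
hold is exact). Pre-post bursts: three EPSPs 20 ms apart, each followed by
a fictive postsynaptic spike at +5 ms; post-pre: three fictive spikes
20 ms apart, the last followed by an EPSP at +10 ms; five bursts per block
at 5 Hz; ten plastic blocks 2 s apart between zero-learning-rate
measurement phases (five test EPSPs each; the peak depolarisation from
holding is the EPSP amplitude). Fictive spikes are forced pairing/reset
events — the held membrane cannot reach threshold, and the run aborts if a
spontaneous spike occurs. Dopamine conditions act at the mixing extremes
(hi: m = 1, lo: m = 0), which is where the extreme kernels are defined;
receptor occupancies are set from D = 6 / D = 0. At the extremes the
per-pair weight changes are large, so ten blocks saturate the conductance
against its floor or ceiling; the reported EPSP ratios are therefore used
for their sign and rank order, not their magnitude.

## Renewal and reacquisition

Context is an afferent subset: context B shares 25 of A's 50 synapses
(the sensory/pre-motor core), the rest drawn from A's complement. After
training in A (baseline + learning + intermission), each sequence (AAA,
ABA, ABB) runs 40 extinction trials (dips) under its second context and
40 reacquisition trials (bursts at full amplitude, every trial) under its
third, fitting rate-coded equivalents and counting key-channel selections
at each stage. Renewal after ABA exceeds the controls because extinction
under B concentrates depression on B's afferents, sparing the A-specific
half of the trained set.

## The coefficient search

Per MSN type, the four amplitudes span a lattice (default [−1, 1] per
axis, five points per axis = 625 points; augmented with explicit sets,
e.g. the shipped defaults). Each point runs three seeded repeats of the
reduced-epoch experiment (D1: 15/30/30/20/15, D2: 15/40/30/20/15 trials),
smooths the ensemble-mean spike counts over three trials, and scores five
features from five-trial windows at epoch ends: baseline flatness,
learning rise (D1 ≥ 3 spikes, D2 no decline — the slight D2 rise is
within three-repeat noise), within-intermission stability, within-epoch
extinction change in the type's direction (D1 fall ≥ 2, D2 rise ≥ 0.25),
and post-extinction flatness. The total score is an equally-weighted sum
of squared shortfalls; a set is *accepted* when every component is zero
(the hard-threshold stand-in for visual inspection). The optional second
stage spans the bounding box of the five best stage-1 sets, expanded 10%.
Scores are deterministic given the seed and embarrassingly parallel
across points.

## Known limitations

* The network's missing numeric weights were reconstructed from the model
  family plus the qualitative selection phenomena; absolute template-match
  percentages depend on them and should not be over-interpreted.
* Induction ratios saturate at the dopamine extremes (signs and orders are
  meaningful, magnitudes are not).
* Tonic balance is exact only near the calibration state; flat epochs are
  statistically flat (no detectable trend across ten repeats), not
  identically zero drift.
* A single representative neuron per population; no MSN–MSN or
  interneuron circuitry, no short-term plasticity, no multi-compartment
  morphology, no intracellular signalling cascade.
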