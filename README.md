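# stdebg

Dopamine-modulated cortico-striatal plasticity and basal ganglia action
selection: a modelling stack linking plasticity at single synapses to the
learning and extinction of actions.

Cortico-striatal synapses onto medium spiny neurons (MSNs) are the leading
candidate for the neural interface between reinforcement and action. In
vitro, their plasticity depends jointly on the postsynaptic receptor type
(D1 vs D2), the dopamine level, and the sign of pre/post spike timing — a
three-factor rule far richer than the classic "high dopamine → LTP, low
dopamine → LTD" dichotomy. This package is for computational
neuroscientists who want to test whether that three-factor rule can
actually carry operant learning: it implements the full chain from
spike-timing events at a synapse, through a spiking MSN's activity changes
over a conditioning experiment, to action selection by a rate-coded basal
ganglia circuit.

## The model

**Plasticity.** For each MSN type, STDP kernels
`f±(Δt) = A± · exp(−|Δt|/τ±)` are defined at the two extremes of the
dopamine scale (eight amplitudes in total). Intermediate levels blend the
extremes through a saturating Naka-Rushton mixing function
`m(D) = M·Dⁿ/(Dⁿ + θⁿ)`, giving dopamine-dependent *plasticity factors*

    P±(D) = m(D)·A±_hi + (1 − m(D))·A±_lo .

Spike pairs do not change weights directly: each pair deposits its kernel
value into a decaying eligibility trace `c±` (τe = 300 ms), and the weight
integrates the trace against the instantaneous plasticity factor,

    dw/dt = (α/τe)·[P₊(D(t))·c₊(t) + P₋(D(t))·c₋(t)] ,

the spike-timing-dependent eligibility (STDE) rule. For constant dopamine
it reduces exactly to STDP; for phasic dopamine arriving 150 ms after the
action-related spiking it solves the temporal credit-assignment problem.

**Neuron.** A biophysical Izhikevich MSN
(`C v̇ = k(v−vr)(v−vt) − u + I`) with 200 plastic AMPA (+ fixed NMDA) and
84 GABAa conductance synapses, and direct dopaminergic modulation of KIR,
L-type Ca²⁺, A-type K⁺ and the synaptic efficacies.

**Circuit.** A six-channel leaky-integrator basal ganglia network
(D1/D2 striatum, STN, GPe, GPi/SNr) that resolves salience competitions;
an action is selected when its GPi output drops below a threshold.

On top of these sit the simulated operant-conditioning experiment
(baseline / learning / intermission / extinction / post-extinction, with a
decaying envelope of dopamine bursts and dips), ideal-selector template
assays, theta-burst induction replication, context-dependent renewal and
reacquisition protocols, and an exhaustive lattice search over the
plasticity coefficients.

## Worked example

```python
import numpy as np
from stdebg import default_coefficients, default_mixing, blended_amplitude
from stdebg.experiment import run_experiment, summarize_profiles

co, mix = default_coefficients(), default_mixing()
for D in (0.0, 3.0, 6.0):
    pp = blended_amplitude("D1", "pos", D, co, mix)
    pn = blended_amplitude("D1", "neg", D, co, mix)
    print(f"D1 D={D}: P+ = {pp:+.3f}, P- = {pn:+.3f}, sum = {pp+pn:+.3f}")

profs = run_experiment("D1", n_repeats=3, seed=1)
sc, g = summarize_profiles(profs)
ep = profs[0].epoch
for e, name in enumerate(("baseline", "learning", "intermission",
                          "extinction", "post-ext")):
    idx = np.flatnonzero(ep == e)
    print(f"{name:12s} counts {sc[idx[:5]].mean():5.1f} -> {sc[idx[-5:]].mean():5.1f}   "
          f"mean g(S) {g[idx[:5]].mean():.3f} -> {g[idx[-5:]].mean():.3f} nS")
```

prints

```
D1 D=0.0: P+ = -0.393, P- = +0.140, sum = -0.253
D1 D=3.0: P+ = +0.005, P- = -0.006, sum = -0.001
D1 D=6.0: P+ = +0.263, P- = -0.100, sum = +0.163
baseline     counts  12.9 ->  12.7   mean g(S) 0.455 -> 0.457 nS
learning     counts  14.5 ->  24.9   mean g(S) 0.520 -> 0.747 nS
intermission counts  18.4 ->  18.2   mean g(S) 0.749 -> 0.749 nS
extinction   counts  18.2 ->   4.8   mean g(S) 0.563 -> 0.311 nS
post-ext     counts   8.5 ->   8.3   mean g(S) 0.313 -> 0.315 nS
```

The plasticity factors show the D1 rule morphing from net LTD at depleted
dopamine, through balanced standard STDP at the tonic level (sum ≈ 0, so
background activity causes no drift), to net LTP during a phasic burst.
The experiment shows the consequence: D1 spike counts and the mean AMPA
conductance of the reinforced subset S rise over learning, hold through
the intermission, and fall back toward baseline over extinction — without
being driven to zero. Running the same experiment for a D2 MSN shows the
complementary profile (slight rise over learning, further rise over
extinction: the substrate of active action suppression).

A command-line interface exposes the standard runs, e.g.

```bash
stdebg sweep --mode selection --out results/
stdebg experiment --seed 1 --repeats 10 --out results/
stdebg shen --out results/
stdebg renewal --out results/
```

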