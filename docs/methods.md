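# Methods

`burstnet` simulates a small visuo-motor system built exclusively from the
primitives of a digital neurosynaptic core: leaky integrate-and-fire (LIF)
neurons with integer parameters, binary synapses at test time, two axon
types, a 1 ms tick, and reset-to-zero firing.  This note records the model,
the numerical conventions, the free design choices and what the shipped
defaults do and do not demonstrate.

## Neuron model

Each neuron carries a membrane potential `M >= 0`, a firing threshold `T in
[1, 256]`, a linear per-tick leak `L`, and one multiplicative weighting
value per input sign (`S+` for excitatory inputs, `S-` for inhibitory).
Spikes emitted at tick `t` are integrated by their targets at `t+1`.  With
`x` and `y` the weighted excitatory/inhibitory drives of a tick,

```
fired = (M + x - y) > T
M'    = 0                       if fired
        max(0, M + x - y - L)   otherwise
```

The threshold test sees the integrated membrane *before* the leak is taken
out; the leak only erodes potential carried to the next tick.  This
ordering is a deliberate numerical convention: several groups of the
published parameter table (the training-time winner-take-all interneurons
with `L >= S+`, the retinal presence detectors with `L = T - 1`, and the
motor coincidence units with `L = T - 1`) can only ever fire under it, and
with it they behave exactly as described.  Under the alternative
(leak-before-threshold) convention those groups are arithmetically dead.
Both orderings agree on every observable in all other groups.

A neuron that does not fire is always left with `M <= T`, so there are no
spontaneous threshold crossings at rest, and membranes are non-negative at
every observable point.

## Architecture

23 neuron groups, 766 neurons.  A 10x10 binary retina (input clamp: a
retinal neuron spikes whenever its pixel is 1) feeds two streams:

* **shape** (ventral): S1 edge detectors read aligned 2-pixel windows
  (1x2 at stride 1,2 and 2x1 at stride 2,1 — the unique tilings that
  produce the published 10x5 / 5x10 grids); C1 relays them, with an
  inhibitory copy projecting a 1-cell surround (noise suppression) and a
  max-pooling stage collapsing 2 cells per orientation; S2-shape (36
  cells) learns C1-max conjunctions without supervision under a
  weakly-enforced winner-take-all (a train-only inhibitory mirror layer);
  CLA-shape holds one 10-neuron pool per letter, trained by value-gated
  burst-STDP.
* **motion** (dorsal): S1-inst and S1-del are 4x4-window presence
  detectors (fire when >= 7 of their 16 pixels are on); S1-del sees the
  retina 20 ticks late.  Because the windows tile at stride 2 and the
  letters carry 7-9 pixels, an object registers exactly when it is
  aligned with a window — every second movement step — so the delayed
  pathway spans two 10-tick movement periods and an
  instantaneous/delayed coincidence names a *movement direction*, not
  just a position.  S2-where (24 cells) learns those coincidences
  unsupervised; CLA-where holds one pool per trajectory (8 x 10).
* **attention**: an inhibitory group receiving topographic motion input
  through the core's spare synapse-value slot at a deliberately
  sub-threshold gain (4 vs. threshold 5) plus learned shape input, so an
  attention cell needs a motion+target-shape coincidence to fire.  Its
  plasticity is value-gated only on trials containing the target letter.
  Its top-down outputs (inhibition of non-target classifications and
  non-target motion) engage only after learning has completed; during
  training only its lateral competition is active.
* **decision**: Target and Obstacle integrate their trajectory pool
  (threshold 21, leak 5) and drive the motor unit at the trajectory's
  arrival placement (Target) or the diagonally opposite placement
  (Obstacle).  Shape-inh vetoes Obstacle when the target letter is
  recognized, Target when the avoidance letter is recognized, and both
  for the distractor.  Shape-decision integrates letter evidence slowly
  (threshold 13, leak 3) and gates the motor units: a motor spike needs a
  Shape-decision + Target/Obstacle coincidence within two ticks.  The
  classifier pools reach the integrators through the spare synapse-value
  slot at gain 2 so that one full pool volley crosses within a couple of
  ticks while partial volleys decay.

All weights are binary at test time; the only graded quantities are the
real-valued plastic weights during training and the per-neuron
multipliers, both native to the hardware model.

## Learning

*Burst traces.* Each presynaptic neuron keeps `b' = max(0, b + 0.4*spike
- 0.05)` per tick: a leaky memory of recent spiking that grows under
bursts.

*Unsupervised burst-STDP.* On every postsynaptic spike of a feature layer,
each incoming plastic weight gains `eta0 * b_pre` (potentiation only),
clamped to [0, 1.5].  Defaults: `eta0 = 0.005` for the shape feature layer
and `0.002` for the motion feature layer.  The rates matter through one
mechanism: between renormalizations, a weight at the 1.5 cap lets its cell
fire from fewer coincident inputs than the binarized network ever will, and
such a cell annexes primitives it should not own.  The motion layer's
presence coincidences last tens of ticks, so its rate must be lower for
the same excursion.

*Renormalization.* Every plastic layer is rescaled per neuron (all its
incoming plastic weights divided by their maximum) at a fixed interval:
500 ticks for the feature layers, 2500 for the value-gated layers.
Renormalization preserves weight ratios; weights decay in absolute terms
only while the neuron's maximum keeps regrowing toward the cap, which is
what separates regularly-reinforced weights from occasionally-reinforced
ones and drives the layer toward binary values.  A final threshold at 0.5
guarantees binarity before testing.

*Value gating.* After each training presentation an external supervisor
compares each classifier layer's winning pool (argmax of spikes integrated
over the trial; ties produce no event) with the trial's label.  The
accumulated burst-STDP change of the *winning pool's* synapses is then
applied, scaled by the annealed reward (0.5 -> 0.1 for correct winners) or
punishment (-0.1 -> 0 for wrong winners) constant; other pools are
untouched.  Crediting only the winner is what lets punishment dethrone an
entrenched wrong winner so the correct pool can start collecting rewards;
crediting every active neuron (an alternative reading) reinforces
wrong-pool bystanders on every correct trial and provably never separates
the pools.  Attention synapses are updated only on target-letter trials,
always with the reward sign.

*Protocol.* One "epoch" is 400 single-object noiseless presentations
(letter, corner and direction uniform).  The default protocol is staged:
one unsupervised epoch (feature layers self-organize under the train-only
winner-take-all), then two epochs with value gating active while
unsupervised refinement continues.  Consolidation = final renormalization,
binarization, severing the train-only groups, and a hardware audit.

## The synthetic environment

Letters T, L, J as 4x4 bitmaps; trajectories start in one of the four
corners and run laterally or vertically at 1 pixel per 10 ticks, leaving
the field after 100 ticks; per-pixel flip noise is redrawn every tick.
The bitmaps were selected by exhaustive search of the 4x4 bitmap space
under the constraints the fixed neuron constants impose (see the comment
in `environment.py`): >= 7 pixels in an aligned presence window and <= 6
in every misaligned one; exactly 3 pooled edge features at a time, pairwise
non-adjacent within an orientation map so the C1 surround never interrupts
a clean letter; at most one pooled feature shared between any two letters
at a matched position.  The glyphs are therefore stylized (serif-like
single-pixel strokes), and they are a config-replaceable input, not a
claim about the original stimuli, whose pixel patterns are not published.

What the generator does *not* emulate: gray levels, correlated noise,
object scale or rotation changes, more than two simultaneous objects, or
an object occluding another (overlaps are a logical OR).  Passing tests
therefore demonstrate the learning machinery under the stated conditions,
not robustness to natural video.

## Readouts and outcome accounting

* Letter recognition: winning CLA-shape pool over the trial.
* Motion direction: winning CLA-where pool over the trial (no spikes or a
  tie = No Decision).  This task is asked of all three letters, including
  the distractor whose *motor* output the decision module deliberately
  silences, so it is read at the classifier rather than the motor layer.
  A `direction_network` configuration (semantics channels severed, motor
  output = anticipated arrival placement) is also provided.
* Full task and two-object task: the last motor spike before the object
  leaves the retina; no spike = No Decision; for a distractor-only trial
  silence is the correct response.  Two distinct motor units spiking on
  the final active tick count as an incorrect (ambiguous) response.

## Known limitations

The shipped operating point reproduces the architecture's qualitative
behaviours — position-invariant letter pools emerge in one epoch,
trajectory-selective motion cells form, attention becomes target-selective,
the hardware audit passes — but falls short of the strongest published
noise-tolerance figures.  Measured with the default protocol: per-letter
recognition averages roughly 70-100% (the letter sharing most features
with the others is the weakest); motion-direction classification is
roughly 75-85% clean and degrades well before 33% noise; the motor
pathway produces no decision on a majority of single-object trials, so
the full-task and two-object batteries sit far below their published
curves.  The root cause is temporal sparsity: with 36 shape cells covering
~84 letter-position patterns at 3 features each, classifier pools volley
a few ticks per object position rather than continuously, and the decision
integrators (whose thresholds and leaks assume sustained pool drive) find
few coincidences, while their vetoes leave one-tick gaps that let the
wrong channel through.  Denser stimuli repair the decision layer but
collapse the feature competition (every cell then crosses threshold on
the first volley and the winner-take-all cannot rank candidates); the
constants in between are not printed in the source material.  The
acceptance script reports what the implementation actually measures.

Smaller numerical notes: ties at any argmax produce no event (training)
or a No Decision (testing); trials reset membranes, spike history and
traces (each presentation is an independent stimulus); anneal progress is
the fraction of completed presentations of the value-gated phase; all
randomness flows from named seeds through independent child generators,
so any experiment is bit-reproducible and paired arms can share trial
streams.
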