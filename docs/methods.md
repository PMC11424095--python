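# Model and methods

`nmph` simulates how two competing memories change their neural
representations under a purely unsupervised, nonmonotonic ("U-shaped")
learning rule. This note documents the model equations, the conventions this
implementation had to fix where the published description leaves them open,
the parameters that matter, and what the simulations do and do not reproduce.

## Architecture

Four rate-coded layers: two clamped input layers — *category* (3 units, the
middle unit is shared by both stimuli) and *item* (2 units, one per pairmate)
— a *hidden* layer (50 units) and an *output* layer (50 units for the
topographic color model, 10 for the associate models). All projections are
full, bidirectional, and share a single weight matrix per pair of layers with
separate forward/backward scale multipliers; weights live in [0, 1].

Memories are pre-wired rather than learned: each item unit connects at 0.99
to a block of six hidden units, the two blocks share 0–5 units (the overlap
manipulation), blocks are internally all-to-all at 0.99, and the category unit
connects to every block unit. The hidden-to-output prewiring differs per
study (topographic blocks plus one-to-one background for the color model; a
single shared or two distinct associate units for the others). Background
weights are drawn per run from the published uniform ranges.

## Dynamics

Each trial is 200 synchronous cycles. Per cycle and layer:

1. **Net input.** `net_i = Σ_p (s_p / k_p) Σ_j w_ij a_j + g_clamp · ext_i`,
   summing over incoming projections p with directional scale `s_p`. The
   divisor is the *expected active count* (the sending layer's kWTA k), so
   the published scales are independent of layer size. This normalization is
   not stated in the source description; dividing by the full sender count
   instead starves feedback from sparse layers and the oscillation mechanism
   never engages. One directional calibration constant departs from the
   rule: the single-winner associate output layer (k=1, N=10) divides by
   `ASSOCIATE_NORM_COUNT = 4`; at divisor 1 its feedback (scale 1.7) is so
   strong that the two pairmates' hidden patterns merge already at the
   baseline test.
2. **Inhibition.** Units are ranked by the inhibition `g_thr = net − θ` that
   would put them at activation threshold. The winner count k′ extends from k
   over units tied with the k-th within `target_diff`, capped at `k_max`;
   inhibition is placed `kwta_point` of the way from the k′-th unit's
   threshold value down toward the (k′+1)-th (higher point ⇒ lower
   inhibition). During training trials, from cycle 125 the inhibition is
   multiplied by `1 + osc·sin(2π(c−125)/75)` — one full period to cycle 200,
   raised first, then lowered so competitors can pop up.
3. **Activation.** `a* = γx/(γx+1)` on the positive part of
   `x = net − θ − gi`; activity moves toward `a*` by a step `dt` per cycle.

Conventions fixed here (the source gives none): threshold θ = 0.25 for
interior layers and 0 for the item layer — the item layer's drive (clamp
0.3, feedback ≲ 0.2) sits below 0.25, and since the oscillation is
multiplicative on `gi`, a fixed θ above the drive would make competitor
item-unit pop-up impossible at any amplitude. `dt = 0.104` for hidden and
output and `0.2` for the small clamped input layers. `dt` is the load-bearing
constant: a unit reached by the falling inhibition late in the trough rises
for only tens of cycles, so its end-of-trial averaged trace — and with it the
coactivity — grades with how early pop-up began. Faster settling saturates
every pop-up and abolishes the moderate-activity regime entirely.

## Learning

Cascaded running averages are reset at trial start and updated every cycle
(`α_ss = α_s = 0.5`, `α_raw = 0.1`, medium = `0.9·raw + 0.1·short`). At the
end of each training trial, each connected pair's coactivity
`κ = μ_med^send · μ_med^recv` passes through the five-parameter piecewise
linear U-shape `(0,0)–(DThr,0)–(DRev,DRevMag)–(ThrP,0)–(1,DMaxMag)`
(linearity is our choice; the five published numbers fully determine it),
scaled by `LRate`, and weights update with hard clipping to [0, 1]. Hard
clipping (rather than soft bounding) is what lets the large negative
`DRevMag` values sever a connection in a single trial — the "escape
velocity" that differentiation needs. Reciprocal directions share one
parameter set and one matrix, so the update is applied exactly once.

## What the simulations reproduce

At the defaults (50 runs × 20 epochs per condition; ~10 s per condition on
one CPU):

* **Overlap curve.** 0/6 and 1/6 overlap: no competitor pop-up, no change in
  correlation or color center-of-mass. 3/6–5/6: strong pop-up, integration
  (correlation → 1) and color attraction. 2/6: a bimodal mix — roughly 40%
  of runs differentiate abruptly (anticorrelated hidden patterns, color
  repulsion), the rest integrate or are flagged undefined.
* **Asymmetry.** In differentiated 2/6 runs the first-presented pairmate's
  color report stays put while the second-presented pairmate's moves away
  (~4 output units); the displacement classifier blames pairmate 2 in a
  clear majority of runs.
* **Anticorrelation and bimodality.** Every differentiated run ends with a
  negative within-pair correlation, and the distribution of final
  correlations is two clusters with an empty middle, not a unimodal bulge.
* **Learning-rate boundary.** At `LRate = 0.1` differentiation disappears
  (2/6 integrates instead) while the high-overlap conditions integrate
  regardless, as only weakening needs to complete within one trial.

## Known limitations

* **Aggregate 2/6 means.** Anticorrelation of 6-active-unit patterns in a
  50-unit layer is bounded at ≈ −0.14, while integrated runs reach +1, so
  the *mean* 2/6 correlation change is dominated by the integrating minority
  and does not go negative; likewise the mean distance change is only weakly
  positive. The per-run bimodal structure, not the mean, carries the effect
  here.
* **Abruptness.** Individual differentiated runs still switch within a
  single epoch, but not all of them on the *first* one: at the defaults
  roughly 40% of differentiated 2/6 runs cross at epoch 1 and the rest at
  epochs 2–4 (after first drifting toward integration), and at `LRate = 0.5`
  severing takes several trials, spreading onsets over epochs 1–6.
* **Shared-associate paradigms.** In the same-associate and curriculum
  models the shared output unit's pathway is deliberately almost unseverable
  (`DRevMag = −0.01`) and feeds both pairmates equally. Under these
  activation dynamics the intact six-unit pairmate-1 clique then always
  out-competes the severed four-unit pairmate-2 clique on the following
  trial: same-associate and interleaved conditions re-integrate rather than
  differentiate, and on many runs repeated oscillation pop-ups erode the
  competitor item unit's connections until that stimulus's pattern falls
  below the activation floor (such runs are flagged undefined and excluded
  from aggregates). Blocked-condition integration and the high-amplitude
  regime (both conditions integrate) do reproduce. We attribute the missing
  differentiation regime to activation-level details of the original
  simulation framework that the description does not specify (noise-convolved
  activation, membrane-potential integration), which would give near-threshold
  units fractional activity instead of the steep all-or-none response of the
  closed-form gain function used here.

## What the generator does and does not emulate

All inputs are internally generated one-hot stimuli; the only randomness is
the background weight draw and the per-epoch presentation order, exactly the
two sources of run-to-run variance described for the original. There is no
sensory noise, no encoding variability and no forgetting, so run-level
variance here is a lower bound on what real data would show; passing tests
demonstrate the competitive-learning mechanism, not fits to empirical effect
sizes.

## Numerical choices

* Ties at exactly the inhibition value count as sub-threshold (deterministic
  winner counts).
* If every ranked unit is tied, the interpolation target below the last
  winner is taken as zero inhibition.
* Undefined correlations/centers-of-mass (all-zero patterns) propagate as
  NaN and are excluded from aggregates but reported in run counts.
* Classification band δ = 0.1 correlation units around baseline; asymmetry
  attribution requires the larger pairmate displacement to be at least twice
  the smaller, with a 5%-of-baseline-norm floor for "moved at all".
* Every random draw descends from one master seed via spawned generators:
  run r's weights depend only on (seed, r), and the schedule stream is
  separate from the weight stream.
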