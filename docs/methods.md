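# Model and methods

`gatenav` simulates a rodent solving Morris water-maze tasks with three
parallel navigation strategies arbitrated by a learned gating network. This
note records the model equations, the defaults and why they were chosen, the
numerical decisions, and what the simulations can and cannot show.

## Arena and kinematics

The pool is a disk of radius 100 cm; the escape platform a disk of radius
5 cm. The agent is a 15 cm diameter disk moving 6 cm per timestep in the
direction chosen by the selected module, with a trial cap of 350 timesteps.
A move that would push the body past the wall is radially clamped to
`arena_radius − 7.5 cm` while keeping the displaced angular coordinate, so
the agent slides along the wall instead of sticking to it. The platform is
"reached" when the agent's centre is on the platform disk. A trial that
times out with a platform present ends with a guided straight-line return
during which all learning updates keep running; the terminal reward update
of that return is what first plants the planning goal, the same way an
animal placed on the platform still learns its location.

## Perception

The entorhinal input is the concatenation of a grid-cell population and one
ring of cue cells per landmark.

* **Grid cells** (27 = 3 scales × 9 phases): the standard three-plane-wave
  interference pattern, rectified to [0, 1] so fields are zero-background
  bumps. Scales default to 60/90/130 cm. Small scales alias badly inside a
  200 cm arena — the joint code then assigns high similarity to positions
  ~60–90 cm apart, which destroys place-field formation downstream; the
  large defaults remove that aliasing.
* **Cue cells** (24 per cue): bearing-tuned cells with circular Gaussian
  tuning (σ = π/4) multiplied by an exponential distance decay
  `exp(−d/λ_m)`. Each ring is 12 bearings × 2 distance constants
  (factors 1.0 and 0.25 of the cue's base constant, 100 cm proximal /
  150 cm distal). Two distance scales matter: a purely bearing-coded ring
  makes every linear policy distance-blind, and the cued-platform task with
  a beacon offset from the platform then becomes unsolvable for the
  cue-guided strategy. The wide σ gives the interpolation across bearings
  that beacon approach from novel directions requires.

Path integration is assumed perfect: grid activity is a deterministic
function of true position. An invisible cue silences its whole ring.

## Cognitive map

The map is learned before any rewarded trial from a 1000-step random walk
(straight-run persistence of 8 steps, which covers the arena far better than
a 3-step persistence walk of the same length), and never relearned during
the task.

* **Place cells** (1000): unit-norm weight rows over the entorhinal input;
  activation is the rectified weighted sum, divided by the population
  maximum, sharpened (exponent 12) and restricted to the 50 most active
  cells. Weights are initialized by *imprinting*: each row is the (seeded)
  normalized entorhinal vector at a randomly chosen walk step. Imprinting is
  the data-driven analogue of random initialization for a competitive
  layer; with uniform random rows the population collapses onto globally
  tuned cells and no localized fields form at all. A competitive Hebbian
  update (10 winners, rate 0.2, rows renormalized) refines the rows along
  the walk. Proximal cues are masked out of the map pathway (their weight
  columns stay zero): the map is anchored on the idiothetic + distal-cue
  frame, so a beacon that travels with the platform cannot smear the fields.
* **Graph cells** (100): same imprint-plus-Hebbian scheme over place-cell
  activity with a single winner per update (online k-means-like tuning,
  which keeps node fields spatially coherent). The walk is then replayed:
  the most active node is recorded per step, an edge links every pair of
  consecutive distinct winners, and node centroids are the activity-weighted
  means of the positions at which each node won.
* **Goal values**: setting the goal marks a node with value 1 and iterates
  `G_i ← α · max_neighbor G` to its fixpoint (α = 0.9), which equals
  `α^(graph distance)`; unreachable nodes stay 0. Re-finding a moved
  platform replaces the goal in one trial — the map itself is
  reward-independent.

## Strategies

All strategies emit the same currency: a proposed allocentric movement
orientation.

* **Direction** (one module per assigned cue) and **Locale** (place-cell
  input) are model-free: action cells `φ_i = 2πi/36` with linear values
  `a = W r`, greedy argmax proposals, and one-step Q-learning on the row of
  the action cell nearest the executed orientation
  (`δ = R + γ max a(next) − a_i*(t)`, γ = 0.9). Module inputs are divided
  by a fixed per-module constant (the peak pattern norm) so the effective
  TD step stays bounded while the natural attenuation with distance is kept
  — a far cue produces a scaled copy of the near pattern, which is exactly
  why an approach policy learned near the cue generalizes to first
  sightings from afar. A module whose cue is invisible is blind: its values
  all read zero and its orientation readout is uniform noise; it stays in
  the selection competition under its learned gating value. Every module
  learns from the executed action, whoever proposed it.
* **Planning**: locate the current graph node (argmax of node activation),
  follow the neighbor with the highest goal value; the emitted orientation
  aims from the agent's actual position at that neighbor's centroid (aiming
  from the node centroid instead invites oscillation at field boundaries).
  Invalid until a goal is known.
* **Exploration**: uniform random orientation, persisted for three
  consecutive executed steps (a fresh draw arms two more steps; persistence
  is only consumed while Exploration actually controls movement).

## Gating network

Each module has one gating unit, `g^k = z_k · r`, over the concatenation of
all cue-cell activities and the planning-graph node activations (place-cell
activations when a map exists without a graph), normalized to unit norm —
without that normalization the effective TD step `η‖r‖²` exceeds 1 and the
gating values thrash by whole units between trials. Selection is a
hierarchical winner-take-all (first among Direction modules, then against
the spatial module and Exploration; ties break Planning > Locale >
Direction > Exploration, then lowest index), bypassed while exploration
persistence is active.

Learning is TD Q-learning on the gating level with generalized credit:
`δ = R + γ_g max_k g^k(next) − g^selected(t)` and every module with a valid
proposal receives `Δz_k = η_g cos(Φ_k − Φ_executed) δ r`, so aligned
proposals share the credit and opposed proposals receive the opposite.
The cosine is the minimal kernel with both properties. γ_g defaults to 0.9;
a `selected`-module bootstrap variant is available by configuration.

Two further choices matter and were genuinely open:

* **Initialization**: gating weights start zero-mean uniform with scale 0.5.
  The scale is what creates stable inter-individual differences over short
  protocols — with near-zero initialization every simulated animal in the
  10-trial competition task converges to the same (place-responder)
  strategy, whereas idiosyncratic priors of the same order as the learned
  values reproduce the coexistence of cue- and place-responders. Zero-mean
  matters too: all-positive priors act as global optimism that swamps early
  learning.
* **Exploration floor** (0.05): at selection time the Exploration unit's
  value is floored at a small positive baseline. Unrewarded extinction
  drives the values of executing strategies toward zero but not below, so
  without a floor the strategy with the smallest *positive residual* value
  — typically the buried Planning unit — inherits control of a long
  unrewarded test trial. The floor makes random exploration the fallback
  once every learned prediction is extinguished, which is both the sensible
  default and the behavior the blocking phenomenon requires.

## Protocols

All six experiments are generated procedurally (no external data): hidden
stable platform with four distal cues (I); platform moved every 4-trial
session, 9 sessions (II); cued stable platform for 10 trials with the cue
hidden on trials 3/6/9 and platform+cue moved to the diametrically opposite
position on trial 10 (III); platform moved per session with a proximal cue
at a constant 4 cm offset, 11 sessions (IV); two training stages then
rotation probes (0/45/90/135°, direction fixed per agent) and extinction
probes without the beacon (V); 12 sessions of cued training with the
platform moved per session or per trial, 3 fixed-platform sessions under
the same or a different beacon, and a final cue-less, platform-less test
trial (VI). Start positions are pseudo-randomized over four wall points in
balanced blocks; probe trials (the rotation and extinction probes of V and
the final test trial of VI) release the agent at the wall opposite the
trained platform, so that the occupancy read-outs are not confounded by
the release point. Every repeat
(default 50) rebuilds the map and reinitializes all weights from its own
subseed.

Free parameters per experiment are the Direction and gating learning rates,
`(η_d, η_g)`: I and II (0.10, 0.30), III (1.20, 0.20), IV (0.35, 0.20),
V (0.30, 0.10), VI (0.03, 0.30). The blocking experiment additionally uses
a longer gating value horizon (γ_g = 0.95 instead of 0.9): its probe trial
releases the agent a full pool-crossing away from the goal quadrant, and
with the default discount no learned strategy's value clears the
exploration floor at that distance. Everything else is shared.

## Read-outs

Escape latency is the timestep count to the platform (350 when capped).
Occupancy is the fraction of free (non-guided) timesteps inside a region;
the before/after phases split a trial at the first entry into a reference
region and partition it exactly. Selection rates exclude guided timesteps.
Stage-level selection rates average per trial (each trial weighted equally)
so that long early trials do not dominate; the responder-conditioned rates
of the competition experiment aggregate over all timesteps, the most literal
reading of an "overall" rate. A repeat is a place-responder when its
competition-trial path enters a disk of twice the platform radius around the
previous platform centre before first reaching the displaced cued platform,
else a cue-responder. Octant analyses compare against an empirical chance
group (Exploration only) run through the same protocol rather than assuming
1/8 or 1/4. Group comparisons use the Mann-Whitney test, within-group
comparisons the Wilcoxon signed-rank test (exact when small and tie-free,
tie-corrected normal approximation otherwise), starred at 0.05/0.01/0.001.

## Problem sizes

Unit tests run miniature populations. The behavioral test suite uses 20
repeats for experiments I–IV, 50 for the competition experiment's responder
statistics, 30 for the generalization-gradient experiment and 25 per group ×
condition for blocking; the acceptance script recomputes all headline
selection percentages at the full 50 repeats. Fewer repeats make the
suite's significance claims harder, not easier, to satisfy.

## Known limitations

* The generalization gradient reproduces cleanly between 0° and 45° but the
  45/90/135° tail is not reliably strictly ordered: in this implementation
  the force that removes the agent from the displaced-cue octant is the
  platform's learned pull, which weakens with rotation angle, so retention
  at large rotations is (if anything) slightly elevated rather than
  monotonically suppressed. See the occupancy profiles produced by the
  acceptance tests.
* Cue-guided behavior is learned from one fixed cue layout per experiment;
  generalization to displaced cues rests on the bearing interpolation of
  the cue-cell ring, not on any visual invariance.
* The synthetic protocols use plausible but invented geometry (cue
  azimuths, platform slots, start points). Latency magnitudes therefore
  match real experiments only qualitatively; the model's claims live in the
  orderings, dissociations and selection-rate patterns, not in absolute
  seconds.
* The Direction-plus-Locale variant underexpresses the "no blocking
  anywhere" pattern on the blocking task's probe: a model-free place-action
  policy has no corridor knowledge from the novel release point, so its
  goal-quadrant occupancy stays near the chance group's even in conditions
  where the full model is clearly above chance. Making the place strategy
  cross from novel positions would require exactly the model-based search
  the Locale variant is defined to lack.
* No odometric noise, no swimming dynamics, no visual occlusion, no
  off-line replay.
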