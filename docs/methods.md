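# Methods

## The model system

`collabhunt` simulates chase-and-escape between one prey and one to three
predators in the square arena [-1, 1]^2, in continuous space and discrete
time (dt = 0.1 s, episode cap 30 s = 300 steps). All agents are disks of
diameter 0.1 whose initial positions are drawn uniformly from
[-0.5, 0.5]^2 with zero velocity. Each step every agent selects one of 13
actions: an acceleration in one of 12 directions spaced 30 degrees apart in
its own relative frame — the u-axis points from the agent to its reference
opponent (the prey for predators; the nearest predator, ties to the lowest
index, for the prey), angles turn counterclockwise, action 1 is straight at
the opponent — or action 13, coasting. Dynamics are semi-implicit Euler with
viscous drag,

    v' = damping * v + a * dt,      p' = p + v' * dt,

with per-step velocity retention `damping = 0.75`, the convention of the
multi-agent particle environments this arena descends from. Predator
acceleration is `mobility x prey_accel` with mobility 1.2 (fast), 1.0
(equal) or 0.8 (slow); the absolute scale `prey_accel = 4.0` units/s^2 is a
free parameter chosen so that an unopposed agent crosses the arena in about
two seconds (terminal speed a*dt/(1-damping) = 1.6 units/s). Predators pass
through each other (no predator-predator collision).

An episode ends on the first of: capture (any predator-prey centre distance
<= 0.1, inclusive; catcher = the closest contacting predator, ties to the
lowest index), the prey's centre leaving the arena, a predator's centre
leaving, or the time limit; the boundary itself counts as inside, and the
precedence is capture > prey out > predator out > timeout. Rewards: capture
pays the catcher +1 (all predators +1 under shared reward) and the prey -1;
an agent leaving the arena is fined -1; timeouts pay nothing (the prey's
success is recorded in the outcome, not rewarded). A *successful predation*
counts captures plus prey exits; predator exits and timeouts are prey
successes. The study grid crosses predator count (1, 2, 3), mobility and
reward sharing, with sharing collapsing for a single predator: 15 cells.

## Learning agents

Each agent — prey included — learns independently: its own network, target
network, replay memory and optimizer, with the other agents treated as part
of the environment. The state vector contains the agent's absolute position,
its velocity in its own relative frame, and each other agent's relative
position and velocity in that frame (4 + 4(n-1) numbers; the agent's own
relative position, identically zero, is omitted — the exact input list is
one of the under-determined details, so featurization sits behind a single
function). The network is a four-layer MLP: two shared 64-unit ReLU layers,
then 32-unit ReLU value and advantage streams merged by the identifiable
dueling aggregation Q = V + (A - mean A). Training uses double-DQN targets
(online argmax, target evaluation; no bootstrap on terminal transitions),
proportional prioritized replay (capacity 10^4, p_i = |TD| + 1e-6, exponent
alpha = 0.6, importance weights (1/(N P(i)))^beta normalized by the batch
maximum), a Huber loss (threshold 1) weighted by those factors, Adam, and an
epsilon-greedy behavior policy annealed linearly 1 -> 0.1 over the first
10^4 episodes. Choices the source material leaves open, fixed here: beta =
0.4, constant; one gradient step per agent per environment step once the
memory holds one minibatch (32); new transitions enter at the running
maximum priority; sampling uses a cumulative-sum table (at capacity 10^4 a
sum tree buys nothing); greedy ties break to the lowest action index;
weights initialize fan-in-scaled uniform from the run seed.

Full-scale defaults are 10^6 episodes at learning rate 1e-6 with a target
sync every 2000 episodes. The desk-scale configuration used by the test
suite and the analysis scripts (`LearnerConfig.desk()`) runs 2x10^4 episodes
at learning rate 1e-4 — scaled so that lr x episodes matches the full run —
keeping the epsilon anneal and sync cadence at their absolute values. At
this scale the one-predator fast cell reaches a capture-dominated regime
(capture fraction ~0.95 in the last tenth of training; greedy success ~1.0
versus ~0.5 for the uniform-random baseline). Desk scale demonstrates that
learning works, not the asymptotic policies; the full-scale headline numbers
require the full run.

The training loop is compiled (numba) float32 code — physics, featurization,
replay, backprop and Adam fused per step — mirroring the float64 numpy
reference implementations op for op; the suite asserts the two paths agree
(featurization and physics to 1e-12, one full gradient step to float32
tolerance). Everything downstream of a seed is deterministic, so a run is a
pure function of (condition, learner config, seed); checkpoints are taken
every 10% of episodes.

## Rule-based predators

The two-predator rule cascade reproduces role division without learning.
Roles re-derive every step from two distances (distance 1 = predator 1 to
prey, distance 2 = predator 2 to prey, threshold 0.4, ties toward predator
1): the closer predator chases; when the other is closer, predator 1 takes
shortcut (distance 2 < 0.4) or approach, predator 2 takes ambush (distance 2
< 0.4) or chase. Chasing first avoids the arena edge (both |x| and |y| >
0.9: hard turn, 3/11 by orientation; both in (0.8, 0.9]: soft turn, 2/12),
then drives an interior prey outward (prey inside the 0.5 box: 11 CW / 3
CCW; inside the (0.5, 0.6] band: 12 CW / 2 CCW), then aligns heading with
the prey by the signed angle psi between the two velocity vectors (bins at
+/-15 and +/-50 degrees mapping to actions 1/2/3; psi = 0 when either agent
is at rest). Orientation (CW/CCW) comes from a 16-entry lookup table —
quadrant of the prey x signed dominant component of the closer-predator-to-
prey vector — generated from the sign of cross(quadrant diagonal, dominant
direction), which reproduces the published worked example ((0.2, 0.3)
predator, (0.5, 0.2) prey -> CW) and flips under reflection; ties: dominant
component to x, coordinate signs 0 -> +. Ambush holds a blocking station:
the bottom point (-0.1, -0.5) while the prey's y <= 0, else the top point
(0, 0.6) — the printed bottom coordinate (-0.1, +0.5) is treated as a sign
slip, and switching on the prey's hemisphere is the reading under which the
published example (predator (-0.2, 0.8), prey (-0.2, -0.8) -> action 12)
holds. Among the three 120-degree-spaced candidate actions {3, 8, 12} the
ambusher takes the one whose next-step position lands closest to the
station (ties to the lowest number), which at the station itself degenerates
to minimal displacement.

## Behavioral cloning

Two-layer softmax classifiers (32 hidden units, linear or ReLU) are fit by
Adam on cross-entropy to (state, action) pairs logged from rule-based
rollouts, split by episode 1000/100/100 into train/validation/test; the
weights with the best validation accuracy are kept. Full-scale settings:
learning rate 1e-4, batch 32, 2000 epochs. The desk-scale scripts use ~30
epochs, ample for these corpora (~50k transitions; transition counts vary
with the stochastic rollouts). Class imbalance (chase actions dominate) is
left unweighted.

## Analysis statistics

* Success proportion H and mean duration (capped at 30 s), mean +/- SEM
  across seeds; the independence benchmark H_n = 1 - (1 - H_1)^n gives the
  group success expected if n solitary hunters succeeded independently —
  exceeding it indicates synergy.
* Occupancy heat maps: 40x40 equal-width binning of [-1, 1]^2 (numpy
  half-open bins, last edge closed; positions clipped to the arena so counts
  conserve logged steps); map similarity is the product-moment correlation
  of flattened counts (invariant to count-vs-frequency normalization),
  undefined-on-constant-maps flagged as an error.
* Concordance rate: fraction of logged multi-predator decisions the
  solo-trained policy would repeat after deleting the other predators'
  feature blocks (for three predators, both extra blocks).
* Circular correlation of paired action sequences: actions 1-12 map to
  angles at 30-degree spacing, pairs containing action 13 are dropped, and
  the angular-deviation product estimator (sine products about the circular
  means) is computed; the estimator is isolated in one function and
  cross-checked against an independent implementation in the tests.
* Representations: 2D t-SNE (perplexity 30 by default, clamped to
  (n-1)/3 for small samples, PCA initialization, seeded) of the 32-unit
  stream activations, with coloring channels (state value, SD of Q across
  actions, predator-prey distances) clipped at their 5th/95th percentiles.

## The scripted prey

The fixture generator stands in for trained or human prey. The `evasive`
controller flees the nearest predator, adds Gaussian angular noise (sd 20
degrees), and blends in an inward repulsion that ramps up once a coordinate
magnitude passes 0.5 (gain 8): a trained prey is penalized for leaving the
arena and keeps to the interior, and without that interior bias a scripted
prey drags its pursuers across the boundary and episodes end by predator
exits rather than hunting. What the scripted prey does not emulate:
adaptation to the predators' policy, human reaction times, or the odd
still-prey states human players induce. Passing behavioral tests against it
shows the rules and statistics behave as designed, not that the learned
policies would dominate a trained prey.

## Problem sizes and determinism

Desk-scale defaults throughout: 2x10^4 training episodes per seed (3 seeds
in the learning check), 100-200 evaluation or rule-based episodes per
statistic, 1200 cloning episodes, ~30 cloning epochs. All randomness flows
from explicit integer seeds through `numpy` generators (the compiled loop
seeds its own generator per block); reruns with the same seed are
bit-identical.

## Known limitations

* The absolute acceleration scale and drag constant are not pinned by the
  source description; different choices rescale episode kinematics.
* The exact featurization order and the prey's frame reference are fixed
  here by documented choice; alternatives would retrain to similar behavior
  but checkpoints are not interchangeable.
* The CW/CCW and ambush lookup tables are constrained by single worked
  examples; other tables consistent with those examples exist.
* Rule-based predators carry no braking rule beyond the printed edge bands,
  so fast approaches near walls still end some episodes by predator exit.
* Desk-scale training shows learning progress, not converged policies; the
  concordance and embedding analyses of trained networks are therefore
  qualitative at this scale.
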