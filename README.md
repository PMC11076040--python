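# collabhunt

Why do some predators hunt in coordinated roles — one chasing, one cutting
off the escape route — when nothing about the task tells them to? This
package is a desk-scale computational-ethology workbench for that question:
a two-dimensional chase-and-escape arena in which predator and prey agents
either learn independently by deep reinforcement learning or follow fully
specified distance-dependent rules, plus the behavioral statistics that
diagnose collaboration.

## What is in the box

* **Environment** (`collabhunt.env`): continuous-space, discrete-time arena
  [-1, 1]^2, dt = 0.1 s, 30 s episodes; disk agents accelerate in 12
  directions (30-degree spacing, relative frame) or coast; drag dynamics
  `v' = 0.75 v + a dt`; capture / out-of-area / timeout events; individual
  vs shared capture rewards; scripted controllers (pursuit, evasive prey,
  random walks) as data-generating fixtures.
* **Learning** (`collabhunt.agents`, `collabhunt.learning`): per-agent
  dueling double-DQN with prioritized replay — Q = V + (A - mean A), target
  y = r + γ Q_target(s', argmax_a Q_online(s', a)), P(i) ∝ p_i^α with
  p_i = |TD| + ε, importance weights (1/(N P(i)))^β — every agent (prey
  included) trained independently. A numba-compiled loop runs desk-scale
  experiments in minutes on one CPU.
* **Rule-based predators** (`collabhunt.rulebased`): the hand-specified
  chaser/blocker cascade (chase, shortcut, approach, ambush) with all
  thresholds, reproducing role division without learning.
* **Cloning** (`collabhunt.cloning`): one-hidden-layer softmax clones
  (linear and ReLU) of the rule-based predators, fit by cross-entropy.
* **Analysis** (`collabhunt.analysis`): success proportions with the
  independence benchmark H_n = 1 - (1 - H_1)^n, 40x40 occupancy heat maps
  and their correlations, concordance rates against solo policies, circular
  correlation of action angles, t-SNE embeddings of hidden representations.
* **Orchestration** (`collabhunt.experiment`): the greedy evaluation
  protocol (100 episodes x 10 seeds), the 15-cell condition grid, and
  seed-reproducible run artifacts.

The `analysis/` directory holds numbered drivers over the library:
`01_rulebased_roles.py`, `02_train_desk.py`, `03_clone_rules.py`,
`04_embed_representations.py`; each writes tidy tables under `results/`.

## Worked example

```bash
python analysis/01_rulebased_roles.py --seed 0
```

```
                          metric    value  seed  episodes
            two_predator_success 0.555000     0       200
    two_predator_mean_duration_s 4.787000     0       200
                    solo_success 0.315000     0       200
       independence_benchmark_h2 0.530775     0       200
       synergy_over_independence 0.024225     0       200
           chaser_prey_heatmap_r 0.307463     0       200
          blocker_prey_heatmap_r 0.180208     0       200
blocker_modal_bin_dist_to_ambush 0.215058     0       200
           chaser_movement_share 0.516552     0       200
       chaser_blocker_circular_r 0.743955     0       200
```

Reading it: two slow rule-based predators catch the evasive prey in 55.5%
of 200 hunts, while solitary hunts succeed 31.5% of the time — so two
*independent* hunters would reach only H_2 = 1 - (1 - 0.315)^2 = 53.1%.
The division of labour shows up spatially: the chaser's occupancy map
correlates with the prey's (r = 0.31) far more than the blocker's
(r = 0.18), and the blocker's most-occupied cell sits next to its ambush
station near the top/bottom centre of the arena.

Training a learner from scratch (one fast predator vs a learning prey):

```bash
python analysis/02_train_desk.py --seed 0 --episodes 20000
```

prints the capture fraction over the last tenth of training and the greedy
evaluation success against the random-policy baseline, and saves the
weights under `results/desk_run/` for the embedding script.

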