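#!/usr/bin/env python
"""Desk-scale independent-learner training in the one-predator fast cell.

Trains predator and prey networks from scratch (2x10^4 episodes by default,
learning rate scaled up to 1e-4 to compensate for the shortened run), then
evaluates the greedy policies against the random-policy baseline. Saves the
run (weights + log + manifest) under results/desk_run/ for the
representation script.
"""

import argparse
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from collabhunt.env import ConditionConfig  # noqa: E402
from collabhunt.experiment import EvaluationProtocol, evaluate, save_run  # noqa: E402
from collabhunt.learning import LearnerConfig, train  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--episodes", type=int, default=20_000)
    parser.add_argument("--outdir", type=pathlib.Path,
                        default=pathlib.Path(__file__).resolve().parents[1] / "results")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cond = ConditionConfig.from_names(1, "fast", "individual")
    learner = LearnerConfig.desk(total_episodes=args.episodes)
    print(f"training 1 predator (fast) vs prey for {args.episodes} episodes ...")
    result = train(cond, learner, seed=args.seed)
    result.log.to_csv(args.outdir / "desk_training_log.csv", index=False)
    save_run(args.outdir / "desk_run", result)

    protocol = EvaluationProtocol(cond, episodes_per_seed=100, n_seeds=3)
    _, trained = evaluate(result.params, protocol, base_seed=args.seed + 1)
    _, base = evaluate(["uniform_random", "uniform_random"], protocol,
                       base_seed=args.seed + 1)

    tail = result.log.tail(args.episodes // 10)
    print(f"last tenth of training: capture fraction "
          f"{(tail['event'] == 'capture').mean():.2f}, "
          f"mean episode length {tail['length'].mean():.1f} steps")
    print(f"greedy evaluation success:  trained {trained.success_proportion:.2f} "
          f"(mean duration {trained.mean_duration:.1f} s)")
    print(f"random-policy baseline:     {base.success_proportion:.2f} "
          f"(mean duration {base.mean_duration:.1f} s)")
    print(f"artifacts in {args.outdir}/desk_run")


if __name__ == "__main__":
    main()
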