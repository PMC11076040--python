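#!/usr/bin/env python
"""Behavioral cloning of the rule-based chaser into two-layer softmax nets.

Regenerates rule-based corpora (1000 train / 100 validation / 100 test
episodes against the scripted evasive prey), fits the linear and nonlinear
(ReLU) clone variants, and reports per-split accuracies against the 1/13
chance level. Writes results/clone_report.csv.
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from collabhunt.cloning import CloneConfig, dataset_from_records, train_clone  # noqa: E402
from collabhunt.env import ConditionConfig, rollout  # noqa: E402
from collabhunt.rulebased import make_rulebased_policies  # noqa: E402
from collabhunt.scripted import get_policy  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--epochs", type=int, default=30,
                        help="training epochs (full-scale setting is 2000)")
    parser.add_argument("--agent", type=int, default=0, choices=(0, 1))
    parser.add_argument("--outdir", type=pathlib.Path,
                        default=pathlib.Path(__file__).resolve().parents[1] / "results")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = ConditionConfig.from_names(2, "slow", "shared")
    rng = np.random.default_rng(args.seed)
    policies = make_rulebased_policies() + [get_policy("evasive")]
    print("simulating 1200 rule-based episodes ...")
    records = [rollout(policies, cfg, rng, episode_id=i) for i in range(1200)]
    ds = dataset_from_records(records, agent=args.agent, config=cfg,
                              n_train=1000, n_val=100, n_test=100)
    print(f"corpus: {len(ds.train_x)} / {len(ds.val_x)} / {len(ds.test_x)} transitions")

    rows = []
    clone_cfg = CloneConfig(epochs=args.epochs)
    for variant in ("linear", "relu"):
        _, report = train_clone(ds, variant, clone_cfg, seed=args.seed)
        rows.append({k: report[k] for k in
                     ("variant", "train_accuracy", "val_accuracy", "test_accuracy",
                      "best_epoch", "n_train", "n_val", "n_test")})
        print(f"{variant:>6}: test accuracy {report['test_accuracy']:.3f} "
              f"(chance 1/13 = {1 / 13:.3f})")
    table = pd.DataFrame(rows)
    table["agent"] = args.agent
    table["seed"] = args.seed
    table.to_csv(args.outdir / "clone_report.csv", index=False)


if __name__ == "__main__":
    main()
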