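#!/usr/bin/env python
"""Role division in rule-based hunts (two slow predators, shared reward).

Rolls out the chaser/blocker rule cascade against the scripted evasive prey,
then measures the signatures of collaboration: the chaser's occupancy heat
map should track the prey's while the blocker camps near the top/bottom
ambush points, and two-predator success should exceed the independence
benchmark H_2 = 1 - (1 - H_1)^2 built from solitary hunts.

Writes results/rulebased_roles.csv (one row per metric) and prints a short
report.
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from collabhunt.analysis import (  # noqa: E402
    circular_correlation,
    distance_moved_ratio,
    heat_map,
    heatmap_correlation,
    modal_bin_center,
    summarize_outcomes,
    theoretical_prediction,
)
from collabhunt.env import ConditionConfig, rollout, save_records_csv  # noqa: E402
from collabhunt.rulebased import RuleConfig, make_rulebased_policies, make_solo_chase_policy  # noqa: E402
from collabhunt.scripted import get_policy  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--episodes", type=int, default=200)
    parser.add_argument("--outdir", type=pathlib.Path,
                        default=pathlib.Path(__file__).resolve().parents[1] / "results")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg2 = ConditionConfig.from_names(2, "slow", "shared")
    rng = np.random.default_rng(args.seed)
    policies = make_rulebased_policies() + [get_policy("evasive")]
    records = [rollout(policies, cfg2, rng, episode_id=i) for i in range(args.episodes)]
    summary = summarize_outcomes(records)

    maps = {a: heat_map(records, a) for a in range(3)}
    r_chaser = heatmap_correlation(maps[0], maps[2])
    r_blocker = heatmap_correlation(maps[1], maps[2])
    rule_cfg = RuleConfig()
    modal = modal_bin_center(maps[1])
    ambush_dist = min(
        float(np.linalg.norm(modal - np.asarray(rule_cfg.bottom_point))),
        float(np.linalg.norm(modal - np.asarray(rule_cfg.top_point))),
    )
    shares = distance_moved_ratio(records)
    circ = circular_correlation(
        np.concatenate([r.actions(0) for r in records]),
        np.concatenate([r.actions(1) for r in records]),
    )

    cfg1 = ConditionConfig.from_names(1, "slow", "individual")
    rng1 = np.random.default_rng(args.seed + 1)
    solo = [make_solo_chase_policy(), get_policy("evasive")]
    solo_records = [rollout(solo, cfg1, rng1, episode_id=i) for i in range(args.episodes)]
    h1 = summarize_outcomes(solo_records).success_proportion
    h2_theory = theoretical_prediction(h1, 2)

    rows = [
        ("two_predator_success", summary.success_proportion),
        ("two_predator_mean_duration_s", summary.mean_duration),
        ("solo_success", h1),
        ("independence_benchmark_h2", h2_theory),
        ("synergy_over_independence", summary.success_proportion - h2_theory),
        ("chaser_prey_heatmap_r", r_chaser),
        ("blocker_prey_heatmap_r", r_blocker),
        ("blocker_modal_bin_dist_to_ambush", ambush_dist),
        ("chaser_movement_share", float(shares[0])),
        ("chaser_blocker_circular_r", circ),
    ]
    table = pd.DataFrame(rows, columns=["metric", "value"])
    table["seed"] = args.seed
    table["episodes"] = args.episodes
    table.to_csv(args.outdir / "rulebased_roles.csv", index=False)
    save_records_csv(records[:10], args.outdir / "rulebased_example_episodes.csv")

    print(table.to_string(index=False))
    print()
    print(
        f"Two slow rule-based predators succeed in {summary.success_proportion:.0%} "
        f"of hunts vs {h2_theory:.0%} expected from independent solitary hunters "
        f"(H1 = {h1:.0%}): the blocker's station-keeping near "
        f"({rule_cfg.bottom_point}/{rule_cfg.top_point}) pays off."
    )
    print(
        f"Occupancy correlation with the prey: chaser r = {r_chaser:.2f}, "
        f"blocker r = {r_blocker:.2f}; blocker modal bin sits "
        f"{ambush_dist:.2f} length units from an ambush point."
    )


if __name__ == "__main__":
    main()
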