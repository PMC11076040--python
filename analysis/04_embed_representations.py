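#!/usr/bin/env python
"""t-SNE embedding of the trained network's hidden representations.

Loads the run saved by 02_train_desk.py, replays greedy episodes, extracts
the 32-unit value- and advantage-stream activations of the predator for
every visited state, embeds them in 2D, and writes the coordinates together
with the coloring channels (state value, SD of the Q values,
predator-to-prey distance, all clipped at the 5th/95th percentiles) to
results/embedding.csv.
"""

import argparse
import pathlib
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from collabhunt.agents import build_state_vector, extract_hidden, make_greedy_policy  # noqa: E402
from collabhunt.analysis import embed_representations, q_channels  # noqa: E402
from collabhunt.env import WorldState, rollout  # noqa: E402
from collabhunt.experiment import load_run  # noqa: E402


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--episodes", type=int, default=30)
    parser.add_argument("--run", type=pathlib.Path,
                        default=pathlib.Path(__file__).resolve().parents[1]
                        / "results" / "desk_run")
    parser.add_argument("--outdir", type=pathlib.Path,
                        default=pathlib.Path(__file__).resolve().parents[1] / "results")
    args = parser.parse_args()
    if not args.run.exists():
        sys.exit(f"no saved run at {args.run}; run analysis/02_train_desk.py first")
    args.outdir.mkdir(parents=True, exist_ok=True)

    params, cond, _, _ = load_run(args.run)
    rng = np.random.default_rng(args.seed)
    policies = [make_greedy_policy(p, cond) for p in params]
    records = [rollout(policies, cond, rng, episode_id=i) for i in range(args.episodes)]

    states, dists = [], []
    for rec in records:
        tab = rec.table.sort_values(["step", "agent_id"])
        arr = tab[["x", "y", "vx", "vy"]].to_numpy().reshape(-1, cond.n_agents, 4)
        for t in range(arr.shape[0]):
            world = WorldState(arr[t, :, :2], arr[t, :, 2:], t, cond.n_predators)
            states.append(build_state_vector(world, 0, cond))
            dists.append(np.linalg.norm(arr[t, 0, :2] - arr[t, cond.prey_index, :2]))
    states = np.asarray(states)
    print(f"{len(states)} predator states from {args.episodes} greedy episodes")

    hv, ha = extract_hidden(params[0], states)
    channels = q_channels(params[0], states)
    channels["predator_prey_distance"] = np.asarray(dists)
    for stream, hidden in (("value", hv), ("advantage", ha)):
        table = embed_representations(hidden, channels, seed=args.seed)
        frame = pd.DataFrame(table.coords, columns=["tsne_1", "tsne_2"])
        frame = pd.concat([frame, table.channels], axis=1)
        frame["stream"] = stream
        out = args.outdir / f"embedding_{stream}.csv"
        frame.to_csv(out, index=False)
        print(f"{stream} stream -> {out}; clip bounds: "
              + ", ".join(f"{k} [{lo:.2f}, {hi:.2f}]"
                          for k, (lo, hi) in table.clip_bounds.items()))


if __name__ == "__main__":
    main()
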