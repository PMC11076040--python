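"""Study orchestration: the evaluation protocol, the condition grid, and
artifact round-tripping.

Evaluation runs the greedy policies (epsilon = 0) over a grid of seeds; each
seed controls only the initial positions, so re-running with the same
checkpoints and seeds reproduces the summary exactly. The full study grid
crosses predator count (1, 2, 3) with relative mobility (fast, equal, slow)
and reward sharing (individual, shared), the sharing factor collapsing in
the one-predator cells: 15 cells in total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scripted
from .agents import PolicyParams, make_greedy_policy
from .analysis import OutcomeSummary, summarize_outcomes
from .env import ConditionConfig, EpisodeRecord, rollout
from .learning import LearnerConfig, TrainResult, train
from .rulebased import RuleConfig, make_rulebased_policies

MOBILITY_NAMES = ("fast", "equal", "slow")
SHARING_NAMES = ("individual", "shared")


@dataclass(frozen=True)
class EvaluationProtocol:
    """Greedy evaluation grid: episodes_per_seed x n_seeds episodes."""

    condition: ConditionConfig
    episodes_per_seed: int = 100
    n_seeds: int = 10
    eps_eval: float = 0.0

    def __post_init__(self) -> None:
        if self.eps_eval != 0.0:
            raise ValueError("evaluation is defined as greedy (eps_eval = 0)")
        if self.episodes_per_seed < 1 or self.n_seeds < 1:
            raise ValueError("episode and seed counts must be positive")


def resolve_policy(spec, config: ConditionConfig):
    """Turn a policy spec into a rollout callable.

    Accepts trained weights (PolicyParams), the string ``"rulebased"`` (the
    two-predator rule cascade; returns the shared policy), a scripted
    controller name, or any callable.
    """
    if isinstance(spec, PolicyParams):
        return make_greedy_policy(spec, config)
    if isinstance(spec, str) and spec == "rulebased":
        return make_rulebased_policies(RuleConfig())[0]
    return scripted.get_policy(spec)


def evaluate(
    policies,
    protocol: EvaluationProtocol,
    base_seed: int = 0,
) -> tuple[list[EpisodeRecord], OutcomeSummary]:
    """Run the seeds x episodes grid with greedy actions.

    ``policies`` holds one spec per agent slot (predators first, prey last).
    Seeds are ``base_seed .. base_seed + n_seeds - 1`` and control initial
    positions (and any scripted-policy noise); greedy networks and the rule
    cascade contribute no randomness.
    """
    config = protocol.condition
    if len(policies) != config.n_agents:
        raise ValueError(
            f"need {config.n_agents} policies (got {len(policies)}) for this condition"
        )
    resolved = [resolve_policy(p, config) for p in policies]
    records = []
    eid = 0
    for s in range(protocol.n_seeds):
        seed = base_seed + s
        rng = np.random.default_rng(seed)
        for _ in range(protocol.episodes_per_seed):
            rec = rollout(resolved, config, rng, episode_id=eid, seed=seed)
            records.append(rec)
            eid += 1
    return records, summarize_outcomes(records)


def condition_grid(**config_overrides) -> list[ConditionConfig]:
    """The 15 study cells: 3 predator counts x 3 mobilities x 2 sharings,
    with sharing collapsed (to 'individual') when there is a single predator."""
    cells = []
    for n in (1, 2, 3):
        for mob in MOBILITY_NAMES:
            sharings = ("individual",) if n == 1 else SHARING_NAMES
            for sh in sharings:
                cells.append(ConditionConfig.from_names(n, mob, sh, **config_overrides))
    return cells


def grid_manifest(conditions: list[ConditionConfig]) -> pd.DataFrame:
    inv_mob = {v: k for k, v in zip(MOBILITY_NAMES, (1.2, 1.0, 0.8))}
    return pd.DataFrame(
        {
            "n_predators": [c.n_predators for c in conditions],
            "mobility": [inv_mob[c.mobility] for c in conditions],
            "sharing": [c.sharing for c in conditions],
            "config_hash": [c.config_hash() for c in conditions],
        }
    )


def run_condition_grid(
    conditions: list[ConditionConfig],
    learner: LearnerConfig,
    protocol_kw: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Train and greedily evaluate every cell; returns a tidy result table.

    Each cell trains with a seed derived from ``seed`` and its position in
    the grid, then evaluates under the protocol (desk-scale callers shrink
    ``episodes_per_seed``/``n_seeds`` through ``protocol_kw``).
    """
    protocol_kw = protocol_kw or {}
    rows = []
    for k, condition in enumerate(conditions):
        result = train(condition, learner, seed=seed + k)
        protocol = EvaluationProtocol(condition, **protocol_kw)
        _, summary = evaluate(result.params, protocol, base_seed=seed)
        rows.append(
            {
                "n_predators": condition.n_predators,
                "mobility": condition.mobility,
                "sharing": condition.sharing,
                "seed": seed + k,
                "success_proportion": summary.success_proportion,
                "sem_success": summary.sem_success,
                "mean_duration": summary.mean_duration,
                "sem_duration": summary.sem_duration,
                "n_episodes": summary.n_episodes,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# artifact round-trips
# ---------------------------------------------------------------------------

def save_run(path, result: TrainResult) -> None:
    """Persist a training run: weights + log + configs, keyed by config hash."""
    import pathlib

    path = pathlib.Path(path)
    path.mkdir(parents=True, exist_ok=True)
    from .agents import save_checkpoint

    save_checkpoint(path / "weights.npz", result.params, result.condition,
                    int(result.learner.total_episodes))
    result.log.to_csv(path / "train_log.csv", index=False)
    manifest = {
        "config": result.condition.to_dict(),
        "config_hash": result.condition.config_hash(),
        "learner": {k: getattr(result.learner, k) for k in (
            "gamma", "alpha", "beta", "lr", "batch", "memory_size",
            "target_sync_every", "total_episodes", "eps_start", "eps_final",
            "eps_anneal_episodes", "priority_floor")},
        "seed": result.seed,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def load_run(path) -> tuple[list[PolicyParams], ConditionConfig, LearnerConfig, int]:
    """Reload a saved run; raises if the weights don't match the manifest config."""
    import pathlib

    path = pathlib.Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    condition = ConditionConfig(**manifest["config"])
    if condition.config_hash() != manifest["config_hash"]:
        raise ValueError("manifest config hash mismatch")
    from .agents import load_checkpoint

    params, _ = load_checkpoint(path / "weights.npz", condition)
    learner = LearnerConfig(**manifest["learner"])
    return params, condition, learner, int(manifest["seed"])
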