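"""Evaluation and behavioral statistics over episode records and network
internals.

Success accounting follows the hunt's framing: a predation is successful
when a predator captures the prey or the prey flees the arena; the prey wins
on timeout or when a predator leaves. The synergy benchmark for n predators
hunting independently is H_n = 1 - (1 - H_1)^n, so group success above that
curve indicates genuine cooperation rather than more lottery tickets.

Spatial behavior is summarized by 40x40 occupancy heat maps over the arena
and their product-moment correlations (a chaser's map tracks the prey's; a
blocker's does not). Decision similarity uses the concordance rate against a
solo-trained policy and the circular correlation between discrete action
angles (actions 1-12 at 30-degree spacing; action 13 is excluded). Hidden
representations are embedded in 2D with t-SNE, with display channels clipped
at the 5th/95th percentiles.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .agents import PolicyParams, build_state_vector, forward, greedy_action
from .env import (
    PREDATOR_SUCCESS_EVENTS,
    ConditionConfig,
    EpisodeRecord,
    WorldState,
)


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

@dataclass
class OutcomeSummary:
    success_proportion: float  # H: fraction of episodes won by the predators
    mean_duration: float  # seconds, capped at the episode time limit
    sem_success: float  # SEM across seeds
    sem_duration: float
    per_seed: pd.DataFrame  # seed, n_episodes, success_proportion, mean_duration
    n_episodes: int


def episodes_table(records: list[EpisodeRecord]) -> pd.DataFrame:
    """Tidy per-episode outcome table (episode_id, seed, outcome, duration)."""
    return pd.DataFrame(
        {
            "episode_id": [r.episode_id for r in records],
            "seed": [r.seed if r.seed is not None else 0 for r in records],
            "outcome": [r.outcome for r in records],
            "duration": [r.duration for r in records],
        }
    )


def summarize_outcomes(records: list[EpisodeRecord]) -> OutcomeSummary:
    """Success proportion and mean duration, mean +/- SEM across seeds."""
    if not records:
        raise ValueError("no episodes to summarize")
    tab = episodes_table(records)
    tab["success"] = tab["outcome"].isin(PREDATOR_SUCCESS_EVENTS)
    per_seed = (
        tab.groupby("seed")
        .agg(
            n_episodes=("episode_id", "size"),
            success_proportion=("success", "mean"),
            mean_duration=("duration", "mean"),
        )
        .reset_index()
    )
    k = len(per_seed)
    sem = lambda x: float(np.std(x, ddof=1) / math.sqrt(k)) if k > 1 else 0.0
    return OutcomeSummary(
        success_proportion=float(tab["success"].mean()),
        mean_duration=float(tab["duration"].mean()),
        sem_success=sem(per_seed["success_proportion"]),
        sem_duration=sem(per_seed["mean_duration"]),
        per_seed=per_seed,
        n_episodes=len(tab),
    )


def theoretical_prediction(h1: float, n: int) -> float:
    """Expected group success H_n = 1 - (1 - H_1)^n under independence."""
    if not (0.0 <= h1 <= 1.0):
        raise ValueError("h1 must be a proportion in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return 1.0 - (1.0 - h1) ** n


# ---------------------------------------------------------------------------
# occupancy heat maps
# ---------------------------------------------------------------------------

@dataclass
class HeatMap:
    counts: np.ndarray  # (bins, bins) integer counts, [0]=x axis, [1]=y axis
    agent_id: int
    n_episodes: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def heat_map(records: list[EpisodeRecord], agent: int, bins: int = 40,
             half_width: float = 1.0) -> HeatMap:
    """Occupancy counts on an equal-width grid over the arena.

    Bins are half-open with the final edge closed (numpy histogram
    convention); positions are clipped to the arena so every logged step is
    counted once.
    """
    xs, ys = [], []
    for rec in records:
        p = rec.positions(agent)
        xs.append(p[:, 0])
        ys.append(p[:, 1])
    x = np.clip(np.concatenate(xs), -half_width, half_width)
    y = np.clip(np.concatenate(ys), -half_width, half_width)
    counts, _, _ = np.histogram2d(x, y, bins=bins, range=[[-half_width, half_width]] * 2)
    return HeatMap(counts.astype(np.int64), agent, len(records))


def heatmap_correlation(a: HeatMap, b: HeatMap) -> float:
    """Product-moment correlation of the flattened count vectors."""
    x = a.counts.ravel().astype(float)
    y = b.counts.ravel().astype(float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("heat-map correlation undefined for a constant map")
    return float(np.corrcoef(x, y)[0, 1])


def modal_bin_center(hm: HeatMap, half_width: float = 1.0) -> np.ndarray:
    """Arena coordinates of the most-occupied bin's centre."""
    bins = hm.counts.shape[0]
    i, j = np.unravel_index(np.argmax(hm.counts), hm.counts.shape)
    w = 2 * half_width / bins
    return np.array([-half_width + (i + 0.5) * w, -half_width + (j + 0.5) * w])


# ---------------------------------------------------------------------------
# decision similarity
# ---------------------------------------------------------------------------

def solo_state_vector(world: WorldState, agent: int, solo_config: ConditionConfig) -> np.ndarray:
    """Project a multi-predator state onto the solo featurization by deleting
    every other predator, keeping this predator and the prey."""
    pos = np.stack([world.pos[agent], world.pos[world.prey_index]])
    vel = np.stack([world.vel[agent], world.vel[world.prey_index]])
    reduced = WorldState(pos, vel, world.step, 1)
    return build_state_vector(reduced, 0, solo_config)


def concordance_rate(
    records: list[EpisodeRecord],
    solo_policy: PolicyParams,
    config: ConditionConfig,
    agent: int | None = None,
) -> float:
    """Fraction of logged predator decisions the solo-trained policy would
    repeat in the same (projected) situation.

    ``agent`` restricts the comparison to one predator; default pools all.
    """
    solo_config = ConditionConfig(
        n_predators=1, mobility=config.mobility, sharing=config.sharing,
        dt=config.dt, time_limit=config.time_limit,
        arena_half_width=config.arena_half_width, agent_diameter=config.agent_diameter,
        init_range=config.init_range, prey_accel=config.prey_accel, damping=config.damping,
    )
    if solo_policy.state_dim != solo_config.state_dim:
        raise ValueError("solo policy featurization does not match the solo condition")
    agents_to_check = range(config.n_predators) if agent is None else [agent]
    matches, total = 0, 0
    for rec in records:
        tab = rec.table.sort_values(["step", "agent_id"])
        arr = tab[["x", "y", "vx", "vy", "action"]].to_numpy(dtype=float)
        arr = arr.reshape(-1, config.n_agents, 5)
        for t in range(arr.shape[0]):
            world = WorldState(arr[t, :, 0:2], arr[t, :, 2:4], t, config.n_predators)
            for i in agents_to_check:
                s = solo_state_vector(world, i, solo_config)
                predicted = greedy_action(forward(solo_policy, s).Q)
                matches += int(predicted == int(arr[t, i, 4]))
                total += 1
    if total == 0:
        raise ValueError("no logged decisions to compare")
    return matches / total


def action_angles_rad(actions: np.ndarray) -> np.ndarray:
    """Movement actions 1-12 as angles 0-330 degrees (returned in radians)."""
    return np.radians((np.asarray(actions, dtype=float) - 1.0) * 30.0)


def circular_correlation(actions_a, actions_b) -> float:
    """Circular correlation between two paired discrete action sequences.

    Pairs where either entry is action 13 (do nothing) are dropped; the
    remaining actions map to angles at 30-degree spacing. Uses the
    angular-deviation product estimator

        r = sum sin(t - tbar) sin(p - pbar)
            / sqrt(sum sin^2(t - tbar) * sum sin^2(p - pbar))

    with circular means tbar, pbar. Returns nan when one sequence has no
    angular dispersion.
    """
    a = np.asarray(actions_a)
    b = np.asarray(actions_b)
    if a.shape != b.shape:
        raise ValueError("sequences must be paired")
    keep = (a != 13) & (b != 13)
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least 2 valid pairs")
    theta = action_angles_rad(a)
    phi = action_angles_rad(b)
    tbar = math.atan2(np.sin(theta).mean(), np.cos(theta).mean())
    pbar = math.atan2(np.sin(phi).mean(), np.cos(phi).mean())
    st = np.sin(theta - tbar)
    sp = np.sin(phi - pbar)
    denom = math.sqrt(float(np.sum(st**2)) * float(np.sum(sp**2)))
    if denom == 0.0:
        return float("nan")
    return float(np.sum(st * sp) / denom)


# ---------------------------------------------------------------------------
# representation embedding
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingTable:
    coords: np.ndarray  # (n, 2) t-SNE coordinates
    channels: pd.DataFrame  # per-state coloring channels
    clip_bounds: dict  # channel -> (5th, 95th percentile)
    perplexity: float
    seed: int


def percentile_clip_bounds(values: np.ndarray, lo: float = 5.0, hi: float = 95.0) -> tuple:
    return (float(np.percentile(values, lo)), float(np.percentile(values, hi)))


def embed_representations(
    hidden_vectors: np.ndarray,
    channels: dict[str, np.ndarray] | None = None,
    perplexity: float = 30.0,
    seed: int = 0,
) -> EmbeddingTable:
    """2D t-SNE embedding of hidden activations with percentile-clipped
    display channels (state value, SD of Q across actions, distances)."""
    from sklearn.manifold import TSNE

    x = np.asarray(hidden_vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two hidden vectors")
    if np.allclose(x, x[0]):
        raise ValueError("degenerate input: all hidden vectors identical")
    channels = channels or {}
    eff_perplexity = min(perplexity, max(1.0, (x.shape[0] - 1) / 3.0))
    coords = TSNE(
        n_components=2, perplexity=eff_perplexity, random_state=seed, init="pca"
    ).fit_transform(x)
    frame = pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in channels.items()})
    bounds = {k: percentile_clip_bounds(frame[k].to_numpy()) for k in frame.columns}
    return EmbeddingTable(coords, frame, bounds, eff_perplexity, seed)


def q_channels(params: PolicyParams, states: np.ndarray) -> dict[str, np.ndarray]:
    """Standard coloring channels from a policy network: V and SD of Q."""
    out = forward(params, np.asarray(states, dtype=float))
    return {"state_value": out.V, "sd_q": out.Q.std(axis=1)}


# ---------------------------------------------------------------------------
# movement shares
# ---------------------------------------------------------------------------

def distance_moved_ratio(records: list[EpisodeRecord]) -> np.ndarray:
    """Each predator's share of the total predator path length during hunts."""
    if not records:
        raise ValueError("no episodes")
    n_pred = int(records[0].table.query("role == 'predator'")["agent_id"].nunique())
    if n_pred < 2:
        raise ValueError("movement shares need at least 2 predators")
    totals = np.zeros(n_pred)
    for rec in records:
        for i in range(n_pred):
            p = rec.positions(i)
            if len(p) > 1:
                totals[i] += float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
    grand = totals.sum()
    if grand == 0:
        raise ValueError("no movement logged")
    return totals / grand
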