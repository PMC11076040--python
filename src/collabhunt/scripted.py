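"""Scripted (non-learning) controllers and fixture-episode generation.

These controllers stand in for trained or human players when the analysis
stages need deterministic, cheap-to-generate trajectories: a pure-pursuit
predator, a stationary or straight-line prey, random walkers, and an evasive
prey that flees the nearest predator with wall avoidance and tunable angular
noise.

Controllers share one calling convention with every other policy in the
package: ``controller(state, agent, config, rng) -> action in 1..13``.
"""

from __future__ import annotations

import math

import numpy as np

from .env import (
    COAST_ACTION,
    ConditionConfig,
    EpisodeRecord,
    WorldState,
    nearest_action,
    rollout,
)


def pursuit(state: WorldState, agent: int, config: ConditionConfig, rng) -> int:
    """Accelerate straight at the reference opponent (action 1)."""
    return 1


def still(state: WorldState, agent: int, config: ConditionConfig, rng) -> int:
    """Coast forever (action 13)."""
    return COAST_ACTION


def uniform_random(state: WorldState, agent: int, config: ConditionConfig, rng) -> int:
    return int(rng.integers(1, 14))


def make_straight_line(heading_deg: float = 0.0):
    """Prey that accelerates along a fixed absolute heading every step."""
    direction = np.array([math.cos(math.radians(heading_deg)), math.sin(math.radians(heading_deg))])

    def controller(state: WorldState, agent: int, config: ConditionConfig, rng) -> int:
        return nearest_action(direction, state, agent)

    return controller


def make_random_walk(turn_sd_deg: float = 45.0, seed_heading_deg: float = 0.0):
    """Persistent random walker: the desired heading diffuses by a Gaussian
    angular increment each step."""
    heading = {"deg": seed_heading_deg}

    def controller(state: WorldState, agent: int, config: ConditionConfig, rng) -> int:
        heading["deg"] += float(rng.normal(0.0, turn_sd_deg))
        d = np.array([math.cos(math.radians(heading["deg"])), math.sin(math.radians(heading["deg"]))])
        return nearest_action(d, state, agent)

    return controller


def make_evasive(noise_sd_deg: float = 20.0, wall_margin: float = 0.5,
                 wall_gain: float = 8.0):
    """Prey that flees the nearest predator while staying off the walls.

    The desired direction is away from the nearest predator plus an inward
    repulsion that ramps up linearly once |coordinate| exceeds
    ``wall_margin``; Gaussian angular noise (sd ``noise_sd_deg``) is then
    applied. The defaults emulate a trained prey, which is penalised for
    leaving the arena and therefore keeps to the interior rather than
    trading its life for distance; a larger margin or weaker gain produces
    wall-hugging flight that ends episodes by somebody crossing the
    boundary.
    """

    def controller(state: WorldState, agent: int, config: ConditionConfig, rng) -> int:
        p = state.pos[agent]
        d_pred = np.linalg.norm(state.pos[: state.n_predators] - p, axis=1)
        nearest = int(np.argmin(d_pred))
        flee = p - state.pos[nearest]
        n = np.linalg.norm(flee)
        flee = flee / n if n > 1e-12 else np.array([1.0, 0.0])
        for k in range(2):
            overshoot = abs(p[k]) - wall_margin
            if overshoot > 0:
                flee[k] -= math.copysign(1.0, p[k]) * wall_gain * overshoot / (1.0 - wall_margin)
        n = np.linalg.norm(flee)
        flee = flee / n if n > 1e-12 else np.array([1.0, 0.0])
        if noise_sd_deg > 0:
            a = math.radians(float(rng.normal(0.0, noise_sd_deg)))
            c, s = math.cos(a), math.sin(a)
            flee = np.array([c * flee[0] - s * flee[1], s * flee[0] + c * flee[1]])
        return nearest_action(flee, state, agent)

    return controller


#: registry of parameter-free controllers addressable by name
NAMED_POLICIES = {
    "pursuit": pursuit,
    "still": still,
    "stationary": still,
    "uniform_random": uniform_random,
}


def get_policy(spec):
    """Resolve a policy spec: a callable passes through; a string looks up
    the registry, with ``evasive``, ``straight_line`` and ``random_walk``
    accepting an optional ``:<parameter>`` suffix."""
    if callable(spec):
        return spec
    if not isinstance(spec, str):
        raise ValueError(f"policy spec must be a name or callable, got {type(spec)}")
    name, _, arg = spec.partition(":")
    if name in NAMED_POLICIES:
        return NAMED_POLICIES[name]
    if name == "evasive":
        return make_evasive(float(arg) if arg else 20.0)
    if name == "straight_line":
        return make_straight_line(float(arg) if arg else 0.0)
    if name == "random_walk":
        return make_random_walk(float(arg) if arg else 45.0)
    raise ValueError(f"unknown policy name {spec!r}")


def generate_scripted_episode(
    policy_spec,
    config: ConditionConfig,
    rng: np.random.Generator,
    episode_id: int = 0,
) -> EpisodeRecord:
    """Run one episode under named scripted controllers and log it.

    ``policy_spec`` is a sequence of policy names/callables, one per agent
    (predators first, prey last). Reproducible given the generator state.
    """
    policies = [get_policy(s) for s in policy_spec]
    return rollout(policies, config, rng, episode_id=episode_id)
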