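"""Hand-specified two-predator policies: chaser and ambusher roles.

These distance-dependent rules reproduce collaborative hunting without any
learning. Each step both predators compare their distances to the prey
(distance 1 = predator 1 to prey, distance 2 = predator 2 to prey) and branch:

* predator 1 (index 0): chase when it is the closer predator; otherwise
  shortcut (cut the corner, distance 2 < threshold) or approach (head
  straight in, distance 2 >= threshold);
* predator 2 (index 1): chase when it is the closer predator; otherwise
  ambush (hold a blocking point at the top or bottom centre of the arena,
  distance 2 < threshold) or chase.

All actions are expressed in the relative frame used everywhere else
(action 1 = toward the prey). Chasing predators first avoid the arena edge,
then try to drive an interior prey outward, then align their heading with
the prey's; the circling direction (CW/CCW) comes from a quadrant lookup
table. The policies are deterministic and memoryless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .env import ConditionConfig, WorldState, frame_axes

CW = "CW"
CCW = "CCW"

CHASE = "chase"
SHORTCUT = "shortcut"
APPROACH = "approach"
AMBUSH = "ambush"


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds of the rule cascade (arena length units / degrees)."""

    distance_threshold: float = 0.4
    outer_edge: float = 0.9  # |x| and |y| beyond this: hard edge avoidance
    inner_edge: float = 0.8  # (inner_edge, outer_edge]: soft edge avoidance
    prey_inside: float = 0.5  # prey within this box: drive it outward
    prey_band: float = 0.6  # (prey_inside, prey_band]: softer drive-out
    psi_bins: tuple = (-50.0, -15.0, 15.0, 50.0)  # degrees
    psi_actions: tuple = (3, 2, 1, 2, 3)
    bottom_point: tuple = (-0.1, -0.5)
    top_point: tuple = (0.0, 0.6)
    ambush_actions: tuple = (3, 8, 12)


def _sgn(x: float) -> int:
    """Sign with zero counted as positive (documented tie-break)."""
    return 1 if x >= 0 else -1


def _build_orientation_table() -> dict:
    """Quadrant-of-prey x dominant-relative-component -> CW/CCW.

    Generated from the sign of cross(quadrant diagonal, dominant direction):
    with the prey in quadrant (cx, cy) and the closer-predator-to-prey vector
    dominated by a signed axis direction d, the motion is clockwise when
    cx*dy - cy*dx < 0. This generator reproduces the worked example
    (closer predator (0.2, 0.3), prey (0.5, 0.2) -> CW) and flips under
    reflection, and is frozen here as an explicit table.
    """
    table = {}
    for cx in (1, -1):
        for cy in (1, -1):
            for axis in ("x", "y"):
                for s in (1, -1):
                    dx, dy = (s, 0) if axis == "x" else (0, s)
                    table[(cx, cy, axis, s)] = CW if (cx * dy - cy * dx) < 0 else CCW
    return table


ORIENTATION_TABLE = _build_orientation_table()


def cw_or_ccw(world: WorldState, cfg: RuleConfig) -> str:
    """Circling orientation from the prey's quadrant and the dominant
    component of the closer-predator-to-prey vector.

    Ties: |x| = |y| resolves to the x component; coordinates exactly 0 count
    as positive.
    """
    prey = world.prey_index
    d = np.linalg.norm(world.pos[: world.n_predators] - world.pos[prey], axis=1)
    closer = int(np.argmin(d))
    rel = world.pos[prey] - world.pos[closer]
    axis = "x" if abs(rel[0]) >= abs(rel[1]) else "y"
    s = _sgn(rel[0] if axis == "x" else rel[1])
    cx, cy = _sgn(world.pos[prey, 0]), _sgn(world.pos[prey, 1])
    return ORIENTATION_TABLE[(cx, cy, axis, s)]


def assign_roles(world: WorldState, cfg: RuleConfig) -> tuple[str, str]:
    """Per-step role branching for the two predators.

    Equal distances resolve toward predator 1 being closer.
    """
    if world.n_predators != 2:
        raise ValueError("rule-based policies are defined for exactly 2 predators")
    prey = world.prey_index
    d1 = float(np.linalg.norm(world.pos[0] - world.pos[prey]))
    d2 = float(np.linalg.norm(world.pos[1] - world.pos[prey]))
    if d1 <= d2:
        rule1 = CHASE
        rule2 = AMBUSH if d2 < cfg.distance_threshold else CHASE
    else:
        rule1 = SHORTCUT if d2 < cfg.distance_threshold else APPROACH
        rule2 = CHASE
    return rule1, rule2


def _edge_avoidance(world: WorldState, predator: int, cfg: RuleConfig, orient: str) -> int | None:
    """Keep a predator near the boundary from leaving the arena."""
    x, y = abs(world.pos[predator, 0]), abs(world.pos[predator, 1])
    if x > cfg.outer_edge and y > cfg.outer_edge:
        return 3 if orient == CW else 11
    if cfg.inner_edge < x <= cfg.outer_edge and cfg.inner_edge < y <= cfg.outer_edge:
        return 2 if orient == CW else 12
    return None


def _psi_degrees(world: WorldState, predator: int) -> float:
    """Signed angle between the predator's and the prey's velocity vectors,
    in (-180, 180]; zero when either is at rest."""
    vp = world.vel[predator]
    vq = world.vel[world.prey_index]
    if np.linalg.norm(vp) < 1e-12 or np.linalg.norm(vq) < 1e-12:
        return 0.0
    cross = vp[0] * vq[1] - vp[1] * vq[0]
    dot = float(vp @ vq)
    return math.degrees(math.atan2(cross, dot))


def chase_action(world: WorldState, predator: int, cfg: RuleConfig) -> int:
    """Chase cascade: own edge avoidance, then drive an interior prey
    outward, then align heading with the prey."""
    orient = cw_or_ccw(world, cfg)
    edge = _edge_avoidance(world, predator, cfg, orient)
    if edge is not None:
        return edge
    px, py = abs(world.pos[world.prey_index, 0]), abs(world.pos[world.prey_index, 1])
    if px <= cfg.prey_inside and py <= cfg.prey_inside:
        return 11 if orient == CW else 3
    if cfg.prey_inside < px <= cfg.prey_band and cfg.prey_inside < py <= cfg.prey_band:
        return 12 if orient == CW else 2
    psi = _psi_degrees(world, predator)
    for bound, action in zip(cfg.psi_bins, cfg.psi_actions):
        if psi <= bound:
            return action
    return cfg.psi_actions[-1]


def shortcut_action(world: WorldState, predator: int, cfg: RuleConfig) -> int:
    """Cut toward the prey's near side: edge avoidance, else 2 (CW) / 12 (CCW)."""
    orient = cw_or_ccw(world, cfg)
    edge = _edge_avoidance(world, predator, cfg, orient)
    if edge is not None:
        return edge
    return 2 if orient == CW else 12


def approach_action(world: WorldState, predator: int, cfg: RuleConfig) -> int:
    """Head straight at the prey: edge avoidance, else action 1."""
    orient = cw_or_ccw(world, cfg)
    edge = _edge_avoidance(world, predator, cfg, orient)
    if edge is not None:
        return edge
    return 1


def ambush_action(
    world: WorldState,
    predator: int,
    cfg: RuleConfig,
    env_config: ConditionConfig | None = None,
) -> int:
    """Move to (and hold) the blocking point, using only actions {3, 8, 12}.

    The reference point is the bottom centre while the prey is in the lower
    half-plane (y <= 0) and the top centre otherwise. Among the three
    120-degree-spaced candidate actions (expressed in the prey-relative
    frame, so the choice depends on the prey's direction), the one whose
    next-step position lands closest to the reference point is taken; at the
    point itself this degenerates to the minimal-displacement action. Ties
    resolve to the lowest action number.
    """
    if env_config is None:
        env_config = ConditionConfig(n_predators=world.n_predators)
    ref = cfg.bottom_point if world.pos[world.prey_index, 1] <= 0 else cfg.top_point
    ref = np.asarray(ref, dtype=float)
    u, v = frame_axes(world, predator)
    mag = env_config.accel_magnitude(predator)
    p = world.pos[predator]
    vel = world.vel[predator]
    best_action, best_dist = None, np.inf
    for action in cfg.ambush_actions:
        theta = math.radians((action - 1) * 30.0)
        accel = mag * (math.cos(theta) * u + math.sin(theta) * v)
        nxt = p + (env_config.damping * vel + accel * env_config.dt) * env_config.dt
        dist = float(np.linalg.norm(nxt - ref))
        if dist < best_dist - 1e-12:
            best_dist = dist
            best_action = action
    return best_action


_RULE_FNS = {
    CHASE: chase_action,
    SHORTCUT: shortcut_action,
    APPROACH: approach_action,
}


def rule_action(
    world: WorldState,
    predator: int,
    rule: str,
    cfg: RuleConfig,
    env_config: ConditionConfig | None = None,
) -> int:
    if rule == AMBUSH:
        return ambush_action(world, predator, cfg, env_config)
    return _RULE_FNS[rule](world, predator, cfg)


def make_solo_chase_policy(cfg: RuleConfig | None = None):
    """Single-predator chase cascade (the solitary-hunting reference used by
    the independence benchmark H_n = 1 - (1 - H_1)^n)."""
    cfg = cfg or RuleConfig()

    def policy(state: WorldState, agent: int, env_config: ConditionConfig, rng) -> int:
        return chase_action(state, agent, cfg)

    return policy


def make_rulebased_policies(cfg: RuleConfig | None = None):
    """Policy callables for the two predators, pluggable into env.rollout."""
    cfg = cfg or RuleConfig()

    def policy(state: WorldState, agent: int, env_config: ConditionConfig, rng) -> int:
        roles = assign_roles(state, cfg)
        return rule_action(state, agent, roles[agent], cfg, env_config)

    return [policy, policy]
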