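"""Two-dimensional chase-and-escape world.

Continuous space, discrete time. One prey and one to three predators move as
disks inside the square arena [-1, 1]^2. Each step every agent picks one of 13
discrete actions: accelerations in 12 directions spaced 30 degrees apart in the
agent's own relative frame (action 1 points at the reference opponent), plus
action 13 = coast. Velocities are damped each step (viscous drag) and positions
follow semi-implicit Euler integration. An episode ends on capture (any
predator disk touching the prey disk), on any agent leaving the arena, or at
the time limit.

Predator acceleration is scaled by the relative-mobility factor (1.2 fast /
1.0 equal / 0.8 slow) relative to the prey. On capture the catching predator
earns +1 (all predators under shared reward); the prey is penalised -1 for
being caught or for leaving the arena, and a predator is penalised -1 for
leaving the arena.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

N_ACTIONS = 13
COAST_ACTION = 13

MOBILITY = {"fast": 1.2, "equal": 1.0, "slow": 0.8}

EVENT_NONE = "none"
EVENT_CAPTURE = "capture"
EVENT_PREY_OUT = "prey_out"
EVENT_PREDATOR_OUT = "predator_out"
EVENT_TIMEOUT = "timeout"

#: events that count as a successful predation (prey leaving the arena is a
#: predator success; predators leaving, or the clock running out, are prey
#: successes)
PREDATOR_SUCCESS_EVENTS = frozenset({EVENT_CAPTURE, EVENT_PREY_OUT})


@dataclass(frozen=True)
class ConditionConfig:
    """One experimental cell plus the physics constants.

    Parameters
    ----------
    n_predators : int
        Number of predator agents (1-3); there is always exactly one prey.
    mobility : float
        Predator acceleration relative to the prey: 1.2 (fast), 1.0 (equal)
        or 0.8 (slow).
    sharing : str
        ``"individual"`` (only the catcher is rewarded) or ``"shared"``
        (every predator is rewarded on capture).
    dt : float
        Step duration in seconds.
    time_limit : float
        Episode cap in seconds (30 s -> 300 steps at dt = 0.1).
    prey_accel : float
        Prey acceleration magnitude in length units / s^2. The absolute scale
        is a free parameter of the model; the default 4.0 lets an unopposed
        agent cross the arena in about two seconds.
    damping : float
        Per-step multiplicative velocity retention factor in (0, 1].
    """

    n_predators: int = 2
    mobility: float = 1.0
    sharing: str = "individual"
    dt: float = 0.1
    time_limit: float = 30.0
    arena_half_width: float = 1.0
    agent_diameter: float = 0.1
    init_range: float = 0.5
    prey_accel: float = 4.0
    damping: float = 0.75

    def __post_init__(self) -> None:
        if self.n_predators not in (1, 2, 3):
            raise ValueError(f"n_predators must be 1-3, got {self.n_predators}")
        if not any(math.isclose(self.mobility, m) for m in MOBILITY.values()):
            raise ValueError(f"mobility must be one of {sorted(MOBILITY.values())}")
        if self.sharing not in ("individual", "shared"):
            raise ValueError(f"sharing must be 'individual' or 'shared', got {self.sharing!r}")
        ratio = self.time_limit / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("time_limit must be an integer multiple of dt")
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must be in (0, 1]")
        if self.agent_diameter >= 2 * self.arena_half_width:
            raise ValueError("agent_diameter must fit in the arena")
        if self.init_range > self.arena_half_width:
            raise ValueError("init_range must not exceed arena_half_width")

    # -- derived quantities -------------------------------------------------
    @property
    def n_agents(self) -> int:
        return self.n_predators + 1

    @property
    def prey_index(self) -> int:
        return self.n_predators

    @property
    def max_steps(self) -> int:
        return round(self.time_limit / self.dt)

    @property
    def state_dim(self) -> int:
        """Length of the per-agent feature vector (see agents module)."""
        return 4 + 4 * (self.n_agents - 1)

    def accel_magnitude(self, agent: int) -> float:
        return self.prey_accel * (self.mobility if agent != self.prey_index else 1.0)

    @classmethod
    def from_names(cls, n_predators: int, mobility: str, sharing: str, **kw) -> "ConditionConfig":
        """Build a cell from the factor names (``"fast"``/``"equal"``/``"slow"``)."""
        return cls(n_predators=n_predators, mobility=MOBILITY[mobility], sharing=sharing, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def config_to_yaml(config: ConditionConfig, path) -> None:
    import yaml

    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)


def config_from_yaml(path) -> ConditionConfig:
    import yaml

    with open(path) as fh:
        return ConditionConfig(**yaml.safe_load(fh))


@dataclass
class WorldState:
    """Positions and velocities of all agent disks at one time step.

    Agents are ordered predators first (indices ``0 .. n_predators-1``),
    prey last.
    """

    pos: np.ndarray  # (n_agents, 2) absolute frame, length units
    vel: np.ndarray  # (n_agents, 2) length units / s
    step: int = 0
    n_predators: int = 1

    @property
    def n_agents(self) -> int:
        return self.pos.shape[0]

    @property
    def prey_index(self) -> int:
        return self.n_predators

    def is_predator(self, agent: int) -> bool:
        return agent != self.prey_index

    def copy(self) -> "WorldState":
        return WorldState(self.pos.copy(), self.vel.copy(), self.step, self.n_predators)


@dataclass
class StepOutcome:
    state: WorldState
    rewards: np.ndarray  # (n_agents,) in {-1, 0, +1}
    terminal: bool
    event: str
    event_agent: int | None = None  # catcher on capture, exiting agent on *_out

    @property
    def catcher(self) -> int | None:
        return self.event_agent if self.event == EVENT_CAPTURE else None


# ---------------------------------------------------------------------------
# relative frames and action decoding
# ---------------------------------------------------------------------------

def reference_opponent(state: WorldState, agent: int) -> int:
    """Frame-defining opponent: the prey for predators; the nearest predator
    (lowest index on ties) for the prey."""
    if state.is_predator(agent):
        return state.prey_index
    d = np.linalg.norm(state.pos[: state.n_predators] - state.pos[agent], axis=1)
    return int(np.argmin(d))


def frame_axes(state: WorldState, agent: int) -> tuple[np.ndarray, np.ndarray]:
    """Unit axes (u, v) of the agent's relative frame in absolute coordinates.

    u points from the agent toward its reference opponent; v is u rotated 90
    degrees counterclockwise. Degenerate geometry (agent and opponent
    coincident) falls back to the absolute axes.
    """
    ref = reference_opponent(state, agent)
    delta = state.pos[ref] - state.pos[agent]
    norm = float(np.hypot(delta[0], delta[1]))
    if norm < 1e-12:
        u = np.array([1.0, 0.0])
    else:
        u = delta / norm
    v = np.array([-u[1], u[0]])
    return u, v


def action_to_acceleration(
    action: int, state: WorldState, agent: int, config: ConditionConfig
) -> np.ndarray:
    """Decode a discrete action into an absolute-frame acceleration vector.

    Action 1 accelerates straight toward the reference opponent, successive
    actions rotate counterclockwise by 30 degrees, action 13 coasts.
    """
    if not (1 <= action <= N_ACTIONS):
        raise ValueError(f"action must be in 1..{N_ACTIONS}, got {action}")
    if action == COAST_ACTION:
        return np.zeros(2)
    u, v = frame_axes(state, agent)
    theta = math.radians((action - 1) * 30.0)
    return config.accel_magnitude(agent) * (math.cos(theta) * u + math.sin(theta) * v)


def nearest_action(direction: np.ndarray, state: WorldState, agent: int) -> int:
    """The movement action (1-12) whose decoded direction best matches the
    given absolute-frame direction (used by scripted controllers)."""
    u, v = frame_axes(state, agent)
    du, dv = float(direction @ u), float(direction @ v)
    theta = math.degrees(math.atan2(dv, du)) % 360.0
    return 1 + int(round(theta / 30.0)) % 12


# ---------------------------------------------------------------------------
# dynamics
# ---------------------------------------------------------------------------

def reset(config: ConditionConfig, rng: np.random.Generator) -> WorldState:
    """Initial state: positions i.i.d. uniform on the init box, velocities zero."""
    pos = rng.uniform(-config.init_range, config.init_range, size=(config.n_agents, 2))
    return WorldState(pos, np.zeros((config.n_agents, 2)), 0, config.n_predators)


def integrate(state: WorldState, accelerations: np.ndarray, config: ConditionConfig) -> WorldState:
    """Semi-implicit Euler with viscous drag: v' = damping*v + a*dt; p' = p + v'*dt.

    Predator-predator overlap is permitted (no collision response).
    """
    accelerations = np.asarray(accelerations, dtype=float)
    if accelerations.shape != state.pos.shape:
        raise ValueError("accelerations must be shaped (n_agents, 2)")
    vel = config.damping * state.vel + accelerations * config.dt
    pos = state.pos + vel * config.dt
    return WorldState(pos, vel, state.step + 1, state.n_predators)


def detect_events(state: WorldState, config: ConditionConfig) -> tuple[str, int | None]:
    """Classify the state. Precedence: capture > prey out > predator out > timeout.

    Capture: any predator-prey centre distance <= agent diameter (sum of
    radii), ties to the closest then lowest-index predator. Out-of-area is
    tested on the disk centre with the boundary itself counting as inside.
    """
    prey = state.prey_index
    d = np.linalg.norm(state.pos[: state.n_predators] - state.pos[prey], axis=1)
    if np.any(d <= config.agent_diameter):
        return EVENT_CAPTURE, int(np.argmin(d))
    half = config.arena_half_width
    out = np.any(np.abs(state.pos) > half, axis=1)
    if out[prey]:
        return EVENT_PREY_OUT, prey
    if np.any(out[: state.n_predators]):
        return EVENT_PREDATOR_OUT, int(np.argmax(out[: state.n_predators]))
    if state.step >= config.max_steps:
        return EVENT_TIMEOUT, None
    return EVENT_NONE, None


def compute_rewards(event: str, event_agent: int | None, config: ConditionConfig) -> np.ndarray:
    """Per-agent reward vector for a detected event."""
    r = np.zeros(config.n_agents)
    if event == EVENT_CAPTURE:
        if event_agent is None:
            raise ValueError("capture event requires the catcher index")
        if config.sharing == "shared":
            r[: config.n_predators] = 1.0
        else:
            r[event_agent] = 1.0
        r[config.prey_index] = -1.0
    elif event == EVENT_PREY_OUT:
        r[config.prey_index] = -1.0
    elif event == EVENT_PREDATOR_OUT:
        r[event_agent] = -1.0
    return r


def step(state: WorldState, actions, config: ConditionConfig) -> StepOutcome:
    """Advance one time step: decode actions, integrate, classify, reward.

    Pure function of (state, actions, config).
    """
    actions = np.asarray(actions, dtype=int)
    if actions.shape != (state.n_agents,):
        raise ValueError("one action per agent required")
    accel = np.stack(
        [action_to_acceleration(int(a), state, i, config) for i, a in enumerate(actions)]
    )
    nxt = integrate(state, accel, config)
    event, event_agent = detect_events(nxt, config)
    rewards = compute_rewards(event, event_agent, config)
    return StepOutcome(nxt, rewards, event != EVENT_NONE, event, event_agent)


# ---------------------------------------------------------------------------
# episode records
# ---------------------------------------------------------------------------

RECORD_COLUMNS = [
    "episode_id",
    "step",
    "agent_id",
    "role",
    "x",
    "y",
    "vx",
    "vy",
    "action",
    "reward",
    "event",
]


@dataclass
class EpisodeRecord:
    """Per-step trajectory table for one episode plus its outcome.

    ``table`` has one row per agent-step; positions/velocities are those of
    the state in which the logged action was taken, and ``event`` labels the
    state that action led to.
    """

    episode_id: int
    table: pd.DataFrame
    outcome: str
    duration: float  # seconds
    catcher: int | None = None
    seed: int | None = None

    @property
    def n_steps(self) -> int:
        return int(self.table["step"].max()) + 1 if len(self.table) else 0

    def positions(self, agent: int) -> np.ndarray:
        sub = self.table[self.table["agent_id"] == agent].sort_values("step")
        return sub[["x", "y"]].to_numpy()

    def actions(self, agent: int) -> np.ndarray:
        sub = self.table[self.table["agent_id"] == agent].sort_values("step")
        return sub["action"].to_numpy()


def records_to_frame(records: list[EpisodeRecord]) -> pd.DataFrame:
    return pd.concat([r.table for r in records], ignore_index=True)


def save_records_csv(records: list[EpisodeRecord], path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def save_records_hdf(records: list[EpisodeRecord], path) -> None:
    records_to_frame(records).to_hdf(path, key="episodes", mode="w")


def rollout(
    policies,
    config: ConditionConfig,
    rng: np.random.Generator,
    episode_id: int = 0,
    seed: int | None = None,
) -> EpisodeRecord:
    """Run one episode under per-agent policies and log it.

    Each policy is a callable ``(state, agent, config, rng) -> action``.
    """
    if len(policies) != config.n_agents:
        raise ValueError("one policy per agent required")
    state = reset(config, rng)
    rows = []
    outcome, catcher = EVENT_TIMEOUT, None
    roles = ["predator"] * config.n_predators + ["prey"]
    for t in range(config.max_steps):
        actions = [int(p(state, i, config, rng)) for i, p in enumerate(policies)]
        out = step(state, actions, config)
        for i in range(config.n_agents):
            rows.append(
                (
                    episode_id,
                    t,
                    i,
                    roles[i],
                    state.pos[i, 0],
                    state.pos[i, 1],
                    state.vel[i, 0],
                    state.vel[i, 1],
                    actions[i],
                    out.rewards[i],
                    out.event,
                )
            )
        state = out.state
        if out.terminal:
            outcome, catcher = out.event, out.catcher
            break
    table = pd.DataFrame(rows, columns=RECORD_COLUMNS)
    duration = (int(table["step"].max()) + 1) * config.dt if len(table) else 0.0
    return EpisodeRecord(episode_id, table, outcome, duration, catcher, seed)
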