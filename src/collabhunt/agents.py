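"""Dueling Q-network: featurization, forward pass, action selection.

Each agent owns a four-layer multilayer perceptron: two shared hidden layers
(64 ReLU units each) branching into a value stream and an advantage stream
(32 ReLU units each, then 1 and 13 linear outputs). The streams are merged by
the identifiable aggregation

    Q(s, a) = V(s) + (A(s, a) - mean_a' A(s, a')),

so the mean of Q over actions equals V and shifting all advantages by a
constant leaves Q unchanged.

The state vector seen by an agent contains its own absolute position, its own
velocity expressed in its relative frame, and, for every other agent, the
relative position and relative velocity in that same frame. The frame is the
one used for action decoding (u-axis toward the reference opponent), so
perception and motor coordinates agree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .env import ConditionConfig, WorldState, frame_axes

N_ACTIONS = 13

# network widths; fixed by the study architecture
TRUNK_UNITS = 64
STREAM_UNITS = 32


def build_state_vector(world: WorldState, agent: int, config: ConditionConfig) -> np.ndarray:
    """Featurize the world from one agent's point of view.

    Layout: [own x, own y, own v_u, own v_v] then for every other agent in
    ascending index order [rel p_u, rel p_v, rel v_u, rel v_v]. Length
    4 + 4*(n_agents - 1). The own relative position (identically zero) is
    omitted.
    """
    if not (0 <= agent < world.n_agents):
        raise IndexError(f"agent {agent} out of range")
    u, v = frame_axes(world, agent)
    rot = np.stack([u, v])  # rows project onto the frame axes
    parts = [world.pos[agent], rot @ world.vel[agent]]
    for other in range(world.n_agents):
        if other == agent:
            continue
        parts.append(rot @ (world.pos[other] - world.pos[agent]))
        parts.append(rot @ (world.vel[other] - world.vel[agent]))
    return np.concatenate(parts)


@dataclass
class PolicyParams:
    """Weights of one agent's dueling network.

    theta: trunk (w1, b1, w2, b2); eta: advantage stream (wa, ba, wa2, ba2);
    xi: value stream (wv, bv, wv2, bv2).
    """

    w1: np.ndarray  # (state_dim, 64)
    b1: np.ndarray
    w2: np.ndarray  # (64, 64)
    b2: np.ndarray
    wa: np.ndarray  # (64, 32)
    ba: np.ndarray
    wa2: np.ndarray  # (32, 13)
    ba2: np.ndarray
    wv: np.ndarray  # (64, 32)
    bv: np.ndarray
    wv2: np.ndarray  # (32, 1)
    bv2: np.ndarray

    ARRAY_NAMES = ("w1", "b1", "w2", "b2", "wa", "ba", "wa2", "ba2", "wv", "bv", "wv2", "bv2")

    @classmethod
    def initialize(
        cls,
        state_dim: int,
        rng: np.random.Generator,
        trunk_units: int = TRUNK_UNITS,
        stream_units: int = STREAM_UNITS,
        n_actions: int = N_ACTIONS,
    ) -> "PolicyParams":
        """Fan-in-scaled uniform initialization (seedable)."""

        def layer(n_in, n_out):
            bound = 1.0 / np.sqrt(n_in)
            w = rng.uniform(-bound, bound, size=(n_in, n_out))
            b = rng.uniform(-bound, bound, size=n_out)
            return w, b

        w1, b1 = layer(state_dim, trunk_units)
        w2, b2 = layer(trunk_units, trunk_units)
        wa, ba = layer(trunk_units, stream_units)
        wa2, ba2 = layer(stream_units, n_actions)
        wv, bv = layer(trunk_units, stream_units)
        wv2, bv2 = layer(stream_units, 1)
        return cls(w1, b1, w2, b2, wa, ba, wa2, ba2, wv, bv, wv2, bv2)

    @property
    def state_dim(self) -> int:
        return self.w1.shape[0]

    @property
    def n_actions(self) -> int:
        return self.wa2.shape[1]

    def arrays(self) -> tuple[np.ndarray, ...]:
        return tuple(getattr(self, name) for name in self.ARRAY_NAMES)

    def copy(self) -> "PolicyParams":
        return PolicyParams(*(a.copy() for a in self.arrays()))

    def __eq__(self, other) -> bool:
        if not isinstance(other, PolicyParams):
            return NotImplemented
        return all(np.array_equal(a, b) for a, b in zip(self.arrays(), other.arrays()))


@dataclass
class QValues:
    """Value, advantages and aggregated action values for one or more states."""

    V: np.ndarray  # scalar per state
    A: np.ndarray  # (..., 13)
    Q: np.ndarray  # (..., 13)


def _relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


def forward(params: PolicyParams, s: np.ndarray) -> QValues:
    """Pure forward pass; accepts a single state vector or a batch."""
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    x = s[None, :] if single else s
    if x.shape[-1] != params.state_dim:
        raise ValueError(f"state dim {x.shape[-1]} != network input {params.state_dim}")
    h1 = _relu(x @ params.w1 + params.b1)
    h2 = _relu(h1 @ params.w2 + params.b2)
    ha = _relu(h2 @ params.wa + params.ba)
    adv = ha @ params.wa2 + params.ba2
    hv = _relu(h2 @ params.wv + params.bv)
    val = (hv @ params.wv2 + params.bv2)[:, 0]
    q = val[:, None] + adv - adv.mean(axis=1, keepdims=True)
    if single:
        return QValues(val[0], adv[0], q[0])
    return QValues(val, adv, q)


def greedy_action(q: np.ndarray) -> int:
    """Argmax over action values, ties broken toward the lowest action index."""
    return int(np.argmax(q)) + 1


def select_action(q: QValues, epsilon: float, rng: np.random.Generator) -> int:
    """Epsilon-greedy selection over the 13 actions (1-based)."""
    if not (0.0 <= epsilon <= 1.0):
        raise ValueError("epsilon must be in [0, 1]")
    if epsilon > 0.0 and rng.random() < epsilon:
        return int(rng.integers(1, N_ACTIONS + 1))
    return greedy_action(np.asarray(q.Q))


def extract_hidden(params: PolicyParams, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Post-ReLU activations of the 32-unit value- and advantage-stream layers.

    Returns (value-stream hidden, advantage-stream hidden); these are the
    internal representations used for the embedding analysis.
    """
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    x = s[None, :] if single else s
    if x.shape[-1] != params.state_dim:
        raise ValueError(f"state dim {x.shape[-1]} != network input {params.state_dim}")
    h1 = _relu(x @ params.w1 + params.b1)
    h2 = _relu(h1 @ params.w2 + params.b2)
    ha = _relu(h2 @ params.wa + params.ba)
    hv = _relu(h2 @ params.wv + params.bv)
    if single:
        return hv[0], ha[0]
    return hv, ha


def make_greedy_policy(params: PolicyParams, config: ConditionConfig):
    """Wrap network weights as a greedy policy callable for rollouts."""

    def policy(state: WorldState, agent: int, cfg: ConditionConfig, rng) -> int:
        s = build_state_vector(state, agent, cfg)
        return greedy_action(forward(params, s).Q)

    return policy


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params_per_agent, config: ConditionConfig, n_episodes: int) -> None:
    """Single-file archive of named weight arrays + config hash + episode count."""
    payload = {"config_hash": np.array(config.config_hash()), "n_episodes": np.array(n_episodes)}
    for i, params in enumerate(params_per_agent):
        for name in PolicyParams.ARRAY_NAMES:
            payload[f"agent{i}_{name}"] = getattr(params, name)
    np.savez(path, **payload)


def load_checkpoint(path, config: ConditionConfig) -> tuple[list[PolicyParams], int]:
    """Load a checkpoint; refuses weights saved under a different config."""
    with np.load(path) as data:
        saved_hash = str(data["config_hash"])
        if saved_hash != config.config_hash():
            raise ValueError(
                f"checkpoint config hash {saved_hash} does not match current config "
                f"{config.config_hash()}"
            )
        n_episodes = int(data["n_episodes"])
        out = []
        for i in range(config.n_agents):
            arrays = [data[f"agent{i}_{name}"] for name in PolicyParams.ARRAY_NAMES]
            out.append(PolicyParams(*arrays))
    return out, n_episodes
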