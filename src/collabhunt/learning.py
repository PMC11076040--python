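"""Independent per-agent optimization: prioritized replay, double-DQN
targets, weighted Huber loss, the epsilon schedule and the training loop.

Every agent — predators and prey alike — owns its own network, target
network, replay memory and Adam optimizer, and treats the other agents as
part of the environment (independent learning). Per environment step each
agent stores one transition and, once its memory holds at least one
minibatch, performs one gradient step on an importance-weighted Huber loss
toward the double-DQN target

    y = r + gamma * Q_target(s', argmax_a' Q_online(s', a')),

with no bootstrap on terminal transitions. Replay sampling is proportional
prioritization, P(i) = p_i^alpha / sum_k p_k^alpha with p_i = |delta_i| +
priority_floor, corrected by importance weights w_i = (1 / (N P(i)))^beta
normalized by the batch maximum.

The numpy functions here are the reference implementations of each
operation; ``train`` runs the same computation through the compiled loop in
``_fastloop`` so desk-scale runs finish in minutes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _fastloop
from .agents import PolicyParams, forward
from .env import ConditionConfig

EVENT_CODES = {0: "none", 1: "capture", 2: "prey_out", 3: "predator_out", 4: "timeout"}


@dataclass(frozen=True)
class LearnerConfig:
    """Learning hyperparameters.

    The defaults are the full-scale training settings (10^6 episodes at
    learning rate 1e-6). ``desk()`` returns the scaled-down configuration
    used throughout the test suite and analysis scripts: 2x10^4 episodes
    with the learning rate raised to 1e-4 so that the total optimizer
    displacement (lr x gradient steps) is comparable to the full run;
    the epsilon anneal and target-sync cadence keep their absolute values.
    """

    gamma: float = 0.9
    alpha: float = 0.6  # prioritization exponent
    beta: float = 0.4  # importance-sampling exponent (constant, no anneal)
    lr: float = 1e-6
    batch: int = 32
    memory_size: int = 10_000
    target_sync_every: int = 2000  # episodes
    total_episodes: int = 1_000_000
    eps_start: float = 1.0
    eps_final: float = 0.1
    eps_anneal_episodes: int = 10_000
    priority_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must be in [0, 1]")
        if self.alpha < 0.0:
            raise ValueError("alpha must be >= 0")
        if not (0.0 <= self.beta <= 1.0):
            raise ValueError("beta must be in [0, 1]")
        if self.priority_floor <= 0.0:
            raise ValueError("priority_floor must be positive")

    @classmethod
    def desk(cls, total_episodes: int = 20_000, **overrides) -> "LearnerConfig":
        kw = dict(total_episodes=total_episodes, lr=1e-4)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class Transition:
    """One replay unit: (s, a, r, s', terminal)."""

    s: np.ndarray
    a: int
    r: float
    s2: np.ndarray
    terminal: bool


class ReplayMemory:
    """Ring buffer of transitions with per-item priorities.

    New transitions enter at the current maximum priority (1 when empty) so
    they are replayed at least once; the oldest item is evicted at capacity.
    """

    def __init__(self, capacity: int, state_dim: int):
        self.capacity = capacity
        self.s = np.zeros((capacity, state_dim))
        self.a = np.zeros(capacity, dtype=np.int64)
        self.r = np.zeros(capacity)
        self.s2 = np.zeros((capacity, state_dim))
        self.terminal = np.zeros(capacity, dtype=bool)
        self.priorities = np.zeros(capacity)
        self.ptr = 0
        self.size = 0
        self.max_priority = 1.0

    def __len__(self) -> int:
        return self.size

    def add(self, t: Transition) -> None:
        self.s[self.ptr] = t.s
        self.a[self.ptr] = t.a
        self.r[self.ptr] = t.r
        self.s2[self.ptr] = t.s2
        self.terminal[self.ptr] = t.terminal
        self.priorities[self.ptr] = self.max_priority
        self.ptr = (self.ptr + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def __getitem__(self, i: int) -> Transition:
        if not (0 <= i < self.size):
            raise IndexError(i)
        return Transition(self.s[i], int(self.a[i]), float(self.r[i]), self.s2[i],
                          bool(self.terminal[i]))


def add_transition(memory: ReplayMemory, t: Transition) -> ReplayMemory:
    memory.add(t)
    return memory


def sampling_probabilities(memory: ReplayMemory, alpha: float) -> np.ndarray:
    """P(i) = p_i^alpha / sum_k p_k^alpha over the current contents."""
    p = memory.priorities[: memory.size] ** alpha
    return p / p.sum()


def sample_batch(
    memory: ReplayMemory, config: LearnerConfig, rng: np.random.Generator
) -> tuple[dict, np.ndarray, np.ndarray]:
    """Draw a prioritized minibatch with importance-sampling weights."""
    if memory.size < config.batch:
        raise ValueError(f"memory holds {memory.size} < batch {config.batch} transitions")
    probs = sampling_probabilities(memory, config.alpha)
    idx = rng.choice(memory.size, size=config.batch, replace=True, p=probs)
    weights = (1.0 / (memory.size * probs[idx])) ** config.beta
    weights = weights / weights.max()
    batch = {
        "s": memory.s[idx],
        "a": memory.a[idx],
        "r": memory.r[idx],
        "s2": memory.s2[idx],
        "terminal": memory.terminal[idx],
    }
    return batch, idx, weights


def update_priorities(memory: ReplayMemory, indices, td_errors, config: LearnerConfig) -> ReplayMemory:
    """Set p_i = |delta_i| + priority_floor for the given items."""
    indices = np.asarray(indices)
    if np.any(indices < 0) or np.any(indices >= memory.size):
        raise IndexError("replay index out of range")
    p = np.abs(np.asarray(td_errors, dtype=float)) + config.priority_floor
    memory.priorities[indices] = p
    memory.max_priority = max(memory.max_priority, float(p.max()))
    return memory


def ddqn_target(batch: dict, online: PolicyParams, target: PolicyParams, gamma: float) -> np.ndarray:
    """Double-DQN targets: online network selects, target network evaluates."""
    q_online = forward(online, batch["s2"]).Q
    q_target = forward(target, batch["s2"]).Q
    astar = np.argmax(q_online, axis=1)
    bootstrap = q_target[np.arange(len(astar)), astar]
    return batch["r"] + gamma * bootstrap * (~np.asarray(batch["terminal"], dtype=bool))


def huber(residual: np.ndarray, threshold: float = 1.0) -> np.ndarray:
    """Piecewise Huber penalty (quadratic inside the threshold, linear outside)."""
    a = np.abs(residual)
    return np.where(a <= threshold, 0.5 * residual**2, threshold * (a - 0.5 * threshold))


def loss_and_grads(
    batch: dict, targets: np.ndarray, weights: np.ndarray, online: PolicyParams
) -> tuple[float, dict, np.ndarray]:
    """IS-weighted Huber loss and its gradients w.r.t. the online weights.

    Gradients flow only through Q(s, a), never through the targets. Returns
    (loss, grads keyed like PolicyParams.ARRAY_NAMES, TD errors).
    """
    x = np.asarray(batch["s"], dtype=float)
    acts = np.asarray(batch["a"], dtype=int) - 1
    B = x.shape[0]
    n_act = online.n_actions

    z1 = x @ online.w1 + online.b1
    h1 = np.maximum(z1, 0.0)
    z2 = h1 @ online.w2 + online.b2
    h2 = np.maximum(z2, 0.0)
    za = h2 @ online.wa + online.ba
    ha = np.maximum(za, 0.0)
    adv = ha @ online.wa2 + online.ba2
    zv = h2 @ online.wv + online.bv
    hv = np.maximum(zv, 0.0)
    val = hv @ online.wv2 + online.bv2

    q_a = val[:, 0] + adv[np.arange(B), acts] - adv.mean(axis=1)
    td = np.asarray(targets, dtype=float) - q_a
    loss = float(np.mean(weights * huber(td)))

    dhub = np.clip(td, -1.0, 1.0)
    g = -(weights * dhub) / B  # dL/dQ(s,a)

    dq = np.zeros((B, n_act))
    dq[np.arange(B), acts] = g
    dval = g[:, None]
    dadv = dq - (g / n_act)[:, None]

    grads = {}
    grads["wv2"] = hv.T @ dval
    grads["bv2"] = dval.sum(axis=0)
    dzv = (dval @ online.wv2.T) * (zv > 0)
    grads["wa2"] = ha.T @ dadv
    grads["ba2"] = dadv.sum(axis=0)
    dza = (dadv @ online.wa2.T) * (za > 0)
    grads["wv"] = h2.T @ dzv
    grads["bv"] = dzv.sum(axis=0)
    grads["wa"] = h2.T @ dza
    grads["ba"] = dza.sum(axis=0)
    dh2 = dzv @ online.wv.T + dza @ online.wa.T
    dz2 = dh2 * (z2 > 0)
    grads["w2"] = h1.T @ dz2
    grads["b2"] = dz2.sum(axis=0)
    dz1 = (dz2 @ online.w2.T) * (z1 > 0)
    grads["w1"] = x.T @ dz1
    grads["b1"] = dz1.sum(axis=0)
    return loss, grads, td


class Adam:
    """Reference Adam optimizer for a PolicyParams (used in tests and by the
    behavioral-cloning trainer; the DQN fast path carries its own fused copy)."""

    def __init__(self, params: PolicyParams, lr: float,
                 b1: float = _fastloop.ADAM_B1, b2: float = _fastloop.ADAM_B2,
                 eps: float = _fastloop.ADAM_EPS):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = {n: np.zeros_like(getattr(params, n)) for n in PolicyParams.ARRAY_NAMES}
        self.v = {n: np.zeros_like(getattr(params, n)) for n in PolicyParams.ARRAY_NAMES}

    def step(self, params: PolicyParams, grads: dict) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        for name in PolicyParams.ARRAY_NAMES:
            g = grads[name].reshape(getattr(params, name).shape)
            m = self.m[name]
            v = self.v[name]
            m[:] = self.b1 * m + (1 - self.b1) * g
            v[:] = self.b2 * v + (1 - self.b2) * g * g
            getattr(params, name)[:] -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


def epsilon(episode: int, config: LearnerConfig) -> float:
    """Linear anneal eps_start -> eps_final over the first anneal window,
    constant afterwards."""
    if episode < 0:
        raise ValueError("episode must be >= 0")
    if episode >= config.eps_anneal_episodes:
        return config.eps_final
    frac = episode / config.eps_anneal_episodes
    return config.eps_start + (config.eps_final - config.eps_start) * frac


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainResult:
    params: list[PolicyParams]  # one per agent, predators first then prey
    log: pd.DataFrame  # per-episode: episode, length, event, epsilon, return_i, loss_i
    checkpoints: list[tuple[int, list[PolicyParams]]]
    condition: ConditionConfig
    learner: LearnerConfig
    seed: int


def _stack_params(params_list: list[PolicyParams]) -> tuple[np.ndarray, ...]:
    """Stack per-agent weights into float32 arrays for the compiled loop."""
    return tuple(
        np.ascontiguousarray(np.stack([getattr(p, n) for p in params_list]), dtype=np.float32)
        for n in PolicyParams.ARRAY_NAMES
    )


def _unstack_params(stacked: tuple[np.ndarray, ...], n_agents: int) -> list[PolicyParams]:
    return [
        PolicyParams(*(arr[i].astype(np.float64) for arr in stacked)) for i in range(n_agents)
    ]


def train(
    condition: ConditionConfig,
    learner: LearnerConfig,
    seed: int,
    n_checkpoints: int = 10,
) -> TrainResult:
    """Train all agents in one condition; fully reproducible from the seed.

    Weights are initialized per agent from the seed, the compiled loop runs
    in blocks, and a checkpoint is snapshotted after every block (every 10%
    of episodes by default) plus the final weights.
    """
    rng = np.random.default_rng(seed)
    init = [PolicyParams.initialize(condition.state_dim, rng) for _ in range(condition.n_agents)]
    if learner.total_episodes == 0:
        return TrainResult(init, pd.DataFrame(), [], condition, learner, seed)

    n_agents = condition.n_agents
    online = _stack_params(init)
    target = tuple(a.copy() for a in online)
    mstate = tuple(np.zeros_like(a) for a in online)
    vstate = tuple(np.zeros_like(a) for a in online)
    adam_t = np.zeros(n_agents, dtype=np.int64)

    cap, dim = learner.memory_size, condition.state_dim
    f32 = np.float32
    rep_s = np.zeros((n_agents, cap, dim), dtype=f32)
    rep_a = np.zeros((n_agents, cap), dtype=np.int64)
    rep_r = np.zeros((n_agents, cap), dtype=f32)
    rep_s2 = np.zeros((n_agents, cap, dim), dtype=f32)
    rep_d = np.zeros((n_agents, cap), dtype=f32)
    rep_p = np.zeros((n_agents, cap), dtype=f32)
    rep_pa = np.zeros((n_agents, cap), dtype=f32)
    rep_meta = np.zeros((n_agents, 2), dtype=np.int64)
    rep_max = np.ones(n_agents)

    total = learner.total_episodes
    block = max(1, math.ceil(total / max(1, n_checkpoints)))
    chunk_seeds = np.random.SeedSequence(seed).generate_state(
        math.ceil(total / block), dtype=np.uint32
    ) % (2**31)

    logs = []
    checkpoints = []
    done_eps = 0
    for ci, chunk_seed in enumerate(chunk_seeds):
        n_eps = min(block, total - done_eps)
        ep_len = np.zeros(n_eps, dtype=np.int64)
        ep_event = np.zeros(n_eps, dtype=np.int64)
        ep_return = np.zeros((n_eps, n_agents))
        ep_loss = np.zeros((n_eps, n_agents))
        _fastloop.train_chunk(
            int(chunk_seed), done_eps, n_eps,
            condition.n_predators, condition.mobility, condition.prey_accel,
            condition.damping, condition.dt, condition.agent_diameter,
            condition.arena_half_width, condition.max_steps, condition.init_range,
            condition.sharing == "shared",
            learner.gamma, learner.alpha, learner.beta, learner.lr, learner.batch,
            learner.target_sync_every, learner.eps_start, learner.eps_final,
            learner.eps_anneal_episodes, learner.priority_floor,
            online, target, mstate, vstate, adam_t,
            rep_s, rep_a, rep_r, rep_s2, rep_d, rep_p, rep_pa, rep_meta, rep_max,
            ep_len, ep_event, ep_return, ep_loss,
        )
        episodes = np.arange(done_eps, done_eps + n_eps)
        frame = pd.DataFrame(
            {
                "episode": episodes,
                "length": ep_len,
                "event": [EVENT_CODES[int(c)] for c in ep_event],
                "epsilon": [epsilon(int(e), learner) for e in episodes],
            }
        )
        for i in range(n_agents):
            frame[f"return_{i}"] = ep_return[:, i]
            frame[f"loss_{i}"] = ep_loss[:, i]
        logs.append(frame)
        done_eps += n_eps
        checkpoints.append((done_eps, _unstack_params(online, n_agents)))

    final = _unstack_params(online, n_agents)
    return TrainResult(final, pd.concat(logs, ignore_index=True), checkpoints,
                       condition, learner, seed)
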