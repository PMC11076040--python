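"""Behavioral cloning of the rule-based predators into one-hidden-layer nets.

A 32-unit hidden layer (linear, or ReLU for the nonlinear variant) followed
by a softmax over the 13 actions is fit by cross-entropy to (state, action)
pairs logged from rule-based rollouts. Corpora are split by episode into
train / validation / test sets (1000 / 100 / 100 episodes at full scale) and
the weights with the best validation accuracy are kept. Chance level is 1/13;
the cascade rules are piecewise, so the nonlinear variant is expected to fit
them at least as well as the linear one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import build_state_vector
from .env import ConditionConfig, EpisodeRecord, WorldState

N_ACTIONS = 13
HIDDEN_UNITS = 32


@dataclass(frozen=True)
class CloneConfig:
    lr: float = 1e-4
    batch: int = 32
    epochs: int = 2000
    hidden: int = HIDDEN_UNITS
    patience: int | None = None  # early stop after this many epochs without val gain

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.batch < 1:
            raise ValueError("epochs and batch must be positive")


@dataclass
class CloneNet:
    """One-hidden-layer softmax classifier over the 13 actions."""

    w1: np.ndarray  # (state_dim, hidden)
    b1: np.ndarray
    w2: np.ndarray  # (hidden, 13)
    b2: np.ndarray
    variant: str  # "linear" | "relu"

    @classmethod
    def initialize(cls, state_dim: int, variant: str, rng: np.random.Generator,
                   hidden: int = HIDDEN_UNITS) -> "CloneNet":
        if variant not in ("linear", "relu"):
            raise ValueError("variant must be 'linear' or 'relu'")
        b = 1.0 / np.sqrt(state_dim)
        w1 = rng.uniform(-b, b, size=(state_dim, hidden))
        b1 = rng.uniform(-b, b, size=hidden)
        b = 1.0 / np.sqrt(hidden)
        w2 = rng.uniform(-b, b, size=(hidden, N_ACTIONS))
        b2 = rng.uniform(-b, b, size=N_ACTIONS)
        return cls(w1, b1, w2, b2, variant)

    def copy(self) -> "CloneNet":
        return CloneNet(self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy(),
                        self.variant)


def _hidden(net: CloneNet, x: np.ndarray) -> np.ndarray:
    h = x @ net.w1 + net.b1
    if net.variant == "relu":
        h = np.maximum(h, 0.0)
    return h


def clone_forward(net: CloneNet, s: np.ndarray) -> np.ndarray:
    """Class probabilities; accepts a single state or a batch."""
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    x = s[None, :] if single else s
    if x.shape[-1] != net.w1.shape[0]:
        raise ValueError(f"state dim {x.shape[-1]} != network input {net.w1.shape[0]}")
    logits = _hidden(net, x) @ net.w2 + net.b2
    logits = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(logits)
    probs = e / e.sum(axis=1, keepdims=True)
    return probs[0] if single else probs


def clone_hidden(net: CloneNet, s: np.ndarray) -> np.ndarray:
    """Hidden-layer activations (the clone's internal representation)."""
    s = np.asarray(s, dtype=float)
    return _hidden(net, s[None, :] if s.ndim == 1 else s)


@dataclass
class CloneDataset:
    """Episode-disjoint train/validation/test splits of (state, action) pairs."""

    train_x: np.ndarray
    train_y: np.ndarray  # actions 1..13
    val_x: np.ndarray
    val_y: np.ndarray
    test_x: np.ndarray
    test_y: np.ndarray

    def __post_init__(self) -> None:
        for x, y in ((self.train_x, self.train_y), (self.val_x, self.val_y),
                     (self.test_x, self.test_y)):
            if len(x) != len(y):
                raise ValueError("states and actions must align")
        if min(len(self.train_x), len(self.val_x), len(self.test_x)) == 0:
            raise ValueError("every split must be non-empty")


def _featurize_records(records: list[EpisodeRecord], agent: int,
                       config: ConditionConfig) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    n_agents = config.n_agents
    for rec in records:
        tab = rec.table.sort_values(["step", "agent_id"])
        arr = tab[["x", "y", "vx", "vy", "action"]].to_numpy(dtype=float)
        arr = arr.reshape(-1, n_agents, 5)
        for t in range(arr.shape[0]):
            world = WorldState(arr[t, :, 0:2], arr[t, :, 2:4], t, config.n_predators)
            xs.append(build_state_vector(world, agent, config))
            ys.append(int(arr[t, agent, 4]))
    return np.asarray(xs), np.asarray(ys, dtype=np.int64)


def dataset_from_records(records: list[EpisodeRecord], agent: int, config: ConditionConfig,
                         n_train: int, n_val: int, n_test: int) -> CloneDataset:
    """Split episodes (in order) into disjoint train/val/test corpora for one
    predator and featurize every logged step."""
    if len(records) < n_train + n_val + n_test:
        raise ValueError("not enough episodes for the requested split")
    tr = records[:n_train]
    va = records[n_train : n_train + n_val]
    te = records[n_train + n_val : n_train + n_val + n_test]
    return CloneDataset(*_featurize_records(tr, agent, config),
                        *_featurize_records(va, agent, config),
                        *_featurize_records(te, agent, config))


def accuracy(net: CloneNet, x: np.ndarray, y: np.ndarray) -> float:
    probs = clone_forward(net, x)
    return float(np.mean(np.argmax(probs, axis=1) + 1 == y))


def cross_entropy(net: CloneNet, x: np.ndarray, y: np.ndarray) -> float:
    probs = clone_forward(net, x)
    p = probs[np.arange(len(y)), y - 1]
    return float(-np.mean(np.log(np.clip(p, 1e-12, None))))


def train_clone(dataset: CloneDataset, variant: str, config: CloneConfig | None = None,
                seed: int = 0) -> tuple[CloneNet, dict]:
    """Fit a clone by minibatch Adam on the cross-entropy error.

    Keeps the weights with the best validation accuracy seen across epochs
    and reports per-split accuracies for that checkpoint.
    """
    config = config or CloneConfig()
    rng = np.random.default_rng(seed)
    x, y = dataset.train_x, dataset.train_y
    net = CloneNet.initialize(x.shape[1], variant, rng, config.hidden)
    m = {k: np.zeros_like(getattr(net, k)) for k in ("w1", "b1", "w2", "b2")}
    v = {k: np.zeros_like(getattr(net, k)) for k in ("w1", "b1", "w2", "b2")}
    t = 0
    n = len(x)
    best_val, best_net, best_epoch = -1.0, net.copy(), 0
    history = []
    stale = 0
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch):
            idx = order[start : start + config.batch]
            xb, yb = x[idx], y[idx] - 1
            B = len(idx)
            h_pre = xb @ net.w1 + net.b1
            h = np.maximum(h_pre, 0.0) if variant == "relu" else h_pre
            logits = h @ net.w2 + net.b2
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = e / e.sum(axis=1, keepdims=True)
            dlogits = probs
            dlogits[np.arange(B), yb] -= 1.0
            dlogits /= B
            grads = {
                "w2": h.T @ dlogits,
                "b2": dlogits.sum(axis=0),
            }
            dh = dlogits @ net.w2.T
            if variant == "relu":
                dh = dh * (h_pre > 0)
            grads["w1"] = xb.T @ dh
            grads["b1"] = dh.sum(axis=0)
            t += 1
            bc1 = 1.0 - 0.9**t
            bc2 = 1.0 - 0.999**t
            for k, g in grads.items():
                m[k] = 0.9 * m[k] + 0.1 * g
                v[k] = 0.999 * v[k] + 0.001 * g * g
                getattr(net, k)[:] -= config.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + 1e-8)
        val_acc = accuracy(net, dataset.val_x, dataset.val_y)
        history.append({"epoch": epoch, "val_accuracy": val_acc,
                        "train_cross_entropy": cross_entropy(net, x, y)})
        if val_acc > best_val:
            best_val, best_net, best_epoch = val_acc, net.copy(), epoch
            stale = 0
        else:
            stale += 1
            if config.patience is not None and stale >= config.patience:
                break
    report = {
        "variant": variant,
        "train_accuracy": accuracy(best_net, x, y),
        "val_accuracy": best_val,
        "test_accuracy": accuracy(best_net, dataset.test_x, dataset.test_y),
        "best_epoch": best_epoch,
        "history": history,
        "n_train": n,
        "n_val": len(dataset.val_x),
        "n_test": len(dataset.test_x),
    }
    return best_net, report
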