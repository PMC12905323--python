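"""Dueling double deep Q-network with prioritized experience replay.

The action-value function is decomposed into a state value and mean-centered
advantages,

    Q(s, a) = V(s) + ( A(s, a) - mean_a' A(s, a') ),

so the advantage head only has to rank actions while the value head tracks
overall state quality.  Targets are double-Q: the online network selects the
argmax action in the next state, the periodically-copied target network
evaluates it.  Transitions are replayed with probability proportional to a
power of their TD-error magnitude, corrected by annealed importance weights.

The network itself is a compact fully-connected architecture written directly
in numpy: the 9-channel 30^3 binary observation is average-pooled to a coarse
lattice, flattened, passed through ReLU trunk layers, and split into the value
and advantage heads.  Forward, backward, Huber loss, Adam, and gradient
clipping are implemented explicitly, which keeps the training loop free of
framework dependencies and bit-reproducible from a single master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "QNetConfig",
    "DuelingQNetwork",
    "ReplayBuffer",
    "TrainConfig",
    "DQNTrainer",
    "select_action",
    "td_target",
    "substream",
]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed."""
    import zlib

    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(name.encode())])
    )


# --- network ---------------------------------------------------------------


@dataclass(frozen=True)
class QNetConfig:
    """Architecture of the dueling Q-network.

    ``pool`` average-pools each spatial axis of the 30^3 observation by that
    factor before flattening; trunk/head widths are fully configurable so the
    same code serves desk-scale CPU runs and larger studies.
    """

    input_channels: int = 9
    grid_size: int = 30
    pool: int = 3
    trunk_hidden: tuple[int, ...] = (256,)
    head_hidden: tuple[int, ...] = (128,)
    n_actions: int = 9

    @property
    def pooled_size(self) -> int:
        return self.grid_size // self.pool

    @property
    def n_features(self) -> int:
        return self.input_channels * self.pooled_size**3


def _init_layer(n_in: int, n_out: int, rng: np.random.Generator):
    # He initialization for ReLU layers
    w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
    return {"W": w.astype(np.float64), "b": np.zeros(n_out)}


class DuelingQNetwork:
    """Plain-numpy dueling Q-network with explicit forward/backward."""

    def __init__(self, config: QNetConfig | None = None, rng: np.random.Generator | None = None):
        self.config = config or QNetConfig()
        rng = rng or np.random.default_rng(0)
        c = self.config
        self.trunk: list[dict] = []
        n = c.n_features
        for width in c.trunk_hidden:
            self.trunk.append(_init_layer(n, width, rng))
            n = width
        self.value_head: list[dict] = []
        self.adv_head: list[dict] = []
        m = n
        for width in c.head_hidden:
            self.value_head.append(_init_layer(m, width, rng))
            m = width
        self.value_head.append(_init_layer(m, 1, rng))
        m = n
        for width in c.head_hidden:
            self.adv_head.append(_init_layer(m, width, rng))
            m = width
        self.adv_head.append(_init_layer(m, c.n_actions, rng))

    # -- parameter plumbing --

    def _layers(self):
        yield from self.trunk
        yield from self.value_head
        yield from self.adv_head

    def get_params(self) -> list[dict]:
        return [{k: v.copy() for k, v in layer.items()} for layer in self._layers()]

    def set_params(self, params: list[dict]) -> None:
        for layer, src in zip(self._layers(), params, strict=True):
            for k in layer:
                layer[k][...] = src[k]

    # -- forward / backward --

    def preprocess(self, states: np.ndarray) -> np.ndarray:
        """Average-pool and flatten observations -> (B, n_features) float."""
        c = self.config
        x = np.asarray(states, dtype=np.float32)
        single = x.ndim == 4
        if single:
            x = x[None]
        b = x.shape[0]
        s, p = c.grid_size, c.pool
        q = c.pooled_size
        x = x.reshape(b, c.input_channels, q, p, q, p, q, p).mean(axis=(3, 5, 7))
        return x.reshape(b, -1).astype(np.float64)

    @staticmethod
    def _mlp_forward(x, layers, cache):
        h = x
        for layer in layers:
            z = h @ layer["W"] + layer["b"]
            cache.append((h, z))
            if layer is not layers[-1]:
                h = np.maximum(z, 0.0)
            else:
                h = z
        return h

    def forward(self, features: np.ndarray, want_cache: bool = False):
        """Q-values (B, n_actions) from preprocessed features.

        Dueling combination: Q = V + (A - mean_a A).
        """
        cache = {"trunk": [], "value": [], "adv": []}
        h = features
        for layer in self.trunk:
            z = h @ layer["W"] + layer["b"]
            cache["trunk"].append((h, z))
            h = np.maximum(z, 0.0)
        v = self._mlp_forward(h, self.value_head, cache["value"])  # (B,1)
        a = self._mlp_forward(h, self.adv_head, cache["adv"])  # (B,Na)
        q = v + (a - a.mean(axis=1, keepdims=True))
        if want_cache:
            cache["trunk_out"] = h
            return q, v, a, cache
        return q

    def q_values(self, states: np.ndarray) -> np.ndarray:
        """Q-values straight from raw observations."""
        return self.forward(self.preprocess(states))

    @staticmethod
    def _mlp_backward(dout, layers, cache, grads):
        d = dout
        for i in reversed(range(len(layers))):
            h, z = cache[i]
            if i != len(layers) - 1:
                d = d * (z > 0.0)
            grads[id(layers[i])] = {"W": h.T @ d, "b": d.sum(axis=0)}
            d = d @ layers[i]["W"].T
        return d

    def backward(self, dq: np.ndarray, cache) -> dict:
        """Gradients of a scalar loss given dL/dQ; returns {id(layer): grad}."""
        na = self.config.n_actions
        # Q = V + A - mean(A): dV = sum_a dq; dA = dq - mean_a dq
        dv = dq.sum(axis=1, keepdims=True)
        da = dq - dq.sum(axis=1, keepdims=True) / na
        grads: dict = {}
        d_from_v = self._mlp_backward(dv, self.value_head, cache["value"], grads)
        d_from_a = self._mlp_backward(da, self.adv_head, cache["adv"], grads)
        d = d_from_v + d_from_a
        for i in reversed(range(len(self.trunk))):
            h, z = cache["trunk"][i]
            d = d * (z > 0.0)
            grads[id(self.trunk[i])] = {"W": h.T @ d, "b": d.sum(axis=0)}
            d = d @ self.trunk[i]["W"].T
        return grads

    # -- persistence --

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self._layers()):
            out[f"W{i}"] = layer["W"]
            out[f"b{i}"] = layer["b"]
        return out

    def load_arrays(self, arrays) -> None:
        for i, layer in enumerate(self._layers()):
            layer["W"][...] = arrays[f"W{i}"]
            layer["b"][...] = arrays[f"b{i}"]


def select_action(
    net: DuelingQNetwork, state: np.ndarray, eps: float, rng: np.random.Generator
) -> int:
    """Epsilon-greedy action; greedy ties break to the lowest index."""
    if rng.random() < eps:
        return int(rng.integers(net.config.n_actions))
    q = net.q_values(state)[0]
    return int(np.argmax(q))


def td_target(
    rewards: np.ndarray,
    next_q_online: np.ndarray,
    next_q_target: np.ndarray,
    terminal: np.ndarray,
    gamma: float,
) -> np.ndarray:
    """Double-Q targets: online argmax, target evaluation; y = r on terminal."""
    a_star = np.argmax(next_q_online, axis=1)
    boot = next_q_target[np.arange(len(a_star)), a_star]
    return rewards + gamma * (1.0 - terminal.astype(float)) * boot


# --- prioritized replay ------------------------------------------------------


class ReplayBuffer:
    """Proportional prioritized replay over fixed-size feature arrays."""

    def __init__(
        self,
        capacity: int,
        feature_dim: int,
        alpha: float = 0.6,
        priority_floor: float = 1e-6,
    ):
        self.capacity = int(capacity)
        self.alpha = alpha
        self.priority_floor = priority_floor
        self.states = np.zeros((self.capacity, feature_dim), dtype=np.float16)
        self.next_states = np.zeros((self.capacity, feature_dim), dtype=np.float16)
        self.actions = np.zeros(self.capacity, dtype=np.int64)
        self.rewards = np.zeros(self.capacity, dtype=np.float64)
        self.terminal = np.zeros(self.capacity, dtype=bool)
        self.priorities = np.zeros(self.capacity, dtype=np.float64)
        self.pos = 0
        self.size = 0

    def add(self, state, action, reward, next_state, terminal) -> None:
        i = self.pos
        self.states[i] = state
        self.next_states[i] = next_state
        self.actions[i] = action
        self.rewards[i] = reward
        self.terminal[i] = terminal
        p_max = self.priorities[: self.size].max() if self.size else 1.0
        self.priorities[i] = max(p_max, self.priority_floor)
        self.pos = (self.pos + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, beta: float, rng: np.random.Generator):
        """Indices, batch arrays, and max-normalized importance weights."""
        if self.size == 0:
            raise ValueError("cannot sample from an empty replay buffer")
        scaled = self.priorities[: self.size] ** self.alpha
        probs = scaled / scaled.sum()
        idx = rng.choice(self.size, size=batch_size, p=probs)
        w = (self.size * probs[idx]) ** (-beta)
        w = w / w.max()
        batch = {
            "states": self.states[idx].astype(np.float64),
            "actions": self.actions[idx],
            "rewards": self.rewards[idx],
            "next_states": self.next_states[idx].astype(np.float64),
            "terminal": self.terminal[idx],
        }
        return idx, batch, w

    def update_priorities(self, idx: np.ndarray, td_errors: np.ndarray) -> None:
        self.priorities[idx] = np.abs(td_errors) + self.priority_floor


# --- optimizer ---------------------------------------------------------------


class Adam:
    """Adam over the network's layer dicts, with global-norm gradient clipping."""

    def __init__(self, net: DuelingQNetwork, lr: float, clip: float = 10.0):
        self.net = net
        self.lr = lr
        self.clip = clip
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in layer.items()} for layer in net._layers()
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in layer.items()} for layer in net._layers()
        ]

    def step(self, grads: dict) -> None:
        layers = list(self.net._layers())
        gs = [grads[id(layer)] for layer in layers]
        total = np.sqrt(sum(float((g[k] ** 2).sum()) for g in gs for k in g))
        scale = self.clip / total if total > self.clip else 1.0
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for layer, g, m, v in zip(layers, gs, self.m, self.v):
            for k in layer:
                gk = g[k] * scale
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * gk
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * gk**2
                layer[k] -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            for k in m:
                out[f"m{i}_{k}"] = m[k]
                out[f"v{i}_{k}"] = v[k]
        return out

    def load_arrays(self, arrays) -> None:
        self.t = int(arrays["t"])
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            for k in m:
                m[k][...] = arrays[f"m{i}_{k}"]
                v[k][...] = arrays[f"v{i}_{k}"]


def huber(x: np.ndarray, delta: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Huber loss values and derivative."""
    absx = np.abs(x)
    quad = absx <= delta
    loss = np.where(quad, 0.5 * x**2, delta * (absx - 0.5 * delta))
    grad = np.where(quad, x, delta * np.sign(x))
    return loss, grad


# --- training loop ------------------------------------------------------------


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the Q-learning run.

    Defaults follow the full-scale study configuration (learning rate 7e-5,
    5e6 total steps, target-network copy every 5e3 steps, epsilon 1 -> 0.05
    over the first 3e6 steps); every horizon scales down for CPU-sized runs.
    Values without an established setting (discount, batch size, optimizer,
    warm-up) are declared package defaults.
    """

    lr: float = 7e-5
    total_steps: int = 5_000_000
    target_update_period: int = 5_000
    eps_start: float = 1.0
    eps_end: float = 0.05
    eps_decay_steps: int = 3_000_000
    buffer_capacity: int = 50_000
    batch_size: int = 32
    gamma: float = 0.99
    per_alpha: float = 0.6
    per_beta_start: float = 0.4
    per_beta_end: float = 1.0
    priority_floor: float = 1e-6
    grad_clip: float = 10.0
    warmup: int = 1_000
    learn_every: int = 1
    seed: int = 0

    def epsilon(self, step: int) -> float:
        frac = min(step / max(self.eps_decay_steps, 1), 1.0)
        return self.eps_start + frac * (self.eps_end - self.eps_start)

    def beta(self, step: int) -> float:
        frac = min(step / max(self.total_steps, 1), 1.0)
        return self.per_beta_start + frac * (self.per_beta_end - self.per_beta_start)


def scaled_train_config(seed: int, total_steps: int = 20_000) -> TrainConfig:
    """Desk-scale CPU training profile for the single-gap benchmark scene.

    Horizons shrink proportionally to the reduced step budget; the learning
    rate is raised to 3e-4, standard for a network this small.
    """
    return TrainConfig(
        lr=3e-4,
        total_steps=total_steps,
        eps_decay_steps=int(total_steps * 0.6),
        buffer_capacity=total_steps,
        warmup=500,
        target_update_period=1_000,
        seed=seed,
    )


def scaled_net_config() -> QNetConfig:
    """Reduced network for CPU runs: pool-6 lattice, 64-unit trunk."""
    return QNetConfig(pool=6, trunk_hidden=(64,), head_hidden=(32,))


@dataclass
class TrainResult:
    net: DuelingQNetwork
    history: list[dict] = field(default_factory=list)
    episode_returns: list[float] = field(default_factory=list)


class DQNTrainer:
    """Single-process trainer: epsilon-greedy rollouts, PER, double-Q updates."""

    def __init__(self, env, config: TrainConfig, net_config: QNetConfig | None = None):
        self.env = env
        self.config = config
        self.net = DuelingQNetwork(net_config, rng=substream(config.seed, "net-init"))
        self.target_net = DuelingQNetwork(net_config, rng=substream(config.seed, "net-init"))
        self.target_net.set_params(self.net.get_params())
        self.opt = Adam(self.net, lr=config.lr, clip=config.grad_clip)
        self.buffer = ReplayBuffer(
            config.buffer_capacity,
            self.net.config.n_features,
            alpha=config.per_alpha,
            priority_floor=config.priority_floor,
        )
        self.explore_rng = substream(config.seed, "exploration")
        self.replay_rng = substream(config.seed, "replay")
        self.env_seed = int(substream(config.seed, "episodes").integers(2**31))
        self.step_i = 0
        self.action_trace: list[int] = []
        self.history: list[dict] = []
        self.episode_returns: list[float] = []
        self._state: np.ndarray | None = None
        self._feat: np.ndarray | None = None
        self._ep_return = 0.0

    def _learn(self) -> float:
        cfg = self.config
        idx, batch, w = self.buffer.sample(
            cfg.batch_size, cfg.beta(self.step_i), self.replay_rng
        )
        q_next_online = self.net.forward(batch["next_states"])
        q_next_target = self.target_net.forward(batch["next_states"])
        y = td_target(
            batch["rewards"], q_next_online, q_next_target, batch["terminal"], cfg.gamma
        )
        q, v, a, cache = self.net.forward(batch["states"], want_cache=True)
        rows = np.arange(len(idx))
        td = q[rows, batch["actions"]] - y
        loss_vals, dhuber = huber(td)
        loss = float(np.mean(w * loss_vals))
        if np.isnan(loss):
            raise RuntimeError("NaN loss encountered during training")
        dq = np.zeros_like(q)
        dq[rows, batch["actions"]] = w * dhuber / len(rows)
        grads = self.net.backward(dq, cache)
        self.opt.step(grads)
        self.buffer.update_priorities(idx, td)
        return loss

    def train(
        self, log_path: str | Path | None = None, steps: int | None = None
    ) -> TrainResult:
        """Run until ``total_steps`` (or ``steps`` more from where we stand)."""
        cfg = self.config
        stop = cfg.total_steps if steps is None else min(self.step_i + steps, cfg.total_steps)
        if self._state is None:
            self._state = self.env.reset(seed=self.env_seed)
            self._feat = self.net.preprocess(self._state)[0]
            self._ep_return = 0.0
        while self.step_i < stop:
            eps = cfg.epsilon(self.step_i)
            a = select_action(self.net, self._state, eps, self.explore_rng)
            if len(self.action_trace) < 200:
                self.action_trace.append(a)
            next_state, r, done, _ = self.env.step(a)
            next_feat = self.net.preprocess(next_state)[0]
            self.buffer.add(self._feat, a, r, next_feat, done)
            self._ep_return += r
            self.step_i += 1
            loss = np.nan
            if self.buffer.size >= max(cfg.warmup, cfg.batch_size) and (
                self.step_i % cfg.learn_every == 0
            ):
                loss = self._learn()
            if self.step_i % cfg.target_update_period == 0:
                self.target_net.set_params(self.net.get_params())
            self.history.append({"step": self.step_i, "eps": eps, "loss": loss})
            if done:
                self.episode_returns.append(self._ep_return)
                self._ep_return = 0.0
                self._state = self.env.reset()
                self._feat = self.net.preprocess(self._state)[0]
            else:
                self._state, self._feat = next_state, next_feat
        if log_path is not None:
            self.write_log(log_path)
        return TrainResult(self.net, self.history, self.episode_returns)

    def write_log(self, path: str | Path) -> Path:
        import csv

        path = Path(path)
        with path.open("w", newline="") as fh:
            wr = csv.DictWriter(fh, fieldnames=["step", "eps", "loss"])
            wr.writeheader()
            wr.writerows(self.history)
        return path

    # -- checkpointing --

    def save_checkpoint(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {f"net_{k}": v for k, v in self.net.state_arrays().items()}
        arrays.update({f"tgt_{k}": v for k, v in self.target_net.state_arrays().items()})
        arrays.update({f"opt_{k}": v for k, v in self.opt.state_arrays().items()})
        b = self.buffer
        arrays.update(
            {
                "buf_states": b.states[: b.size],
                "buf_next_states": b.next_states[: b.size],
                "buf_actions": b.actions[: b.size],
                "buf_rewards": b.rewards[: b.size],
                "buf_terminal": b.terminal[: b.size],
                "buf_priorities": b.priorities[: b.size],
                "buf_pos": np.asarray(b.pos),
            }
        )
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {
            "step_i": self.step_i,
            "config": asdict(self.config),
            "net_config": asdict(self.net.config),
            "explore_rng": self.explore_rng.bit_generator.state,
            "replay_rng": self.replay_rng.bit_generator.state,
            "episode_returns": self.episode_returns,
            "ep_return": self._ep_return,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, default=str))
        import pickle

        with path.with_suffix(".env.pkl").open("wb") as fh:
            pickle.dump(self.env, fh)
        return path.with_suffix(".npz")

    def load_checkpoint(self, path: str | Path) -> None:
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as data:
            self.net.load_arrays(
                {k[4:]: data[k] for k in data.files if k.startswith("net_")}
            )
            self.target_net.load_arrays(
                {k[4:]: data[k] for k in data.files if k.startswith("tgt_")}
            )
            self.opt.load_arrays(
                {k[4:]: data[k] for k in data.files if k.startswith("opt_")}
            )
            n = int(data["buf_pos"]) if "buf_states" in data.files else 0
            size = len(data["buf_states"])
            b = self.buffer
            b.states[:size] = data["buf_states"]
            b.next_states[:size] = data["buf_next_states"]
            b.actions[:size] = data["buf_actions"]
            b.rewards[:size] = data["buf_rewards"]
            b.terminal[:size] = data["buf_terminal"]
            b.priorities[:size] = data["buf_priorities"]
            b.size = size
            b.pos = n
        meta = json.loads(path.with_suffix(".json").read_text())
        env_pkl = path.with_suffix(".env.pkl")
        if env_pkl.exists():
            import pickle

            with env_pkl.open("rb") as fh:
                self.env = pickle.load(fh)
        self.step_i = meta["step_i"]
        self.explore_rng.bit_generator.state = _rng_state(meta["explore_rng"])
        self.replay_rng.bit_generator.state = _rng_state(meta["replay_rng"])
        self.episode_returns = list(meta["episode_returns"])
        self._ep_return = float(meta.get("ep_return", 0.0))
        if getattr(self.env, "grid", None) is not None:
            self._state = self.env._observation()
            self._feat = self.net.preprocess(self._state)[0]


def _rng_state(state) -> dict:
    # JSON round-trips PCG64 state ints as strings in some layouts; coerce back
    if isinstance(state, dict) and "state" in state and isinstance(state["state"], dict):
        inner = {k: int(v) for k, v in state["state"].items()}
        return {**state, "state": inner}
    return state
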