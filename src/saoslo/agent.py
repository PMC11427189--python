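"""Single-step deterministic policy-gradient agent with LSTM networks.

The actor consumes the observation matrix as a length-(2N+1) sequence of
(N+1)-vectors (normalised metric + probe code per row), encodes it with a
recurrent layer and predicts N correction coefficients through a saturating
(tanh) head.  The critic encodes the same sequence, concatenates the action
to the final recurrent state and regresses the immediate reward.  Because
every episode is a single prediction with an immediate reward, there is no
bootstrapping and no target networks: the critic target IS the observed
reward, and the actor follows the deterministic policy gradient through the
critic.

Exploration works by adding k zero-mean Gaussian noise profiles to each
prediction and evaluating all of them against the same hidden aberration,
turning one episode into k stored transitions; the noise SD anneals
linearly to zero by the final episode.  A warm-up phase collects
transitions with frozen networks before any update.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import nn
from .env import SAOEnv

__all__ = ["ActorPolicy", "CriticValue", "TrainingSchedule", "ReplayBuffer",
           "AgentCheckpoint", "act", "train", "transfer_learn"]


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------
class ActorPolicy:
    """Recurrent deterministic policy: observation matrix -> N coefficients,
    each bounded to [-action_limit, action_limit] by a tanh output head."""

    def __init__(self, n_modes: int, hidden: int = 128,
                 action_limit: float = 0.25, bias: float = 0.5,
                 rng: Optional[np.random.Generator] = None,
                 params: Optional[dict] = None):
        self.n_modes = n_modes
        self.hidden = hidden
        self.action_limit = float(action_limit)
        self.bias = float(bias)  # observation bias the policy was trained with
        d_in = n_modes + 1
        if params is None:
            rng = np.random.default_rng() if rng is None else rng
            params = {**nn.lstm_init(rng, d_in, hidden),
                      **nn.dense_init(rng, hidden, n_modes, "head")}
        self.params = params

    def forward(self, obs: np.ndarray):
        """Batched forward; obs shape (B, 2N+1, N+1). Returns (a, cache)."""
        h, lstm_cache = nn.lstm_forward(self.params, obs)
        pre = h @ self.params["head.W"] + self.params["head.b"]
        t = np.tanh(pre)
        return self.action_limit * t, {"lstm": lstm_cache, "h": h, "t": t}

    def backward(self, d_action: np.ndarray, cache: dict) -> dict:
        """Gradients of a scalar loss given d(loss)/d(action)."""
        t = cache["t"]
        dpre = d_action * self.action_limit * (1.0 - t * t)
        grads = {"head.W": cache["h"].T @ dpre, "head.b": dpre.sum(axis=0)}
        dh = dpre @ self.params["head.W"].T
        grads.update(nn.lstm_backward(self.params, dh, cache["lstm"]))
        return grads

    def act(self, observation: np.ndarray) -> np.ndarray:
        """Deterministic action for one observation matrix (2N+1, N+1)."""
        observation = np.asarray(observation, dtype=float)
        if observation.shape != (2 * self.n_modes + 1, self.n_modes + 1):
            raise ValueError(
                f"observation shape {observation.shape} does not match "
                f"N={self.n_modes}")
        a, _ = self.forward(observation[None])
        return a[0]

    @classmethod
    def from_checkpoint(cls, checkpoint) -> "ActorPolicy":
        if isinstance(checkpoint, (str, Path)):
            checkpoint = AgentCheckpoint.load(checkpoint)
        return checkpoint.actor_policy()


class CriticValue:
    """Recurrent action-value estimate of the immediate reward."""

    def __init__(self, n_modes: int, hidden: int = 128,
                 rng: Optional[np.random.Generator] = None,
                 params: Optional[dict] = None):
        self.n_modes = n_modes
        self.hidden = hidden
        d_in = n_modes + 1
        if params is None:
            rng = np.random.default_rng() if rng is None else rng
            params = {**nn.lstm_init(rng, d_in, hidden),
                      **nn.dense_init(rng, hidden + n_modes, hidden, "fc1"),
                      **nn.dense_init(rng, hidden, 1, "fc2")}
        self.params = params

    def forward(self, obs: np.ndarray, action: np.ndarray):
        h, lstm_cache = nn.lstm_forward(self.params, obs)
        z = np.concatenate([h, action], axis=1)
        u_pre = z @ self.params["fc1.W"] + self.params["fc1.b"]
        u = np.maximum(u_pre, 0.0)
        q = (u @ self.params["fc2.W"] + self.params["fc2.b"])[:, 0]
        return q, {"lstm": lstm_cache, "z": z, "u": u}

    def backward(self, dq: np.ndarray, cache: dict):
        """Returns (param grads, d(loss)/d(action))."""
        du = np.outer(dq, self.params["fc2.W"][:, 0])
        du *= (cache["u"] > 0)
        grads = {
            "fc2.W": cache["u"].T @ dq[:, None],
            "fc2.b": np.array([dq.sum()]),
            "fc1.W": cache["z"].T @ du,
            "fc1.b": du.sum(axis=0),
        }
        dz = du @ self.params["fc1.W"].T
        dh, d_action = dz[:, :self.hidden], dz[:, self.hidden:]
        grads.update(nn.lstm_backward(self.params, dh, cache["lstm"]))
        return grads, d_action

    def predict(self, obs: np.ndarray, action: np.ndarray) -> np.ndarray:
        q, _ = self.forward(np.asarray(obs, dtype=float),
                            np.asarray(action, dtype=float))
        return q


# ---------------------------------------------------------------------------
# replay memory and schedule
# ---------------------------------------------------------------------------
class ReplayBuffer:
    """Flat ring buffer of (observation matrix, action, reward) transitions."""

    def __init__(self, capacity: int, seq_len: int, obs_dim: int, n_modes: int):
        self.capacity = capacity
        self.obs = np.empty((capacity, seq_len, obs_dim))
        self.act = np.empty((capacity, n_modes))
        self.rew = np.empty(capacity)
        self.size = 0
        self._ptr = 0

    def add(self, obs: np.ndarray, action: np.ndarray, reward: float) -> None:
        p = self._ptr
        self.obs[p], self.act[p], self.rew[p] = obs, action, reward
        self._ptr = (p + 1) % self.capacity
        self.size = min(self.size + 1, self.capacity)

    def sample(self, batch_size: int, rng: np.random.Generator):
        idx = rng.integers(0, self.size, batch_size)
        return self.obs[idx], self.act[idx], self.rew[idx]


@dataclass
class TrainingSchedule:
    """Hyperparameters of one training run.

    ``warmup_episodes`` defaults to 10% of ``episodes``; during warm-up the
    networks stay frozen and transitions come from exploration noise alone.
    The exploration SD anneals linearly from ``exploration_sd0`` (um) to
    exactly zero at the final episode.
    """

    episodes: int = 40_000
    warmup_episodes: Optional[int] = None
    noise_profiles_per_episode: int = 15
    exploration_sd0: float = 0.05
    replay_capacity: int = 1_000_000
    batch_size: int = 256
    actor_lr: float = 1e-4
    critic_lr: float = 1e-3
    updates_per_episode: int = 1
    hidden: int = 128
    action_limit: float = 0.25
    seed: Optional[int] = None

    def __post_init__(self):
        if self.warmup_episodes is None:
            self.warmup_episodes = self.episodes // 10
        if not 0 <= self.warmup_episodes < self.episodes:
            raise ValueError("warm-up must be shorter than the run")

    def exploration_sd(self, episode: int) -> float:
        """Linear anneal; exactly zero at the final episode."""
        if self.episodes == 1:
            return 0.0
        frac = episode / (self.episodes - 1)
        return self.exploration_sd0 * max(0.0, 1.0 - frac)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------
@dataclass
class AgentCheckpoint:
    """Actor+critic weights plus the configuration needed to rebuild them.

    Serialised as a flat ``.npz`` of named arrays (keys ``actor/<name>``,
    ``critic/<name>``) next to a JSON sidecar with the configuration, so the
    weights are loadable without any training code.
    """

    actor_params: dict
    critic_params: dict
    config: dict = field(default_factory=dict)

    def actor_policy(self) -> ActorPolicy:
        c = self.config
        return ActorPolicy(
            n_modes=c["n_modes"], hidden=c["hidden"],
            action_limit=c["action_limit"], bias=c.get("bias", 0.5),
            params={k: v.copy() for k, v in self.actor_params.items()})

    def critic_value(self) -> CriticValue:
        c = self.config
        return CriticValue(
            n_modes=c["n_modes"], hidden=c["hidden"],
            params={k: v.copy() for k, v in self.critic_params.items()})

    def save(self, path) -> None:
        path = Path(path)
        arrays = {f"actor/{k}": v for k, v in self.actor_params.items()}
        arrays.update({f"critic/{k}": v for k, v in self.critic_params.items()})
        np.savez(path.with_suffix(".npz"), **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.config, indent=2))

    @classmethod
    def load(cls, path) -> "AgentCheckpoint":
        path = Path(path)
        with np.load(path.with_suffix(".npz")) as z:
            actor = {k[len("actor/"):]: z[k] for k in z.files
                     if k.startswith("actor/")}
            critic = {k[len("critic/"):]: z[k] for k in z.files
                      if k.startswith("critic/")}
        config = json.loads(path.with_suffix(".json").read_text())
        return cls(actor, critic, config)


def act(policy, observation: np.ndarray) -> np.ndarray:
    """Deterministic coefficients for one observation matrix."""
    if not isinstance(policy, ActorPolicy):
        policy = ActorPolicy.from_checkpoint(policy)
    return policy.act(observation)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------
def _update_networks(actor, critic, buffer, schedule, opt_a, opt_c, rng):
    """One critic regression step and one policy-gradient step."""
    obs_b, act_b, rew_b = buffer.sample(schedule.batch_size, rng)
    B = len(rew_b)
    # critic: minimise MSE to the observed immediate reward
    q, cache = critic.forward(obs_b, act_b)
    err = q - rew_b
    critic_loss = float(np.mean(err * err))
    if not np.isfinite(critic_loss):
        raise FloatingPointError("critic loss diverged (non-finite)")
    grads_c, _ = critic.backward(2.0 * err / B, cache)
    opt_c.step(critic.params, grads_c)
    # actor: ascend the critic's value at the policy's own action
    a_pi, cache_a = actor.forward(obs_b)
    q_pi, cache_q = critic.forward(obs_b, a_pi)
    _, d_action = critic.backward(-np.ones(B) / B, cache_q)
    grads_a = actor.backward(d_action, cache_a)
    opt_a.step(actor.params, grads_a)
    return critic_loss, float(np.mean(q_pi))


def _training_loop(actor, critic, env: SAOEnv, schedule: TrainingSchedule,
                   rng: np.random.Generator, buffer=None, progress=False):
    k = schedule.noise_profiles_per_episode
    n = env.n_modes
    if buffer is None:
        buffer = ReplayBuffer(schedule.replay_capacity,
                              env.n_observations, n + 1, n)
    opt_a = nn.Adam(actor.params, schedule.actor_lr)
    opt_c = nn.Adam(critic.params, schedule.critic_lr)
    trace = {"episode": [], "mean_reward": [], "exploration_sd": [],
             "critic_loss": []}
    iterator = range(schedule.episodes)
    if progress:
        try:
            from tqdm import tqdm
            iterator = tqdm(iterator, desc="episodes")
        except ImportError:
            pass
    for ep in iterator:
        obs = env.reset(rng)
        base = actor.act(obs)
        sd = schedule.exploration_sd(ep)
        profiles = rng.normal(0.0, sd, (k, n)) if sd > 0 else np.zeros((k, n))
        rewards = env.evaluate_action_batch(base, profiles)
        for p, r in zip(profiles, rewards):
            buffer.add(obs, base + p, r)
        closs = np.nan
        if ep >= schedule.warmup_episodes:
            for _ in range(schedule.updates_per_episode):
                closs, _ = _update_networks(
                    actor, critic, buffer, schedule, opt_a, opt_c, rng)
        trace["episode"].append(ep)
        trace["mean_reward"].append(float(rewards.mean()))
        trace["exploration_sd"].append(sd)
        trace["critic_loss"].append(closs)
    return buffer, pd.DataFrame(trace)


def train(env: SAOEnv, schedule: TrainingSchedule,
          rng: Optional[np.random.Generator] = None, progress: bool = False):
    """Train an agent from scratch on ``env``.

    Returns ``(AgentCheckpoint, trace)`` where ``trace`` is a per-episode
    DataFrame (episode, mean_reward over the k noisy actions,
    exploration_sd, critic_loss).
    """
    if rng is None:
        rng = np.random.default_rng(schedule.seed)
    n = env.n_modes
    actor = ActorPolicy(n, schedule.hidden, schedule.action_limit,
                        bias=env.bias, rng=rng)
    critic = CriticValue(n, schedule.hidden, rng=rng)
    _, trace = _training_loop(actor, critic, env, schedule, rng,
                              progress=progress)
    config = {"n_modes": n, "hidden": schedule.hidden,
              "action_limit": schedule.action_limit, "bias": env.bias,
              "target_indices": list(env.target_indices),
              "schedule": {k: v for k, v in asdict(schedule).items()}}
    return AgentCheckpoint(actor.params, critic.params, config), trace


def transfer_learn(checkpoint: AgentCheckpoint, target_env: SAOEnv,
                   rng: Optional[np.random.Generator] = None,
                   episodes: int = 1000, noise_profiles_per_episode: int = 7,
                   exploration_sd0: float = 0.02,
                   schedule: Optional[TrainingSchedule] = None,
                   progress: bool = False):
    """Fine-tune a trained agent on a (perturbed) target environment.

    A brief continuation of the same update rule — immediate-reward critic
    target, deterministic policy gradient — with a fresh, smaller
    exploration schedule and no warm-up freeze (the networks start from
    competent weights, so exploration noise alone suffices to refresh the
    replay memory before updates begin).
    """
    if checkpoint.config["n_modes"] != target_env.n_modes:
        raise ValueError(
            f"checkpoint has N={checkpoint.config['n_modes']} but the target "
            f"environment has N={target_env.n_modes}")
    if rng is None:
        rng = np.random.default_rng()
    if schedule is None:
        src = checkpoint.config.get("schedule", {})
        schedule = TrainingSchedule(
            episodes=episodes, warmup_episodes=max(1, episodes // 20),
            noise_profiles_per_episode=noise_profiles_per_episode,
            exploration_sd0=exploration_sd0,
            batch_size=src.get("batch_size", 256),
            actor_lr=src.get("actor_lr", 1e-4),
            critic_lr=src.get("critic_lr", 1e-3),
            updates_per_episode=src.get("updates_per_episode", 1),
            hidden=checkpoint.config["hidden"],
            action_limit=checkpoint.config["action_limit"])
    actor = checkpoint.actor_policy()
    critic = checkpoint.critic_value()
    _, trace = _training_loop(actor, critic, target_env, schedule, rng,
                              progress=progress)
    config = dict(checkpoint.config)
    config["transfer"] = {"episodes": schedule.episodes,
                          "noise_profiles_per_episode":
                              schedule.noise_profiles_per_episode,
                          "exploration_sd0": schedule.exploration_sd0}
    return AgentCheckpoint(actor.params, critic.params, config), trace
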