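"""Deterministic tiny configurations and scripted inputs for fast testing.

Everything here regenerates bit-identically from a seed; scripted episodes
carry their expected rewards/terminations by construction so modules can be
exercised in seconds without any training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .env import MazeConfig, TMazeEnv
from .intention import IntentionParams, kl_diag_gauss, synergize
from .networks import AgentModel, NetworkConfig


def tiny_maze_config() -> MazeConfig:
    """Small maze with an 8x16 camera.

    Sized so optimal trials take ~6-8 steps and undirected random actions
    still reach an exit in a noticeable fraction of episodes, keeping
    desk-scale training runs informative.
    """
    return MazeConfig(width=1.8, arm_width=0.8, arm_height=0.6, bar_height=0.8,
                      exit_depth=0.4, max_speed=0.2, max_steps=40,
                      image_height=8, image_width=16)


def tiny_network_config() -> NetworkConfig:
    return NetworkConfig.tiny()


@dataclass
class ScriptedEpisode:
    """An action sequence with its expected outcome in the tiny maze."""

    actions: np.ndarray
    expected_reward: float
    expected_done: bool
    expected_exit: str | None
    expected_collisions: int


def straight_to_left_exit() -> ScriptedEpisode:
    """Up the arm then left along the bar; ends at the left exit."""
    actions = np.array([[0.0, 1.0]] * 3 + [[-1.0, 0.0]] * 3)
    cfg = tiny_maze_config()
    return ScriptedEpisode(actions=actions, expected_reward=cfg.reward_left,
                           expected_done=True, expected_exit="left",
                           expected_collisions=0)


def wall_bump_episode(bumps: int = 4) -> ScriptedEpisode:
    """Pushes left into the arm wall; the first 2 steps are free, then each
    further push is a collision worth the collision reward."""
    free_steps = 2
    actions = np.array([[-0.75, 0.0]] * (free_steps + bumps))
    cfg = tiny_maze_config()
    return ScriptedEpisode(actions=actions,
                           expected_reward=cfg.collision_reward * bumps,
                           expected_done=False, expected_exit=None,
                           expected_collisions=bumps)


@dataclass
class CannedIntentionPair:
    q: IntentionParams
    p: IntentionParams
    kl_per_dim: np.ndarray
    kl_sum: float
    synergy: IntentionParams


@dataclass
class FixtureSet:
    seed: int
    maze: MazeConfig
    network: NetworkConfig
    model: AgentModel
    episodes: dict = field(default_factory=dict)
    intention_pairs: list = field(default_factory=list)


def make_fixtures(seed: int = 0) -> FixtureSet:
    rng = np.random.default_rng(seed)
    pairs = []
    for _ in range(3):
        q = IntentionParams(mu=rng.normal(size=4), sigma=rng.uniform(0.2, 2.0, 4),
                            role="posterior")
        p = IntentionParams(mu=rng.normal(size=4), sigma=rng.uniform(0.2, 2.0, 4),
                            role="prior")
        per_dim, total = kl_diag_gauss(q, p)
        pairs.append(CannedIntentionPair(q=q, p=p, kl_per_dim=per_dim,
                                         kl_sum=total, synergy=synergize(p, q)))
    return FixtureSet(
        seed=seed,
        maze=tiny_maze_config(),
        network=tiny_network_config(),
        model=AgentModel(tiny_network_config(), seed=seed),
        episodes={
            "straight_left": straight_to_left_exit(),
            "wall_bump": wall_bump_episode(),
        },
        intention_pairs=pairs,
    )


def surrogate_quadratic(goal_mu: np.ndarray, sigma_penalty: float = 0.1):
    """Separable quadratic CEM oracle: ||mu - mu*||^2 + penalty * ||sigma||^2.

    Candidates are (mu, xi) rows as used by the planner's search space, with
    sigma = softplus(xi); the minimum over mu sits exactly at ``goal_mu``.
    """
    goal_mu = np.asarray(goal_mu, dtype=np.float64)
    d = goal_mu.size

    def score(cand: np.ndarray) -> np.ndarray:
        mu = cand[:, :d]
        sigma = np.logaddexp(0.0, cand[:, d:])
        return ((mu - goal_mu[None]) ** 2).sum(axis=1) + sigma_penalty * (sigma**2).sum(axis=1)

    return score


def run_scripted(episode: ScriptedEpisode, config: MazeConfig | None = None):
    """Execute a scripted episode; returns (total reward, done, collisions, env)."""
    env = TMazeEnv(config or tiny_maze_config())
    env.reset()
    total, collisions, done = 0.0, 0, False
    for action in episode.actions:
        result = env.step(action)
        total += result.reward
        collisions += int(result.info["collision"])
        done = result.done
        if done:
            break
    return total, done, collisions, env
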