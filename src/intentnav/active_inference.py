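"""Goal-directed inference of the posterior intention at behaving time.

With the model frozen, the posterior intention's parameters (mu_q, xi_q with
sigma_q = softplus(xi_q)) are optimized by the cross-entropy method to
minimize a variational free energy with respect to a goal: reconstruct the
actual current observation, drive the predicted future observation toward
the goal, and stay close to the habitual prior (KL complexity term).

The search stops early once the synergized intention is precise enough:
after each generation the synergized STD is formed from the fitted sigma_q
and the prior sigma_p (precision additivity), and iteration ends when its
mean drops to the threshold — so a sufficiently confident habit needs a
single generation.

Goals are either a full observation or a color to pursue/avoid; color goals
score the predicted future image by counting pixels within 0.25 of the
target color (scaled by 5 for pursue, 100 for avoid, with minimization
semantics).
"""

from __future__ import annotations


from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .intention import IntentionParams, kl_diag_gauss, softplus, softplus_inv, synergize
from .networks import AgentModel


@dataclass
class AIfConfig:
    population: int = 256
    elites: int = 32
    max_generations: int = 16
    sigma_thres: float = 0.05
    color_tolerance: float = 0.25
    pursue_scale: float = 5.0
    avoid_scale: float = 100.0
    beta_z: float = 0.1
    init_spread_xi: float = 0.5  # search spread over xi; mu spread follows the prior STD

    def __post_init__(self):
        if not (0 < self.elites <= self.population):
            raise ValueError("need 0 < elites <= population")
        if self.sigma_thres < 0 or self.max_generations < 1:
            raise ValueError("invalid threshold or generation cap")


@dataclass
class GoalSpec:
    """Either a full goal observation or a color to pursue/avoid."""

    kind: str                      # "full" | "color"
    observation: np.ndarray = None
    color: tuple = None            # RGB in [0,1]
    mode: str = "pursue"           # "pursue" | "avoid"

    def __post_init__(self):
        if self.kind not in ("full", "color"):
            raise ValueError(f"unknown goal kind {self.kind!r}")
        if self.kind == "full":
            if self.observation is None:
                raise ValueError("full goal requires an observation")
            self.observation = np.asarray(self.observation, dtype=np.float64)
        else:
            if self.color is None:
                raise ValueError("color goal requires a color")
            self.color = tuple(float(c) for c in self.color)
            if any(c < 0 or c > 1 for c in self.color):
                raise ValueError("color components must lie in [0,1]")
            if self.mode not in ("pursue", "avoid"):
                raise ValueError(f"unknown color mode {self.mode!r}")


class GoalMemory:
    """Terminal observations with their associated (revaluable) rewards."""

    def __init__(self, max_per_exit: int = 20):
        self.max_per_exit = max_per_exit
        self._entries: list[dict] = []

    def __len__(self):
        return len(self._entries)

    @property
    def entries(self):
        return list(self._entries)

    def add(self, obs: np.ndarray, reward: float, exit_id: str):
        self._entries.append({"obs": np.asarray(obs, dtype=np.float64),
                              "reward": float(reward), "exit": exit_id})
        per = [e for e in self._entries if e["exit"] == exit_id]
        if len(per) > self.max_per_exit:
            oldest = per[0]
            self._entries = [e for e in self._entries if e is not oldest]

    def revalue(self, reward_map: dict):
        """Rewrite memorized rewards per exit identity (outcome revaluation)."""
        known = {e["exit"] for e in self._entries}
        for exit_id in reward_map:
            if exit_id not in ("left", "right"):
                raise KeyError(f"unknown exit id {exit_id!r}")
        del known
        for e in self._entries:
            if e["exit"] in reward_map:
                e["reward"] = float(reward_map[e["exit"]])

    def select_goal(self, rng: np.random.Generator):
        """Uniform draw among the entries carrying the maximal reward."""
        if not self._entries:
            raise LookupError("no goal available: goal memory is empty")
        best = max(e["reward"] for e in self._entries)
        pool = [e for e in self._entries if e["reward"] == best]
        e = pool[rng.integers(0, len(pool))]
        return e["obs"], e["exit"]


def save_goal_png(observation: np.ndarray, path):
    """Export a goal observation as an 8-bit PNG."""
    from PIL import Image

    arr = (np.clip(np.asarray(observation), 0, 1) * 255).astype(np.uint8)
    Image.fromarray(arr).save(path)


def load_goal_png(path) -> np.ndarray:
    """Import a goal observation from PNG back into [0,1] floats."""
    from PIL import Image

    return np.asarray(Image.open(path), dtype=np.float64)[..., :3] / 255.0


def color_goal_score(pred_future: np.ndarray, color, mode: str,
                     tolerance: float = 0.25, pursue_scale: float = 5.0,
                     avoid_scale: float = 100.0) -> float:
    """Signed, scaled count of pixels matching the goal color.

    S counts entries with |pred - G_c| < tolerance (strict).  Pursue returns
    -pursue_scale*S (minimization rewards matches); avoid returns
    +avoid_scale*S (minimization suppresses matches).
    """
    pred = np.asarray(pred_future, dtype=np.float64)
    g = np.asarray(color, dtype=np.float64).reshape((1,) * (pred.ndim - 1) + (3,))
    s = float((np.abs(pred - g) < tolerance).sum())
    if mode == "pursue":
        return -pursue_scale * s
    if mode == "avoid":
        return avoid_scale * s
    raise ValueError(f"unknown color mode {mode!r}")


def _bernoulli_ll(pred: np.ndarray, target: np.ndarray, axes) -> np.ndarray:
    p = np.clip(pred, 1e-6, 1 - 1e-6)
    return (target * np.log(p) + (1 - target) * np.log(1 - p)).sum(axis=axes)


def _score_candidates(model: AgentModel, mu_c, xi_c, obs_cur, goal: GoalSpec,
                      prior: IntentionParams, config: AIfConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Vector of free-energy losses, one per candidate (mu, xi) row."""
    P, zdim = mu_c.shape
    sigma_c = softplus(xi_c)
    z = mu_c + rng.standard_normal((P, zdim)) * sigma_c
    with ad.no_grad():
        pred_cur_t, pred_fut_t = model.decode_predictions(z)
    pred_cur = pred_cur_t.data.transpose(0, 2, 3, 1)
    pred_fut = pred_fut_t.data.transpose(0, 2, 3, 1)
    ll_cur = _bernoulli_ll(pred_cur, np.asarray(obs_cur)[None], (1, 2, 3))
    if goal.kind == "full":
        goal_term = -_bernoulli_ll(pred_fut, goal.observation[None], (1, 2, 3))
    else:
        g = np.asarray(goal.color).reshape(1, 1, 1, 3)
        s = (np.abs(pred_fut - g) < config.color_tolerance).sum(axis=(1, 2, 3))
        sign = -config.pursue_scale if goal.mode == "pursue" else config.avoid_scale
        goal_term = sign * s
    sp = np.maximum(prior.sigma, 1e-6)[None]
    kl = (np.log(sp / sigma_c) + ((mu_c - prior.mu[None]) ** 2 + sigma_c**2)
          / (2 * sp**2) - 0.5).sum(axis=1)
    return -ll_cur + goal_term + config.beta_z * kl


def aif_loss(cand: IntentionParams, current_obs, goal: GoalSpec,
             prior: IntentionParams, model: AgentModel,
             config: AIfConfig | None = None,
             rng: np.random.Generator | None = None) -> float:
    """Free energy of one candidate intention with respect to a goal."""
    config = config or AIfConfig()
    rng = rng or np.random.default_rng(0)
    xi = cand.xi if cand.xi is not None else softplus_inv(cand.sigma)
    return float(_score_candidates(model, cand.mu[None], xi[None], current_obs,
                                   goal, prior, config, rng)[0])


def cem_minimize(score_fn, init_mean: np.ndarray, init_spread: np.ndarray,
                 config: AIfConfig, rng: np.random.Generator, stop_fn=None):
    """Generic cross-entropy-method loop.

    Each generation draws ``population`` candidate vectors around the search
    mean, keeps the ``elites`` lowest-scoring ones and refits mean/STD to
    them (no smoothing).  ``stop_fn(mean)``, checked after each refit, may
    end the search early.  Returns (mean, generations_used).
    """
    m = np.array(init_mean, dtype=np.float64)
    s = np.array(init_spread, dtype=np.float64)
    generations = 0
    for _ in range(config.max_generations):
        cand = m[None] + rng.standard_normal((config.population, m.size)) * s[None]
        losses = np.asarray(score_fn(cand))
        elite = cand[np.argsort(losses)[: config.elites]]
        m = elite.mean(axis=0)
        s = np.maximum(elite.std(axis=0), 1e-8)
        generations += 1
        if stop_fn is not None and stop_fn(m):
            break
    return m, generations


def cem_optimize(prior: IntentionParams, current_obs, goal: GoalSpec,
                 model: AgentModel, config: AIfConfig | None = None,
                 rng: np.random.Generator | None = None):
    """Cross-entropy-method inference of the posterior intention.

    The search distribution over (mu_q, xi_q) starts at the prior (the KL
    term anchors it there anyway).  After each refit the synergized STD —
    formed from the fitted sigma_q and the prior sigma_p — is checked
    against ``sigma_thres`` for early stop.  Returns
    (posterior IntentionParams, generations_used).
    """
    config = config or AIfConfig()
    rng = rng or np.random.default_rng(0)
    zdim = prior.dim
    init_mean = np.concatenate([prior.mu, softplus_inv(np.maximum(prior.sigma, 1e-6))])
    init_spread = np.concatenate([np.maximum(prior.sigma, 1e-3),
                                  np.full(zdim, config.init_spread_xi)])

    def score(cand):
        return _score_candidates(model, cand[:, :zdim], cand[:, zdim:],
                                 current_obs, goal, prior, config, rng)

    def precise_enough(m):
        posterior = _to_posterior(m, zdim)
        return float(np.mean(synergize(prior, posterior).sigma)) <= config.sigma_thres

    m, generations = cem_minimize(score, init_mean, init_spread, config, rng,
                                  stop_fn=precise_enough)
    return _to_posterior(m, zdim), generations


def _to_posterior(m: np.ndarray, zdim: int) -> IntentionParams:
    sigma = np.maximum(softplus(m[zdim:]), 1e-6)
    return IntentionParams(mu=m[:zdim], sigma=sigma, role="posterior", xi=m[zdim:])
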