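"""Sequence replay and the end-to-end training step.

One gradient step minimizes

    total = prediction errors (current + future, Bernoulli negative
            log-likelihood) + beta_z * KL[posterior || prior]
            + beta_a * policy loss + value loss

averaged over a batch of replayed sequences.  The posterior intention is
inferred per step from the (current, uniformly-sampled-future) observation
pair; the prior comes from the recurrent context unrolled from a zero state
at each sequence start.  The RL part is soft actor-critic with twin critics,
target networks and an adaptive entropy temperature whose target is annealed
linearly over the training course.

Episodes that end by the step cap are flagged done for episode control but
non-terminal for bootstrapping, so values are not biased at timeouts.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .networks import AgentModel, tanh_gaussian_log_prob


@dataclass
class LearnConfig:
    beta_z: float = 0.1
    beta_a: float = 1e5
    gamma: float = 0.9
    update_interval: int = 5          # gradient step every N environment steps
    batch_sequences: int = 60
    sequence_length: int = 60
    buffer_capacity: int = 2**13
    target_entropy_start: float = 0.0
    target_entropy_end: float = -4.0
    anneal_steps: int = 200_000       # env steps over which the target anneals
    lr: float = 3e-4
    alpha_lr: float = 3e-4        # entropy-temperature adaptation rate
    polyak_tau: float = 0.005
    seed: int = 0

    def __post_init__(self):
        for name in ("gamma", "update_interval", "batch_sequences",
                     "sequence_length", "buffer_capacity", "lr", "polyak_tau",
                     "anneal_steps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.target_entropy_end > self.target_entropy_start:
            raise ValueError("target entropy schedule must be non-increasing")

    def target_entropy(self, env_step: int) -> float:
        frac = min(max(env_step / self.anneal_steps, 0.0), 1.0)
        return self.target_entropy_start + frac * (
            self.target_entropy_end - self.target_entropy_start)


@dataclass
class Transition:
    obs: np.ndarray
    next_obs: np.ndarray
    action: np.ndarray
    reward: float
    done: bool
    terminal: bool = None  # False at timeouts even though done is True

    def __post_init__(self):
        if self.terminal is None:
            self.terminal = self.done


class ReplayBuffer:
    """Ring of experience sequences; sequences never span episode boundaries.

    A done flag or reaching ``max_len`` closes the open sequence; when the
    ring is full the oldest closed sequence is evicted first.
    """

    def __init__(self, capacity: int = 2**13, max_len: int = 60):
        self.capacity = capacity
        self.max_len = max_len
        self._ring = deque(maxlen=capacity)
        self._open: list[Transition] = []

    def __len__(self):
        return len(self._ring)

    @property
    def sequences(self):
        return self._ring

    def store(self, transition: Transition):
        self._open.append(transition)
        if transition.done or len(self._open) >= self.max_len:
            self._ring.append(self._open)
            self._open = []

    def sample(self, rng: np.random.Generator, n: int):
        idx = rng.integers(0, len(self._ring), size=n)
        return [self._ring[i] for i in idx]


def sample_future_index(t: int, episode_end: int, rng: np.random.Generator) -> int:
    """Uniform integer on [t+1, episode_end] inclusive."""
    if t >= episode_end:
        raise ValueError("no future observation available")
    return int(rng.integers(t + 1, episode_end + 1))


def bernoulli_loglik(pred, target) -> "Tensor | float":
    """Sum over pixels of target*ln(pred) + (1-target)*ln(1-pred).

    Probabilities are clamped to [1e-6, 1-1e-6].  Accepts an autodiff Tensor
    prediction (returns a Tensor) or plain arrays (returns a float).
    """
    eps = 1e-6
    if isinstance(pred, Tensor):
        tgt = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=np.float64))
        if pred.shape != tgt.shape:
            raise ValueError("prediction/target shape mismatch")
        p = pred.clip(eps, 1.0 - eps)
        return (tgt * p.log() + (1.0 - tgt) * (1.0 - p).log()).sum()
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError("prediction/target shape mismatch")
    p = np.clip(pred, eps, 1.0 - eps)
    return float((target * np.log(p) + (1.0 - target) * np.log(1.0 - p)).sum())


@dataclass
class LossBreakdown:
    pred_current: float
    pred_future: float
    kl: float
    policy: float
    value: float
    alpha: float
    total: float = field(default=None)

    def __post_init__(self):
        parts = [self.pred_current, self.pred_future, self.kl, self.policy,
                 self.value, self.alpha]
        if any(not np.isfinite(v) for v in parts):
            raise FloatingPointError(f"non-finite loss components: {self}")
        if self.total is None:
            self.total = (self.pred_current + self.pred_future + self.kl
                          + self.policy + self.value)

    def as_dict(self):
        return {
            "pred_current": self.pred_current, "pred_future": self.pred_future,
            "kl": self.kl, "policy": self.policy, "value": self.value,
            "alpha": self.alpha, "total": self.total,
        }


class Trainer:
    """Owns the optimizer state; performs one end-to-end gradient step."""

    def __init__(self, model: AgentModel, config: LearnConfig | None = None):
        self.model = model
        self.config = config or LearnConfig()
        g = model.param_groups()
        net_params = model.main_parameters() + g["critics"]
        self.optimizer = ad.Adam(net_params, lr=self.config.lr)
        # the temperature has its own rate: its adaptation speed must track
        # the (possibly compressed) length of the training schedule
        self.alpha_optimizer = ad.Adam([model.log_alpha], lr=self.config.alpha_lr)
        self.rng = np.random.default_rng(self.config.seed)
        self.updates_done = 0

    # -- batch assembly -------------------------------------------------------
    def _assemble(self, sequences):
        """Stack sequences into padded arrays with a validity mask."""
        cfg = self.model.cfg
        h, w, c = cfg.image_shape
        B = len(sequences)
        L = max(len(s) for s in sequences)
        obs = np.zeros((B, L + 1, h, w, c))
        act = np.zeros((B, L, cfg.action_dim))
        rew = np.zeros((B, L))
        term = np.zeros((B, L))
        mask = np.zeros((B, L))
        fut_idx = np.zeros((B, L), dtype=int)
        lengths = np.zeros(B, dtype=int)
        for b, seq in enumerate(sequences):
            n = len(seq)
            lengths[b] = n
            for t, tr in enumerate(seq):
                obs[b, t] = tr.obs
                act[b, t] = tr.action
                rew[b, t] = tr.reward
                term[b, t] = float(tr.terminal)
                mask[b, t] = 1.0
                fut_idx[b, t] = sample_future_index(t, n, self.rng)
            obs[b, n] = seq[-1].next_obs
            # padded steps point future at themselves; they are masked out
            fut_idx[b, n:] = n
        return obs, act, rew, term, mask, fut_idx, lengths

    def _posterior_over_batch(self, obs, fut_idx, L):
        """Posterior (mu, xi) tensors for every step, flattened to (B*L, zdim)."""
        B = obs.shape[0]
        cur = obs[:, :L].reshape(B * L, *obs.shape[2:])
        fut = obs[np.arange(B)[:, None], fut_idx[:, :L]].reshape(B * L, *obs.shape[2:])
        return self.model.posterior_encoder(cur, fut)

    # -- the gradient step ----------------------------------------------------
    def train_step(self, buffer: ReplayBuffer, env_step: int = 0):
        """One optimization step on a batch sampled from the buffer.

        Returns a LossBreakdown, or None (with no update) when the buffer
        holds fewer closed sequences than the batch size.
        """
        cfg = self.config
        if len(buffer) < cfg.batch_sequences:
            return None
        sequences = buffer.sample(self.rng, cfg.batch_sequences)
        breakdown = self._train_on_sequences(sequences, env_step)
        self.model.polyak_update(cfg.polyak_tau)
        self.updates_done += 1
        return breakdown

    def _train_on_sequences(self, sequences, env_step: int = 0) -> LossBreakdown:
        cfg = self.config
        model = self.model
        obs, act, rew, term, mask, fut_idx, lengths = self._assemble(sequences)
        B, L = mask.shape
        zdim = model.cfg.intention_dim
        n_valid = mask.sum()
        mask_t = Tensor(mask.reshape(B * L, 1))

        # ---- recurrent prior over the sequences
        feats = model.encode_observation(obs[:, :L].reshape(B * L, *obs.shape[2:]))
        feats_bl = [feats[np.arange(B) * L + t] for t in range(L)]
        hstate = model.init_context(B)
        prior_mu_steps, prior_xi_steps = [], []
        for t in range(L):
            hstate = model.update_context(hstate, feats_bl[t])
            mu_p, xi_p = model.prior_head(hstate)
            prior_mu_steps.append(mu_p)
            prior_xi_steps.append(xi_p)
        # (B, L, z) -> (B*L, z) with the same flattening order as feats
        prior_mu = ad.concat([m.reshape(B, 1, zdim) for m in prior_mu_steps], axis=1).reshape(B * L, zdim)
        prior_xi = ad.concat([x.reshape(B, 1, zdim) for x in prior_xi_steps], axis=1).reshape(B * L, zdim)
        prior_sigma = prior_xi.softplus()

        # ---- amortized posterior and reparameterized z
        post_mu, post_xi = self._posterior_over_batch(obs, fut_idx, L)
        post_sigma = post_xi.softplus()
        eps_z = self.rng.standard_normal((B * L, zdim))
        z = post_mu + Tensor(eps_z) * post_sigma

        # ---- decode and prediction errors (masked mean over steps)
        pred_cur, pred_fut = model.decode_predictions(z)
        tgt_cur = Tensor(np.ascontiguousarray(
            obs[:, :L].reshape(B * L, *obs.shape[2:]).transpose(0, 3, 1, 2)))
        tgt_fut = Tensor(np.ascontiguousarray(
            obs[np.arange(B)[:, None], fut_idx[:, :L]]
            .reshape(B * L, *obs.shape[2:]).transpose(0, 3, 1, 2)))
        eps = 1e-6
        pc = pred_cur.clip(eps, 1 - eps)
        pf = pred_fut.clip(eps, 1 - eps)
        ll_cur = ((tgt_cur * pc.log() + (1 - tgt_cur) * (1 - pc).log())
                  .sum(axis=1).sum(axis=1).sum(axis=1).reshape(B * L, 1))
        ll_fut = ((tgt_fut * pf.log() + (1 - tgt_fut) * (1 - pf).log())
                  .sum(axis=1).sum(axis=1).sum(axis=1).reshape(B * L, 1))
        pred_err_cur = -(ll_cur * mask_t).sum() * (1.0 / n_valid)
        pred_err_fut = -(ll_fut * mask_t).sum() * (1.0 / n_valid)

        # ---- complexity: analytic KL[q || p], masked mean
        kl = ((prior_sigma / post_sigma).log()
              + ((post_mu - prior_mu) * (post_mu - prior_mu) + post_sigma * post_sigma)
              / (2.0 * prior_sigma * prior_sigma) - 0.5)
        kl_mean = (kl.sum(axis=1, keepdims=True) * mask_t).sum() * (1.0 / n_valid)

        # ---- SAC policy loss conditioned on posterior z
        alpha_const = float(np.exp(model.log_alpha.data[0]))
        mu_a, sigma_a = model.policy(z)
        eps_a = self.rng.standard_normal(mu_a.shape)
        u = mu_a + Tensor(eps_a) * sigma_a
        a_new = u.tanh()
        logp = tanh_gaussian_log_prob(u, mu_a, sigma_a)
        obs_flat = Tensor(np.ascontiguousarray(
            obs[:, :L].reshape(B * L, *obs.shape[2:]).transpose(0, 3, 1, 2)))
        q_news = []
        critic_params = [p for cr in model.critics for p in cr.parameters()]
        for p in critic_params:  # critics act as fixed scorers for the actor
            p.requires_grad = False
        try:
            for cr in model.critics:
                q_news.append(cr(obs_flat, a_new))
        finally:
            for p in critic_params:
                p.requires_grad = True
        q_min = ad.minimum(q_news[0], q_news[1])
        policy_loss = ((alpha_const * logp - q_min) * mask_t).sum() * (1.0 / n_valid)

        # ---- SAC value loss (gradients confined to the critics)
        with ad.no_grad():
            targets = self._bellman_targets(obs, rew, term, fut_idx, lengths,
                                            mask, alpha_const, env_step)
        tgt_t = Tensor(targets.reshape(B * L, 1))
        value_loss = Tensor(np.zeros(()))
        act_t = Tensor(act.reshape(B * L, -1))
        for cr in model.critics:
            q = cr(obs_flat, act_t)
            value_loss = value_loss + ((q - tgt_t) * (q - tgt_t) * mask_t).sum() * (1.0 / n_valid)

        # ---- temperature adaptation toward the annealed target entropy
        h_target = cfg.target_entropy(env_step)
        alpha_loss = (model.log_alpha * float(-((logp.data + h_target) * mask.reshape(-1, 1)).sum() / n_valid)).sum()

        total = (pred_err_cur + pred_err_fut + cfg.beta_z * kl_mean
                 + cfg.beta_a * policy_loss + value_loss + alpha_loss)
        if not np.isfinite(total.data):
            raise FloatingPointError("non-finite training loss")
        self.optimizer.zero_grad()
        self.alpha_optimizer.zero_grad()
        total.backward()
        self.optimizer.step()
        self.alpha_optimizer.step()

        return LossBreakdown(
            pred_current=float(pred_err_cur.data),
            pred_future=float(pred_err_fut.data),
            kl=cfg.beta_z * float(kl_mean.data),
            policy=cfg.beta_a * float(policy_loss.data),
            value=float(value_loss.data),
            alpha=float(alpha_loss.data),
        )

    def _bellman_targets(self, obs, rew, term, fut_idx, lengths, mask,
                         alpha: float, env_step: int) -> np.ndarray:
        """r + gamma * (1-terminal) * (min_i Q_target_i(s', a') - alpha log pi(a')).

        Next-step actions are drawn through the posterior-intention pathway,
        matching the learning-time policy conditioning.
        """
        model = self.model
        cfg = self.config
        B, L = rew.shape
        zdim = model.cfg.intention_dim
        # posterior at the next step: pair (obs_{t+1}, obs_{t''}), t'' in [t+2, end]
        nxt = np.minimum(np.arange(1, L + 1)[None, :].repeat(B, 0), lengths[:, None])
        fut2 = np.zeros((B, L), dtype=int)
        for b in range(B):
            for t in range(L):
                lo = min(nxt[b, t] + 1, lengths[b])
                fut2[b, t] = self.rng.integers(lo, lengths[b] + 1) if lo <= lengths[b] else lengths[b]
        cur_n = obs[np.arange(B)[:, None], nxt].reshape(B * L, *obs.shape[2:])
        fut_n = obs[np.arange(B)[:, None], fut2].reshape(B * L, *obs.shape[2:])
        mu_q, xi_q = model.posterior_encoder(cur_n, fut_n)
        sig_q = np.logaddexp(0.0, xi_q.data)
        z_n = mu_q.data + self.rng.standard_normal((B * L, zdim)) * sig_q
        mu_a, sigma_a = model.policy(z_n)
        u = mu_a.data + self.rng.standard_normal(mu_a.shape) * sigma_a.data
        a_n = np.tanh(u)
        logp = (tanh_gaussian_log_prob(Tensor(u), Tensor(mu_a.data), Tensor(sigma_a.data))).data
        obs_n_t = Tensor(np.ascontiguousarray(cur_n.transpose(0, 3, 1, 2)))
        a_n_t = Tensor(a_n)
        q1 = model.q_value(obs_n_t, a_n_t, 0, target=True).data
        q2 = model.q_value(obs_n_t, a_n_t, 1, target=True).data
        v_next = (np.minimum(q1, q2) - alpha * logp).reshape(B, L)
        return rew + cfg.gamma * (1.0 - term) * v_next * mask


def free_energy_components(trainer: Trainer, sequences) -> dict:
    """Free-energy terms of a batch without updating parameters.

    Convenience wrapper used by diagnostics and tests; shares the assembly
    and loss code path with training but discards gradients.
    """
    model = trainer.model
    cfg = trainer.config
    obs, act, rew, term, mask, fut_idx, lengths = trainer._assemble(sequences)
    B, L = mask.shape
    zdim = model.cfg.intention_dim
    n_valid = mask.sum()
    with ad.no_grad():
        feats = model.encode_observation(obs[:, :L].reshape(B * L, *obs.shape[2:]))
        hstate = model.init_context(B)
        mus, xis = [], []
        for t in range(L):
            hstate = model.update_context(hstate, feats[np.arange(B) * L + t])
            mu_p, xi_p = model.prior_head(hstate)
            mus.append(mu_p.data)
            xis.append(xi_p.data)
        prior_mu = np.stack(mus, axis=1).reshape(B * L, zdim)
        prior_sigma = np.logaddexp(0.0, np.stack(xis, axis=1).reshape(B * L, zdim))
        post_mu_t, post_xi_t = trainer._posterior_over_batch(obs, fut_idx, L)
        post_mu, post_sigma = post_mu_t.data, np.logaddexp(0.0, post_xi_t.data)
        z = post_mu + trainer.rng.standard_normal((B * L, zdim)) * post_sigma
        pred_cur, pred_fut = model.decode_predictions(z)
    tgt_cur = obs[:, :L].reshape(B * L, *obs.shape[2:]).transpose(0, 3, 1, 2)
    tgt_fut = (obs[np.arange(B)[:, None], fut_idx[:, :L]]
               .reshape(B * L, *obs.shape[2:]).transpose(0, 3, 1, 2))
    p_cur = np.clip(pred_cur.data, 1e-6, 1 - 1e-6)
    p_fut = np.clip(pred_fut.data, 1e-6, 1 - 1e-6)
    ll_cur = (tgt_cur * np.log(p_cur) + (1 - tgt_cur) * np.log(1 - p_cur)).sum(axis=(1, 2, 3))
    ll_fut = (tgt_fut * np.log(p_fut) + (1 - tgt_fut) * np.log(1 - p_fut)).sum(axis=(1, 2, 3))
    kl = (np.log(prior_sigma / post_sigma)
          + ((post_mu - prior_mu) ** 2 + post_sigma**2) / (2 * prior_sigma**2)
          - 0.5).sum(axis=1)
    m = mask.reshape(-1)
    return {
        "pred_current": float(-(ll_cur * m).sum() / n_valid),
        "pred_future": float(-(ll_fut * m).sum() / n_valid),
        "kl": float((kl * m).sum() / n_valid),
        "beta_z": cfg.beta_z,
        "free_energy": float((-(ll_cur + ll_fut) * m).sum() / n_valid
                             + cfg.beta_z * (kl * m).sum() / n_valid),
    }
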