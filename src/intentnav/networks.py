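"""Differentiable function approximators of the agent.

One observation encoder (strided conv stack), a GRU context, a prior head
producing the habitual intention, an amortized posterior encoder over
(current, future) observation pairs, an image decoder predicting current and
future observations from the intention, tanh-squashed Gaussian policy heads,
and twin critics with their own observation encoders (independent of the
main model, touched only by the value loss).

All tensors use NCHW internally; the public surface takes/returns HWC float
images in [0, 1] and plain NumPy vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .intention import IntentionParams

LOG_2PI = float(np.log(2.0 * np.pi))


# -- configuration -------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Layer sizing; presets scale the same topology up or down."""

    image_shape: tuple = (16, 64, 3)
    hidden_width: int = 256
    rnn_size: int = 256
    intention_dim: int = 4
    action_dim: int = 2
    # (out_channels, kernel, stride, padding) per conv layer
    conv_specs: tuple = (
        (8, (4, 4), (2, 2), (1, 1)),
        (16, (4, 4), (2, 2), (1, 1)),
        (16, (4, 4), (2, 2), (1, 1)),
        (64, (2, 4), (2, 2), (0, 1)),
        (256, (1, 4), (1, 4), (0, 0)),
    )
    # (out_channels, kernel, stride, padding, output_padding) per deconv layer
    deconv_specs: tuple = (
        (64, (1, 4), (1, 1), (0, 0), (0, 0)),
        (16, (2, 4), (1, 2), (0, 1), (0, 0)),
        (16, (4, 4), (2, 2), (1, 1), (0, 0)),
        (8, (4, 4), (2, 2), (1, 1), (0, 0)),
        (8, (3, 3), (2, 2), (1, 1), (1, 1)),
    )
    final_conv: tuple = (6, (3, 3), (1, 1), (1, 1))

    def __post_init__(self):
        if min(self.hidden_width, self.rnn_size, self.intention_dim, self.action_dim) <= 0:
            raise ValueError("network sizes must be positive")

    @property
    def feature_dim(self) -> int:
        return self.conv_specs[-1][0]

    @classmethod
    def default(cls) -> "NetworkConfig":
        return cls()

    @classmethod
    def tiny(cls) -> "NetworkConfig":
        """Desk-scale preset: 8x16 images, width-32 trunk, same topology."""
        return cls(
            image_shape=(8, 16, 3),
            hidden_width=32,
            rnn_size=32,
            conv_specs=(
                (4, (4, 4), (2, 2), (1, 1)),
                (8, (4, 4), (2, 2), (1, 1)),
                (16, (2, 4), (2, 2), (0, 1)),
                (32, (1, 2), (1, 2), (0, 0)),
            ),
            deconv_specs=(
                (16, (1, 2), (1, 2), (0, 0), (0, 0)),
                (8, (2, 4), (1, 2), (0, 1), (0, 0)),
                (8, (4, 4), (2, 2), (1, 1), (0, 0)),
                (4, (3, 3), (2, 2), (1, 1), (1, 1)),
            ),
        )

    @classmethod
    def micro(cls) -> "NetworkConfig":
        """Width-4 preset for numerical gradient checks."""
        return cls(
            image_shape=(4, 8, 3),
            hidden_width=4,
            rnn_size=8,
            conv_specs=(
                (4, (4, 4), (2, 2), (1, 1)),
                (8, (2, 4), (2, 2), (0, 1)),
                (8, (1, 2), (1, 2), (0, 0)),
            ),
            deconv_specs=(
                (8, (1, 2), (1, 2), (0, 0), (0, 0)),
                (4, (2, 4), (1, 2), (0, 1), (0, 0)),
                (4, (3, 3), (2, 2), (1, 1), (1, 1)),
            ),
        )


# -- building blocks -----------------------------------------------------------

class Linear:
    def __init__(self, nin, nout, rng):
        scale = np.sqrt(2.0 / nin)
        self.w = Tensor(rng.normal(0.0, scale, size=(nin, nout)), requires_grad=True)
        self.b = Tensor(np.zeros(nout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class MLP2:
    """2-layer perceptron with ReLU hidden activation."""

    def __init__(self, nin, hidden, nout, rng):
        self.l1 = Linear(nin, hidden, rng)
        self.l2 = Linear(hidden, nout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).relu())

    def parameters(self):
        return self.l1.parameters() + self.l2.parameters()


class Conv:
    def __init__(self, cin, cout, kernel, stride, padding, rng):
        kh, kw = kernel
        scale = np.sqrt(2.0 / (cin * kh * kw))
        self.w = Tensor(rng.normal(0.0, scale, size=(cout, cin, kh, kw)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv2d(x, self.w, self.b, self.stride, self.padding)

    def parameters(self):
        return [self.w, self.b]


class ConvT:
    def __init__(self, cin, cout, kernel, stride, padding, output_padding, rng):
        kh, kw = kernel
        scale = np.sqrt(2.0 / (cin * kh * kw))
        self.w = Tensor(rng.normal(0.0, scale, size=(cin, cout, kh, kw)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.stride, self.padding, self.output_padding = stride, padding, output_padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_transpose2d(x, self.w, self.b, self.stride, self.padding,
                                   self.output_padding)

    def parameters(self):
        return [self.w, self.b]


class ConvEncoder:
    """Strided conv stack + flatten; ReLU after every layer."""

    def __init__(self, cfg: NetworkConfig, in_channels, rng):
        self.cfg = cfg
        self.layers = []
        cin = in_channels
        for cout, k, s, p in cfg.conv_specs:
            self.layers.append(Conv(cin, cout, k, s, p, rng))
            cin = cout

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
        n = x.shape[0]
        return x.reshape(n, -1)

    def parameters(self):
        return [p for l in self.layers for p in l.parameters()]


class GRUCell:
    def __init__(self, nin, nh, rng):
        s_in, s_h = np.sqrt(1.0 / nin), np.sqrt(1.0 / nh)
        mk = lambda shape, s: Tensor(rng.normal(0.0, s, size=shape), requires_grad=True)
        self.wxr, self.wxu, self.wxn = (mk((nin, nh), s_in) for _ in range(3))
        self.whr, self.whu, self.whn = (mk((nh, nh), s_h) for _ in range(3))
        self.br = Tensor(np.zeros(nh), requires_grad=True)
        self.bu = Tensor(np.zeros(nh), requires_grad=True)
        self.bn = Tensor(np.zeros(nh), requires_grad=True)
        self.bhn = Tensor(np.zeros(nh), requires_grad=True)
        self.nh = nh

    def __call__(self, h: Tensor, x: Tensor) -> Tensor:
        r = (x @ self.wxr + h @ self.whr + self.br).sigmoid()
        u = (x @ self.wxu + h @ self.whu + self.bu).sigmoid()
        n = (x @ self.wxn + r * (h @ self.whn + self.bhn) + self.bn).tanh()
        return (1.0 - u) * n + u * h

    def parameters(self):
        return [self.wxr, self.wxu, self.wxn, self.whr, self.whu, self.whn,
                self.br, self.bu, self.bn, self.bhn]


class Decoder:
    """2-layer MLP lift + transposed-conv stack; last layer emits 6 channels
    (predicted current RGB + predicted future RGB), logistic-squashed."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.cfg = cfg
        self.lift = MLP2(cfg.intention_dim, cfg.hidden_width, cfg.feature_dim, rng)
        self.layers = []
        cin = cfg.feature_dim
        for cout, k, s, p, op in cfg.deconv_specs:
            self.layers.append(ConvT(cin, cout, k, s, p, op, rng))
            cin = cout
        cout, k, s, p = cfg.final_conv
        self.final = Conv(cin, cout, k, s, p, rng)

    def __call__(self, z: Tensor):
        n = z.shape[0]
        x = self.lift(z).relu().reshape(n, self.cfg.feature_dim, 1, 1)
        for layer in self.layers:
            x = layer(x).relu()
        x = self.final(x).sigmoid()
        pred_cur = x[:, 0:3]
        pred_fut = x[:, 3:6]
        return pred_cur, pred_fut  # NCHW

    def parameters(self):
        return (self.lift.parameters()
                + [p for l in self.layers for p in l.parameters()]
                + self.final.parameters())


class Critic:
    """Q(obs, action) with its own observation encoder (Table-1 shaped)."""

    def __init__(self, cfg: NetworkConfig, rng):
        self.encoder = ConvEncoder(cfg, 3, rng)
        self.head = MLP2(cfg.feature_dim + cfg.action_dim, cfg.hidden_width, 1, rng)

    def __call__(self, obs_nchw: Tensor, action: Tensor) -> Tensor:
        feat = self.encoder(obs_nchw)
        return self.head(ad.concat([feat, action], axis=1))

    def parameters(self):
        return self.encoder.parameters() + self.head.parameters()


def _hwc_to_nchw(obs) -> Tensor:
    arr = np.asarray(obs, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr[None]
    return Tensor(np.ascontiguousarray(arr.transpose(0, 3, 1, 2)))


def _nchw_to_hwc(t: Tensor) -> np.ndarray:
    return t.data.transpose(0, 2, 3, 1)


class AgentModel:
    """All trainable networks of the agent, with named parameter groups."""

    CHECKPOINT_VERSION = 1

    def __init__(self, cfg: NetworkConfig | None = None, seed: int = 0):
        self.cfg = cfg or NetworkConfig.default()
        rng = np.random.default_rng(seed)
        c = self.cfg
        self.encoder = ConvEncoder(c, 3, rng)
        self.gru = GRUCell(c.feature_dim, c.rnn_size, rng)
        self.prior_mu = MLP2(c.rnn_size, c.hidden_width, c.intention_dim, rng)
        self.prior_xi = MLP2(c.rnn_size, c.hidden_width, c.intention_dim, rng)
        self.post_trunk = ConvEncoder(c, 6, rng)
        self.post_mu = MLP2(c.feature_dim, c.hidden_width, c.intention_dim, rng)
        self.post_xi = MLP2(c.feature_dim, c.hidden_width, c.intention_dim, rng)
        self.decoder = Decoder(c, rng)
        self.policy_mu = MLP2(c.intention_dim, c.hidden_width, c.action_dim, rng)
        self.policy_xi = MLP2(c.intention_dim, c.hidden_width, c.action_dim, rng)
        self.critics = [Critic(c, rng), Critic(c, rng)]
        self.target_critics = [Critic(c, rng), Critic(c, rng)]
        self.sync_targets()
        self.log_alpha = Tensor(np.zeros(1), requires_grad=True)

    # -- parameter bookkeeping ------------------------------------------------
    def param_groups(self) -> dict:
        groups = {
            "encoder": self.encoder.parameters(),
            "gru": self.gru.parameters(),
            "prior": self.prior_mu.parameters() + self.prior_xi.parameters(),
            "posterior": (self.post_trunk.parameters() + self.post_mu.parameters()
                          + self.post_xi.parameters()),
            "decoder": self.decoder.parameters(),
            "policy": self.policy_mu.parameters() + self.policy_xi.parameters(),
            "critics": [p for cr in self.critics for p in cr.parameters()],
            "alpha": [self.log_alpha],
        }
        return groups

    def main_parameters(self):
        g = self.param_groups()
        return (g["encoder"] + g["gru"] + g["prior"] + g["posterior"]
                + g["decoder"] + g["policy"])

    def all_parameters(self):
        g = self.param_groups()
        return self.main_parameters() + g["critics"] + g["alpha"]

    def sync_targets(self):
        for tc, cr in zip(self.target_critics, self.critics):
            for pt, p in zip(tc.parameters(), cr.parameters()):
                pt.data = p.data.copy()

    def polyak_update(self, tau: float):
        for tc, cr in zip(self.target_critics, self.critics):
            for pt, p in zip(tc.parameters(), cr.parameters()):
                pt.data = (1.0 - tau) * pt.data + tau * p.data

    # -- forward surface ------------------------------------------------------
    def encode_observation(self, obs) -> Tensor:
        """Conv features of an HWC observation (batched or single)."""
        t = obs if isinstance(obs, Tensor) else _hwc_to_nchw(obs)
        self._check_image(t)
        return self.encoder(t)

    def _check_image(self, t: Tensor):
        h, w, _ = self.cfg.image_shape
        if t.shape[-2:] != (h, w) or t.shape[1] not in (3, 6):
            raise ValueError(f"observation shape {t.shape} incompatible with {self.cfg.image_shape}")

    def init_context(self, batch: int = 1) -> Tensor:
        return Tensor(np.zeros((batch, self.cfg.rnn_size)))

    def update_context(self, h: Tensor, feat: Tensor) -> Tensor:
        return self.gru(h, feat)

    def prior_head(self, h: Tensor):
        """(mu, xi) tensors of the prior intention; sigma = softplus(xi)."""
        return self.prior_mu(h), self.prior_xi(h)

    def prior_params(self, h: Tensor) -> IntentionParams:
        mu, xi = self.prior_head(h)
        return IntentionParams.from_xi(mu.data[0], xi.data[0], role="prior")

    def posterior_encoder(self, obs_t, obs_future):
        """(mu, xi) of the amortized posterior from the channel-concatenated pair."""
        a = obs_t if isinstance(obs_t, Tensor) else _hwc_to_nchw(obs_t)
        b = obs_future if isinstance(obs_future, Tensor) else _hwc_to_nchw(obs_future)
        pair = ad.concat([a, b], axis=1)
        self._check_image(pair)
        feat = self.post_trunk(pair)
        return self.post_mu(feat), self.post_xi(feat)

    def decode_predictions(self, z):
        """Predicted (current, future) observations (HWC, in (0,1)) from z."""
        zt = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
        cur, fut = self.decoder(zt)
        return cur, fut  # NCHW tensors; use decode_images for HWC arrays

    def decode_images(self, z):
        with ad.no_grad():
            cur, fut = self.decode_predictions(z)
        return _nchw_to_hwc(cur), _nchw_to_hwc(fut)

    def policy(self, z):
        """Pre-squash action distribution (mu_a, sigma_a) from intention z."""
        zt = z if isinstance(z, Tensor) else Tensor(np.atleast_2d(np.asarray(z, dtype=np.float64)))
        mu = self.policy_mu(zt)
        sigma = self.policy_xi(zt).softplus()
        return mu, sigma

    def sample_action(self, z, eps) -> np.ndarray:
        """a = tanh(mu_a + eps * sigma_a); eps is the exploration noise draw."""
        with ad.no_grad():
            mu, sigma = self.policy(z)
        u = mu.data + np.asarray(eps) * sigma.data
        return np.tanh(u)[0] if u.shape[0] == 1 else np.tanh(u)

    def q_value(self, obs, action, index: int = 0, target: bool = False) -> Tensor:
        obs_t = obs if isinstance(obs, Tensor) else _hwc_to_nchw(obs)
        act_t = action if isinstance(action, Tensor) else Tensor(np.atleast_2d(np.asarray(action, dtype=np.float64)))
        net = (self.target_critics if target else self.critics)[index]
        return net(obs_t, act_t)

    # -- checkpointing --------------------------------------------------------
    def save(self, path):
        arrays = {"__version__": np.array([self.CHECKPOINT_VERSION])}
        for name, params in self.param_groups().items():
            for i, p in enumerate(params):
                arrays[f"{name}/{i}"] = p.data
        for ci, tc in enumerate(self.target_critics):
            for i, p in enumerate(tc.parameters()):
                arrays[f"target_critic{ci}/{i}"] = p.data
        np.savez(path, **arrays)

    def load(self, path):
        data = np.load(path)
        if int(data["__version__"][0]) != self.CHECKPOINT_VERSION:
            raise ValueError("checkpoint version mismatch")
        for name, params in self.param_groups().items():
            for i, p in enumerate(params):
                p.data = data[f"{name}/{i}"].copy()
        for ci, tc in enumerate(self.target_critics):
            for i, p in enumerate(tc.parameters()):
                p.data = data[f"target_critic{ci}/{i}"].copy()


def gaussian_log_prob(u: Tensor, mu: Tensor, sigma: Tensor) -> Tensor:
    """Log density of u under N(mu, diag sigma^2), summed over the last axis."""
    var = sigma * sigma
    return (-0.5 * ((u - mu) * (u - mu)) / var - sigma.log() - 0.5 * LOG_2PI).sum(axis=1, keepdims=True)


def tanh_gaussian_log_prob(u: Tensor, mu: Tensor, sigma: Tensor) -> Tensor:
    """log pi(a) for a = tanh(u) with u ~ N(mu, sigma); includes the
    change-of-variables correction."""
    base = gaussian_log_prob(u, mu, sigma)
    a = u.tanh()
    corr = (1.0 - a * a + 1e-6).log().sum(axis=1, keepdims=True)
    return base - corr
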