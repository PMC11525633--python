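"""Network shapes, determinism, softplus heads, gradient-flow separation."""

import numpy as np
import pytest

from intentnav import _autodiff as ad
from intentnav._autodiff import Tensor
from intentnav.networks import (AgentModel, NetworkConfig,
                                tanh_gaussian_log_prob)


@pytest.fixture(scope="module")
def obs_for():
    def make(model, n=2, seed=0):
        h, w, _ = model.cfg.image_shape
        return np.random.default_rng(seed).uniform(size=(n, h, w, 3))
    return make


@pytest.mark.parametrize("preset,feat", [("default", 256), ("tiny", 32)])
def test_encoder_output_length(preset, feat):
    cfg = getattr(NetworkConfig, preset)()
    model = AgentModel(cfg, seed=0)
    h, w, _ = cfg.image_shape
    out = model.encode_observation(np.zeros((1, h, w, 3)))
    assert out.shape == (1, feat)
    assert np.all(np.isfinite(out.data))


def test_encoder_deterministic_on_identical_images(tiny_model, obs_for):
    obs = obs_for(tiny_model, 1)
    a = tiny_model.encode_observation(obs).data
    b = tiny_model.encode_observation(obs.copy()).data
    assert np.array_equal(a, b)


def test_encoder_rejects_wrong_shape(tiny_model):
    with pytest.raises(ValueError):
        tiny_model.encode_observation(np.zeros((1, 5, 5, 3)))


def test_context_update_finite_and_bounded(tiny_model, rng):
    h = tiny_model.init_context(1)
    feat0 = tiny_model.encode_observation(
        np.zeros((1,) + tuple(tiny_model.cfg.image_shape)))
    h1 = tiny_model.update_context(h, feat0)
    assert np.all(np.isfinite(h1.data))
    # gating keeps the state bounded over a long random rollout
    state = tiny_model.init_context(1)
    for _ in range(1000):
        feat = Tensor(rng.normal(size=(1, tiny_model.cfg.feature_dim)))
        state = tiny_model.update_context(state, feat)
    assert np.abs(state.data).max() <= 1.0 + 1e-9


def test_context_replay_reproduces_final_state(tiny_model, obs_for):
    obs = obs_for(tiny_model, 5)
    def final_state():
        h = tiny_model.init_context(1)
        for i in range(5):
            h = tiny_model.update_context(h, tiny_model.encode_observation(obs[i:i + 1]))
        return h.data
    assert np.array_equal(final_state(), final_state())


def test_prior_head_softplus_parameterization(tiny_model):
    h = tiny_model.init_context(1)
    mu, xi = tiny_model.prior_head(h)
    sigma = np.logaddexp(0, xi.data)
    assert np.all(sigma > 0)
    # softplus(0) = ln 2
    assert np.logaddexp(0, 0.0) == pytest.approx(np.log(2))
    params = tiny_model.prior_params(h)
    assert params.role == "prior" and np.all(params.sigma > 0)


def test_posterior_is_order_sensitive(tiny_model, obs_for):
    a, b = obs_for(tiny_model, 2, seed=7)
    mu_ab, _ = tiny_model.posterior_encoder(a[None], b[None])
    mu_ba, _ = tiny_model.posterior_encoder(b[None], a[None])
    assert not np.allclose(mu_ab.data, mu_ba.data)


def test_decoder_shapes_and_range(tiny_model, rng):
    z = rng.normal(size=(3, 4))
    cur, fut = tiny_model.decode_predictions(z)
    h, w, _ = tiny_model.cfg.image_shape
    assert cur.shape == fut.shape == (3, 3, h, w)
    for t in (cur, fut):
        assert np.all(t.data > 0) and np.all(t.data < 1)
    cur2, _ = tiny_model.decode_predictions(z.copy())
    assert np.array_equal(cur.data, cur2.data)


def test_default_decoder_reconstructs_16x64():
    model = AgentModel(NetworkConfig.default(), seed=0)
    cur, fut = model.decode_predictions(np.zeros((1, 4)))
    assert cur.shape == (1, 3, 16, 64) and fut.shape == (1, 3, 16, 64)


def test_policy_actions_bounded_and_deterministic(tiny_model, rng):
    z = rng.normal(size=(1, 4))
    mu, sigma = tiny_model.policy(z)
    assert np.all(sigma.data > 0)
    draws = np.tanh(mu.data + rng.standard_normal((10_000, 2)) * sigma.data)
    assert np.all(np.abs(draws) < 1.0)
    assert np.allclose(tiny_model.sample_action(z, np.zeros(2)), np.tanh(mu.data)[0])
    mu2, sigma2 = tiny_model.policy(z.copy())
    assert np.array_equal(mu.data, mu2.data) and np.array_equal(sigma.data, sigma2.data)


def test_twin_critics_differ_at_initialization(tiny_model, obs_for):
    obs = obs_for(tiny_model, 1)
    action = np.zeros((1, 2))
    q0 = tiny_model.q_value(obs, action, 0).data
    q1 = tiny_model.q_value(obs, action, 1).data
    assert np.isfinite(q0).all() and not np.allclose(q0, q1)


def test_gradient_flow_audit(obs_for):
    """Free-energy + policy losses reach every main-model group; the value
    loss touches only critic parameters."""
    model = AgentModel(NetworkConfig.tiny(), seed=0)
    obs = obs_for(model, 2, seed=1)
    groups = model.param_groups()

    def grads_of(group):
        return [p.grad for p in groups[group]]

    def zero_all():
        for ps in groups.values():
            for p in ps:
                p.grad = None

    # surrogate free energy + policy pathway
    zero_all()
    feat = model.encode_observation(obs)
    h = model.update_context(model.init_context(2), feat)
    mu_p, xi_p = model.prior_head(h)
    mu_q, xi_q = model.posterior_encoder(obs, obs[::-1])
    sig_p, sig_q = xi_p.softplus(), xi_q.softplus()
    z = mu_q + Tensor(np.random.default_rng(0).standard_normal((2, 4))) * sig_q
    cur, fut = model.decode_predictions(z)
    kl = ((sig_p / sig_q).log()
          + ((mu_q - mu_p) * (mu_q - mu_p) + sig_q * sig_q) / (2 * sig_p * sig_p) - 0.5).sum()
    mu_a, sig_a = model.policy(z)
    loss = (cur.sum() + fut.sum()) + kl + (mu_a * mu_a + sig_a).sum()
    loss.backward()
    for name in ("encoder", "gru", "prior", "posterior", "decoder", "policy"):
        assert any(g is not None and np.any(g != 0) for g in grads_of(name)), name
    assert all(g is None for g in grads_of("critics"))

    # value pathway
    zero_all()
    q = model.q_value(obs, np.zeros((2, 2)), 0) + model.q_value(obs, np.zeros((2, 2)), 1)
    (q * q).sum().backward()
    assert any(g is not None and np.any(g != 0) for g in grads_of("critics"))
    for name in ("encoder", "gru", "prior", "posterior", "decoder", "policy"):
        assert all(g is None for g in grads_of(name)), name


def test_micro_model_finite_difference_gradient():
    """End-to-end numerical gradient check on the width-4 preset."""
    model = AgentModel(NetworkConfig.micro(), seed=2)
    rng = np.random.default_rng(0)
    h, w, _ = model.cfg.image_shape
    obs = rng.uniform(size=(1, h, w, 3))
    eps = rng.standard_normal((1, 4))

    def loss_value():
        feat = model.encode_observation(obs)
        hs = model.update_context(model.init_context(1), feat)
        mu_p, xi_p = model.prior_head(hs)
        z = mu_p + Tensor(eps) * xi_p.softplus()
        cur, fut = model.decode_predictions(z)
        mu_a, sig_a = model.policy(z)
        return cur.sum() + fut.sum() * 0.5 + (mu_a * mu_a).sum() + sig_a.sum()

    loss = loss_value()
    for p in model.main_parameters():
        p.grad = None
    loss.backward()
    checked = 0
    fd_eps = 1e-6
    rng2 = np.random.default_rng(1)
    for p in model.main_parameters():
        if p.grad is None:
            continue
        flat = p.data.reshape(-1)
        idx = rng2.integers(0, flat.size)
        orig = flat[idx]
        flat[idx] = orig + fd_eps
        lp = float(loss_value().data)
        flat[idx] = orig - fd_eps
        lm = float(loss_value().data)
        flat[idx] = orig
        num = (lp - lm) / (2 * fd_eps)
        ana = p.grad.reshape(-1)[idx]
        assert num == pytest.approx(ana, rel=1e-3, abs=1e-7)
        checked += 1
    assert checked > 10


def test_checkpoint_roundtrip(tmp_path, obs_for):
    model = AgentModel(NetworkConfig.tiny(), seed=3)
    obs = obs_for(model, 1)
    before = model.encode_observation(obs).data.copy()
    path = tmp_path / "ckpt.npz"
    model.save(path)
    other = AgentModel(NetworkConfig.tiny(), seed=99)
    assert not np.allclose(other.encode_observation(obs).data, before)
    other.load(path)
    assert np.array_equal(other.encode_observation(obs).data, before)


def test_tanh_gaussian_log_prob_matches_numeric():
    # change-of-variables: density of a=tanh(u), u~N(0.3, 0.5^2) at a point
    mu, sigma, u = 0.3, 0.5, 0.1
    lp = tanh_gaussian_log_prob(Tensor([[u]]), Tensor([[mu]]), Tensor([[sigma]]))
    base = -0.5 * ((u - mu) / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    expected = base - np.log(1 - np.tanh(u) ** 2 + 1e-6)
    assert lp.data[0, 0] == pytest.approx(expected, rel=1e-9)
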