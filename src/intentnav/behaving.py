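"""Per-step action selection and the agent-environment loop.

Each step: encode the observation into the recurrent context, read the
habitual prior intention from it, optionally infer the goal-directed
posterior by CEM active inference, fuse the two by inverse-variance synergy
(or pass a single intention through, per mode), sample z, and squash the
policy draw with temporally correlated pink exploration noise.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import numpy as np

from . import _autodiff as ad
from .active_inference import AIfConfig, GoalSpec, cem_optimize
from .intention import IntentionParams, habitual_ratio, sample, synergize
from .networks import AgentModel


class BehaveMode(enum.Enum):
    SYNERGIZED = "synergized"
    HABITUAL_ONLY = "habitual_only"
    GOAL_DIRECTED_ONLY = "goal_directed_only"


@dataclass
class StepDiagnostics:
    prior: IntentionParams
    posterior: IntentionParams | None
    used: IntentionParams
    habitual_ratio: float | None
    generations_used: int
    action: np.ndarray
    collision: bool = False


def pink_noise(rng: np.random.Generator, dims: int, horizon: int) -> np.ndarray:
    """(horizon, dims) noise with power spectral density ~ 1/f per dimension.

    Built by shaping a white spectrum with 1/sqrt(f) and normalizing each
    dimension to zero mean, unit variance over the episode.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if horizon == 1:
        return rng.standard_normal((1, dims))
    white = rng.standard_normal((horizon, dims))
    spec = np.fft.rfft(white, axis=0)
    freqs = np.fft.rfftfreq(horizon)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    shaped = np.fft.irfft(spec * scale[:, None], n=horizon, axis=0)
    shaped -= shaped.mean(axis=0, keepdims=True)
    std = shaped.std(axis=0, keepdims=True)
    std[std == 0] = 1.0
    return shaped / std


def act(model: AgentModel, context, obs, eps, mode: BehaveMode,
        goal: GoalSpec | None = None, aif_config: AIfConfig | None = None,
        rng: np.random.Generator | None = None):
    """One action-selection step.

    Returns (action, new context, StepDiagnostics).  ``eps`` is this step's
    exploration-noise draw (one row of a pink-noise sequence).
    """
    rng = rng or np.random.default_rng(0)
    aif_config = aif_config or AIfConfig()
    with ad.no_grad():
        feat = model.encode_observation(obs)
        new_context = model.update_context(context, feat)
        prior = model.prior_params(new_context)

    posterior, generations = None, 0
    effective_mode = mode
    if mode in (BehaveMode.SYNERGIZED, BehaveMode.GOAL_DIRECTED_ONLY):
        if goal is None:
            warnings.warn("goal-directed mode without a goal; falling back to habitual")
            effective_mode = BehaveMode.HABITUAL_ONLY
        else:
            posterior, generations = cem_optimize(prior, obs, goal, model,
                                                  aif_config, rng)

    if effective_mode == BehaveMode.HABITUAL_ONLY:
        used = prior
    elif effective_mode == BehaveMode.GOAL_DIRECTED_ONLY:
        used = posterior
    else:
        used = synergize(prior, posterior)

    z = sample(used, rng.standard_normal(used.dim))
    action = model.sample_action(z, np.asarray(eps))
    ratio = (habitual_ratio(prior.sigma, posterior.sigma)
             if posterior is not None else None)
    diag = StepDiagnostics(prior=prior, posterior=posterior, used=used,
                           habitual_ratio=ratio, generations_used=generations,
                           action=action)
    return action, new_context, diag


def run_episode(env, model: AgentModel, mode: BehaveMode,
                goal: GoalSpec | None = None,
                aif_config: AIfConfig | None = None,
                rng: np.random.Generator | None = None,
                on_step=None):
    """Reset-act-step loop until the episode ends.

    The recurrent context persists within the episode and starts from zeros.
    ``on_step(obs, result, diag)`` is called after every environment step
    (the training driver uses it to store experience and trigger updates).
    Returns (trajectory positions, episode reward, steps, diagnostics list).
    """
    rng = rng or np.random.default_rng(0)
    obs = env.reset()
    context = model.init_context(1)
    noise = pink_noise(rng, model.cfg.action_dim, env.config.max_steps)
    trajectory = [env.position]
    diags = []
    total_reward, steps = 0.0, 0
    done = False
    while not done:
        action, context, diag = act(model, context, obs, noise[steps], mode,
                                    goal=goal, aif_config=aif_config, rng=rng)
        result = env.step(action)
        diag.collision = result.info["collision"]
        diags.append(diag)
        if on_step is not None:
            on_step(obs, result, diag)
        trajectory.append(result.info["position"])
        total_reward += result.reward
        obs = result.obs
        steps += 1
        done = result.done
    return trajectory, total_reward, steps, diags
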