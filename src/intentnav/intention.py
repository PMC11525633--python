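"""Diagonal-Gaussian latent-intention math.

The agent's behavioral intention is a low-dimensional (default 4-d) latent
variable with a diagonal Gaussian distribution.  The *prior* role is the
habitual intention computed model-free from context; the *posterior* role is
the goal-directed intention inferred against a goal; the *synergized* role is
their precision-weighted fusion, equivalently the normalized product of the
two Gaussian densities.  Everything here is pure NumPy with no model state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: floor applied to STDs before inverting, to keep precisions finite
SIGMA_FLOOR = 1e-6


def softplus(x):
    return np.logaddexp(0.0, x)


def softplus_inv(y):
    """Inverse of ln(1+e^x); requires y > 0."""
    y = np.asarray(y, dtype=np.float64)
    # stable: x = y + log(1 - e^(-y))
    return y + np.log(-np.expm1(-y))


@dataclass
class IntentionParams:
    """Mean/STD of a diagonal Gaussian over the latent intention.

    ``role`` tags which pathway produced it: "prior" (habitual),
    "posterior" (goal-directed) or "synergized".
    """

    mu: np.ndarray
    sigma: np.ndarray
    role: str = "prior"
    xi: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=np.float64)
        self.sigma = np.asarray(self.sigma, dtype=np.float64)
        if self.mu.shape != self.sigma.shape:
            raise ValueError("mu and sigma must have the same shape")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if self.xi is not None:
            self.xi = np.asarray(self.xi, dtype=np.float64)

    @classmethod
    def from_xi(cls, mu, xi, role="prior"):
        xi = np.asarray(xi, dtype=np.float64)
        return cls(mu=mu, sigma=softplus(xi), role=role, xi=xi)

    @property
    def dim(self) -> int:
        return self.mu.shape[-1]


def _check_sigma(*sigmas):
    for s in sigmas:
        if np.any(np.asarray(s) <= 0):
            raise ValueError("sigma must be strictly positive")


def kl_diag_gauss(q: IntentionParams, p: IntentionParams):
    """Analytic KL[q || p] for diagonal Gaussians.

    Per dimension: ln(sigma_p/sigma_q) + ((mu_q-mu_p)^2 + sigma_q^2) /
    (2 sigma_p^2) - 1/2.  Returns (per-dimension vector, scalar sum).
    """
    _check_sigma(q.sigma, p.sigma)
    sp = np.maximum(p.sigma, SIGMA_FLOOR)
    sq = np.maximum(q.sigma, SIGMA_FLOOR)
    per_dim = np.log(sp / sq) + ((q.mu - p.mu) ** 2 + sq**2) / (2.0 * sp**2) - 0.5
    return per_dim, float(per_dim.sum())


def synergize(p: IntentionParams, q: IntentionParams) -> IntentionParams:
    """Inverse-variance-weighted fusion of prior and posterior intentions.

    mu_s = (w_p mu_p + w_q mu_q)/(w_p + w_q) with w = sigma^-2, and
    sigma_s = (sigma_p^-2 + sigma_q^-2)^(-1/2); this equals the mean/STD of
    the normalized product of the two Gaussian densities, so the synergized
    precision is the sum of the two precisions (exceeding each of them).
    """
    _check_sigma(p.sigma, q.sigma)
    wp = np.maximum(p.sigma, SIGMA_FLOOR) ** -2.0
    wq = np.maximum(q.sigma, SIGMA_FLOOR) ** -2.0
    mu_s = (wp * p.mu + wq * q.mu) / (wp + wq)
    sigma_s = (wp + wq) ** -0.5
    return IntentionParams(mu=mu_s, sigma=sigma_s, role="synergized")


def habitual_ratio(sigma_p: np.ndarray, sigma_q: np.ndarray) -> float:
    """Weight of the habitual (prior) intention in the synergy.

    mean(sigma_p)^-2 / (mean(sigma_p)^-2 + mean(sigma_q)^-2) where the mean
    runs over the intention dimensions of the STD vector; close to 1 when the
    prior is much more precise than the posterior.
    """
    _check_sigma(sigma_p, sigma_q)
    wp = max(float(np.mean(sigma_p)), SIGMA_FLOOR) ** -2.0
    wq = max(float(np.mean(sigma_q)), SIGMA_FLOOR) ** -2.0
    return wp / (wp + wq)


def sample(params: IntentionParams, noise: np.ndarray) -> np.ndarray:
    """Reparameterized draw z = mu + noise * sigma."""
    _check_sigma(params.sigma)
    return params.mu + np.asarray(noise, dtype=np.float64) * params.sigma
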