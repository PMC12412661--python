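"""Mean-field variational Gaussian weights and their KL penalty.

Each uncertain weight carries a posterior N(mean, sd^2) with sd = exp(log_sd)
and a fixed Gaussian prior.  Sampling uses the reparameterization
mean + sd * eps with eps ~ N(0, 1), so draws stay differentiable with
respect to both variational parameters.
"""

from __future__ import annotations

import numpy as np

from .. import autodiff as ad

__all__ = ["VariationalGaussian", "sample_weights", "kl_gaussian"]


class VariationalGaussian:
    """Variational posterior over an array of weights.

    Parameters
    ----------
    mean : array
        Posterior mean initialization (e.g. a precomputed LoG kernel).
    sd : float or array
        Initial posterior SD.
    prior_mean, prior_sd : float
        Gaussian prior; the prior SD is set per layer (0.5 ... 2.5 on the
        default five-level ladder).
    """

    def __init__(self, mean, sd=0.05, prior_mean=0.0, prior_sd=1.0,
                 dtype=np.float32):
        mean = np.asarray(mean, dtype=dtype)
        sd_arr = np.broadcast_to(np.asarray(sd, dtype=dtype), mean.shape)
        if np.any(sd_arr < 0):
            raise ValueError("initial sd must be nonnegative")
        self.mean = ad.Tensor(mean.copy(), requires_grad=True)
        with np.errstate(divide="ignore"):
            self.log_sd = ad.Tensor(np.log(sd_arr.copy()), requires_grad=True)
        self.prior_mean = float(prior_mean)
        self.prior_sd = float(prior_sd)

    @property
    def shape(self):
        return self.mean.shape

    def sd(self) -> ad.Tensor:
        return self.log_sd.exp()

    def parameters(self):
        return [self.mean, self.log_sd]

    def sample(self, rng: np.random.Generator) -> ad.Tensor:
        return sample_weights(self, rng)

    def kl(self) -> ad.Tensor:
        """KL(q || p) summed over weights, as a graph node."""
        sd = self.sd()
        var = sd * sd
        p_var = self.prior_sd ** 2
        dm = self.mean - self.prior_mean
        terms = (np.log(self.prior_sd) - self.log_sd
                 + (var + dm * dm) / (2.0 * p_var) - 0.5)
        return terms.sum()


def sample_weights(vg: VariationalGaussian, rng) -> ad.Tensor:
    """Reparameterized draw: mean + sd * eps, differentiable in both params."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    eps = rng.standard_normal(vg.shape).astype(vg.mean.dtype)
    return vg.mean + vg.log_sd.exp() * eps


def kl_gaussian(q_mean, q_sd, p_mean, p_sd) -> float:
    """Closed-form KL divergence between diagonal Gaussians, summed.

    KL(N(m_q, s_q^2) || N(m_p, s_p^2))
      = log(s_p/s_q) + (s_q^2 + (m_q - m_p)^2) / (2 s_p^2) - 1/2
    """
    q_mean, q_sd = np.asarray(q_mean, dtype=float), np.asarray(q_sd, dtype=float)
    p_mean, p_sd = np.asarray(p_mean, dtype=float), np.asarray(p_sd, dtype=float)
    if np.any(q_sd <= 0) or np.any(p_sd <= 0):
        raise ValueError("standard deviations must be positive")
    terms = (np.log(p_sd / q_sd)
             + (q_sd ** 2 + (q_mean - p_mean) ** 2) / (2 * p_sd ** 2) - 0.5)
    return float(np.sum(terms))
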