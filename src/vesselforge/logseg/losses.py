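"""Training objectives: Dice overlap, Bernoulli ELBO, and their combination.

The segmenter maximizes the evidence lower bound of a voxelwise Bernoulli
likelihood under the variational weight posterior while minimizing the Dice
loss, i.e. it minimizes  L_Dice - ELBO.
"""

from __future__ import annotations

import numpy as np

from .. import autodiff as ad
from ..volume import ScalarVolume

__all__ = ["dice_coefficient", "dice_loss", "bernoulli_loglik", "elbo",
           "combined_objective"]


def _values(x):
    return x.values if isinstance(x, ScalarVolume) else np.asarray(x)


def dice_coefficient(pred, truth) -> float:
    """Soft Dice overlap  2*sum(g*o) / (sum(g^2) + sum(o^2)).

    Accepts volumes or arrays on the same grid.  Two empty masks are in
    perfect agreement, so empty-vs-empty is defined as 1.
    """
    g = _values(truth).astype(float)
    o = _values(pred).astype(float)
    if g.shape != o.shape:
        raise ValueError("prediction and truth must share a grid")
    denom = np.sum(g * g) + np.sum(o * o)
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(g * o) / denom)


def dice_loss(pred, truth) -> float:
    return 1.0 - dice_coefficient(pred, truth)


def _dice_tensor(probs: ad.Tensor, labels: np.ndarray, eps=1e-8) -> ad.Tensor:
    g = np.asarray(labels).astype(probs.dtype).reshape(probs.shape)
    num = (probs * g).sum() * 2.0
    den = (probs * probs).sum() + float(np.sum(g * g)) + eps
    return num / den


def bernoulli_loglik(logits: ad.Tensor, labels: np.ndarray) -> ad.Tensor:
    """Mean voxelwise Bernoulli log-likelihood, stable in the logits."""
    g = np.asarray(labels).astype(logits.dtype).reshape(logits.shape)
    return (logits * g - logits.softplus()).mean()


def elbo(images: np.ndarray, labels: np.ndarray, model, mc_samples: int = 1,
         rng=None, kl_scale: float = 1.0, _cache: dict | None = None
         ) -> ad.Tensor:
    """Monte-Carlo ELBO: E_q[log p(D|theta)] - kl_scale * KL(q || p).

    ``kl_scale`` rescales the KL term so the prior's pull is comparable to
    one mini-batch of data (commonly 1 / patches-per-epoch).
    """
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    x = np.asarray(images, dtype=float)
    if x.ndim == 4:
        x = x[:, None]
    ll_terms = []
    for s in range(mc_samples):
        logits, _ = model.forward(x, sample=True, rng=rng)
        ll_terms.append(bernoulli_loglik(logits, labels))
        if _cache is not None and s == 0:
            _cache["logits"] = logits
    ll = ll_terms[0]
    for t in ll_terms[1:]:
        ll = ll + t
    ll = ll / float(mc_samples)
    kl = model.kl_total()
    if _cache is not None:
        _cache["loglik"] = ll
        _cache["kl"] = kl
    return ll - kl_scale * kl


def combined_objective(images: np.ndarray, labels: np.ndarray, model,
                       mc_samples: int = 1, rng=None, kl_scale: float = 1.0):
    """Minimization target  L_Dice - ELBO;  returns (loss, components).

    The Dice term reuses the first ELBO weight sample so one forward pass
    serves both terms.
    """
    cache: dict = {}
    e = elbo(images, labels, model, mc_samples=mc_samples, rng=rng,
             kl_scale=kl_scale, _cache=cache)
    probs = cache["logits"].sigmoid()
    labs = np.asarray(labels, dtype=float)
    if labs.ndim == 4:
        labs = labs[:, None]
    dice = _dice_tensor(probs, labs)
    loss = (1.0 - dice) - e
    components = {
        "objective": float(loss.data),
        "dice": float(dice.data),
        "loglik": float(cache["loglik"].data),
        "kl": float(cache["kl"].data),
        "elbo": float(e.data),
    }
    return loss, components
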