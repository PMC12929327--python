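"""Task losses and their fixed-weight combination.

The primary milestone loss is multi-label binary cross-entropy on logits;
the auxiliary segmentation loss is multi-class focal loss; the total is the
convex combination 0.9 * L_pri + 0.1 * L_aux that the joint objective and
the inner meta-step minimise.  All reductions are means (over criteria,
pixels and batch) so the loss scale does not depend on batch composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .exceptions import ConfigError


@dataclass(frozen=True)
class LossWeights:
    w_pri: float = 0.9
    w_aux: float = 0.1
    focal_gamma: float = 2.0

    def __post_init__(self):
        if self.w_pri < 0 or self.w_aux < 0:
            raise ConfigError("loss weights must be non-negative")
        if self.focal_gamma < 0:
            raise ConfigError("focal gamma must be non-negative")


def primary_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Binary cross-entropy with logits, averaged over criteria and batch.

    Uses the stable form max(x,0) - x*y + log(1 + exp(-|x|)); labels must be
    exactly 0 or 1.
    """
    labels = np.asarray(labels, dtype=np.float64)
    if labels.shape != tuple(logits.shape):
        raise ConfigError(f"labels {labels.shape} vs logits {tuple(logits.shape)}")
    if not np.isin(labels, (0.0, 1.0)).all():
        raise ConfigError("criterion labels must be binary")
    x = logits
    # softplus(-x) + x*(1-y)  ==  max(x,0) - x*y + log1p(exp(-|x|))
    return ad.tmean(ad.softplus(ad.neg(x)) + x * ad.astensor(1.0 - labels))


def auxiliary_loss(seg_logits: Tensor, masks: np.ndarray,
                   weights: LossWeights = LossWeights()) -> Tensor:
    """Multi-class focal loss, mean over pixels and batch.

    Per pixel with true-class probability p_t the contribution is
    -(1 - p_t)^gamma * log(p_t); gamma = 0 recovers cross-entropy.
    """
    masks = np.asarray(masks)
    b, h, w, k = seg_logits.shape
    if masks.shape != (b, h, w):
        raise ConfigError(f"masks {masks.shape} vs logits {tuple(seg_logits.shape)}")
    if masks.min() < 0 or masks.max() >= k:
        raise ConfigError(f"mask labels outside 0..{k - 1}")
    logp = ad.log_softmax(seg_logits, axis=-1)
    onehot = np.zeros((b, h, w, k))
    np.put_along_axis(onehot, masks[..., None], 1.0, axis=-1)
    logp_t = ad.tsum(logp * ad.astensor(onehot), axis=-1)    # (B,H,W)
    if weights.focal_gamma == 0.0:
        return ad.tmean(ad.neg(logp_t))
    p_t = ad.exp(logp_t)
    mod = ad.power(1.0 - p_t + 1e-12, weights.focal_gamma)
    return ad.tmean(ad.neg(mod * logp_t))


def total_loss(l_pri: Tensor, l_aux: Tensor,
               weights: LossWeights = LossWeights()) -> Tensor:
    """w_pri * L_pri + w_aux * L_aux."""
    return ad.astensor(weights.w_pri) * l_pri + ad.astensor(weights.w_aux) * l_aux
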