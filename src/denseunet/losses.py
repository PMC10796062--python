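"""Segmentation losses: binary cross-entropy, the Tversky family, and the
hybrid BCE + overlap losses used for training.

The Tversky index TI = |A.B| / (|A.B| + a|A-B| + b|B-A|) is computed with
soft set sizes (|A.B| = sum p*t, |A-B| = sum p*(1-t), |B-A| = sum (1-p)*t),
so it is differentiable in the predicted probabilities and reduces exactly
to the count form on binary inputs.  Dice is the a = b = 0.5 special case
and Jaccard the a = b = 1 case; ``dice_loss`` and ``jaccard_loss`` are
implemented through that reduction so the identities hold structurally.
The index is maximal (1) at perfect overlap, so the quantity minimized in
training is ``1 - TI``; the raw index is exposed separately.

With b > a, false negatives are penalized more than false positives, which
counteracts the foreground/background imbalance of tumor slices.  The
defaults a = 0.3, b = 0.7 follow that regime.

All functions accept numpy arrays or autograd ``Tensor``s and return a
scalar ``Tensor`` (use ``.item()`` for a float).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor, concat, narrow
from .containers import ValidationError

_CLAMP = 1e-7

#: (alpha, beta) used by the secondary term of each hybrid mixture; None
#: means "take alpha/beta from the config" (the Tversky mixture).
MIXTURES: dict[str, tuple[float, float] | None] = {
    "bce_tversky": None,
    "bce_dice": (0.5, 0.5),
    "bce_jaccard": (1.0, 1.0),
}


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of the hybrid loss.

    alpha weights false positives and beta false negatives in the Tversky
    term; ``bce_weight`` is the per-sample weight w of the BCE term
    (generally 1); ``smooth`` stabilizes empty-region denominators.
    """

    alpha: float = 0.3
    beta: float = 0.7
    bce_weight: float = 1.0
    mixture: str = "bce_tversky"
    smooth: float = 1e-6

    def validate(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValidationError(f"alpha/beta must be >= 0, got ({self.alpha}, {self.beta})")
        if self.smooth <= 0:
            raise ValidationError(f"smooth must be > 0, got {self.smooth}")
        if self.mixture not in MIXTURES:
            raise ValidationError(
                f"unknown mixture {self.mixture!r}; choose from {sorted(MIXTURES)}"
            )


def _pair(pred, target) -> tuple[Tensor, Tensor]:
    pred = pred if isinstance(pred, Tensor) else Tensor(np.asarray(pred, dtype=np.float64))
    target = target if isinstance(target, Tensor) else Tensor(np.asarray(target, dtype=np.float64))
    if pred.shape != target.shape:
        raise ValidationError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    return pred, target


def bce_loss(pred, target, weight: float = 1.0) -> Tensor:
    """Mean binary cross-entropy -w.[t log p + (1-t) log(1-p)] over pixels.

    Predictions are clamped to (1e-7, 1 - 1e-7) so exact 0/1 probabilities
    stay finite; the loss is zero iff pred equals target pre-clamp.
    """
    pred, target = _pair(pred, target)
    p = pred.clip(_CLAMP, 1.0 - _CLAMP)
    ll = target * p.log() + (1.0 - target) * (1.0 - p).log()
    return -weight * ll.mean()


def tversky_index(pred, target, alpha: float = 0.3, beta: float = 0.7,
                  smooth: float = 1e-6) -> Tensor:
    """Soft Tversky index TP/(TP + alpha.FP + beta.FN), in [0, 1]."""
    pred, target = _pair(pred, target)
    tp = (pred * target).sum()
    fp = (pred * (1.0 - target)).sum()
    fn = ((1.0 - pred) * target).sum()
    return (tp + smooth) / (tp + alpha * fp + beta * fn + smooth)


def tversky_loss(pred, target, alpha: float = 0.3, beta: float = 0.7,
                 smooth: float = 1e-6) -> Tensor:
    """1 - Tversky index; 0 at perfect overlap, near 1 for disjoint masks."""
    return 1.0 - tversky_index(pred, target, alpha=alpha, beta=beta, smooth=smooth)


def dice_loss(pred, target, smooth: float = 1e-6) -> Tensor:
    """Soft Dice loss: the alpha = beta = 0.5 Tversky special case."""
    return tversky_loss(pred, target, alpha=0.5, beta=0.5, smooth=smooth)


def jaccard_loss(pred, target, smooth: float = 1e-6) -> Tensor:
    """Soft Jaccard loss: the alpha = beta = 1 Tversky special case."""
    return tversky_loss(pred, target, alpha=1.0, beta=1.0, smooth=smooth)


def class_to_region_probs(class_probs: Tensor) -> Tensor:
    """Assemble region probabilities from 4-class softmax output.

    Input is (N, 4, h, w) with class channels (healthy, label-1, label-2,
    label-4); output is (N, 3, h, w) with region channels (WT, TC, ET):
    P(WT) = p1 + p2 + p3, P(TC) = p1 + p3, P(ET) = p3.
    """
    if class_probs.shape[1] != 4:
        raise ValidationError(
            f"expected 4 class channels, got {class_probs.shape[1]}"
        )
    p1 = narrow(class_probs, 1, 1, 1)
    p2 = narrow(class_probs, 1, 2, 1)
    p3 = narrow(class_probs, 1, 3, 1)
    return concat([p1 + p2 + p3, p1 + p3, p3], axis=1)


def mixed_loss(pred_regions, target_regions, config: LossConfig | None = None) -> Tensor:
    """Hybrid loss: BCE plus an overlap term, averaged over the 3 regions.

    ``pred_regions`` and ``target_regions`` are (N, 3, h, w) (or (3, h, w))
    in WT/TC/ET channel order; ``config.mixture`` selects the overlap term
    (Tversky at the configured alpha/beta, or its Dice/Jaccard special
    cases).  Strictly positive unless the prediction is perfect.
    """
    config = config or LossConfig()
    config.validate()
    pred, target = _pair(pred_regions, target_regions)
    axis = 0 if pred.ndim == 3 else 1
    if pred.shape[axis] != 3:
        raise ValidationError(
            f"expected 3 region channels (WT, TC, ET), got {pred.shape[axis]}"
        )
    ab = MIXTURES[config.mixture]
    alpha, beta = (config.alpha, config.beta) if ab is None else ab
    total = None
    for r in range(3):
        p = narrow(pred, axis, r, 1)
        t = narrow(target, axis, r, 1)
        term = bce_loss(p, t, weight=config.bce_weight) + tversky_loss(
            p, t, alpha=alpha, beta=beta, smooth=config.smooth
        )
        total = term if total is None else total + term
    return total * (1.0 / 3.0)
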