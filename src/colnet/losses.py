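"""Loss functions: soft Dice, adversarial reconstruction loss, and the
λ-weighted mixed objective that couples the two branches.

The reconstruction objective follows the adversarial-autoencoder pattern:
the reconstructor minimises MSE(R(x), x) plus a generator cross-entropy
term that pushes the discriminator to call reconstructions real, while the
discriminator minimises real-vs-fake cross-entropy. The mixed loss is
``loss_s + λ * loss_r``; λ = 0 recovers purely supervised training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn import Tensor

__all__ = [
    "LossWeights", "LossBreakdown", "soft_dice_loss", "reconstruction_loss",
    "mix_loss", "cross_entropy_pair",
]

_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """λ weights the reconstruction branch; adv_weight the generator CE term."""

    lam: float = 0.2
    adv_weight: float = 1.0

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        if self.adv_weight < 0:
            raise ValueError("adv_weight must be nonnegative")


@dataclass
class LossBreakdown:
    loss_s: float = float("nan")
    loss_r: float = float("nan")
    loss_mse: float = float("nan")
    loss_adv_g: float = float("nan")
    loss_d: float = float("nan")
    loss_mix: float = float("nan")


def _wrap(x) -> Tensor:
    # Tensor's own dtype policy applies: float64 stays, the rest is float32
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x))


def soft_dice_loss(pred_prob, target, smooth: float = 0.0) -> Tensor:
    """1 - (2 Σ p·t + smooth) / (Σ p + Σ t + smooth).

    ``pred_prob`` holds foreground probabilities, ``target`` the binary
    mask; shapes (H, W) or (N, H, W). The Dice overlap is computed per
    sample over the spatial axes and the losses averaged across the batch.
    When both prediction and target are all-zero with smooth=0 the loss is
    0 by convention (empty matches empty perfectly).
    """
    p = _wrap(pred_prob)
    t_arr = np.asarray(target.values if hasattr(target, "values") else target)
    t = _wrap(t_arr.astype(p.data.dtype))
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if p.data.min() < -1e-6 or p.data.max() > 1 + 1e-6:
        raise ValueError("pred_prob must lie in [0, 1]")
    axes = (-2, -1) if p.ndim >= 2 else None
    denom_vals = p.data.sum(axis=axes) + \
        np.asarray(t.data).sum(axis=axes)
    if smooth == 0.0 and np.any(denom_vals == 0):
        warnings.warn("empty prediction and target with smooth=0; "
                      "Dice loss taken as 0 by convention")
        if np.all(denom_vals == 0):
            return Tensor(np.float32(0.0))
    inter = (p * t).sum(axis=axes)
    denom = p.sum(axis=axes) + t.sum(axis=axes)
    dice = (2.0 * inter + smooth) / (denom + smooth)
    loss = 1.0 - dice
    return loss.mean() if loss.ndim > 0 else loss


def cross_entropy_pair(prob_pairs, label: int,
                       validate: bool = True) -> Tensor:
    """-mean(log p[label]) over (N, 2) probability pairs.

    Column 0 is P(reconstructed), column 1 is P(real). Probabilities are
    clamped to [1e-7, 1 - 1e-7] before the log so confident mistakes give a
    large but finite loss.
    """
    p = _wrap(prob_pairs)
    if p.ndim != 2 or p.shape[1] != 2:
        raise ValueError(f"expected (N, 2) probability pairs, got {p.shape}")
    sums = p.data.sum(axis=1)
    if validate and np.any(np.abs(sums - 1.0) > 1e-4):
        raise ValueError("probability pairs must sum to 1 within 1e-4")
    picked = p * Tensor(np.eye(2, dtype=np.float32)[label][None, :])
    picked = picked.sum(axis=1)
    return -(picked.clip(_EPS, 1.0 - _EPS).log()).mean()


LABEL_FAKE = 0   # reconstructed
LABEL_REAL = 1


def reconstruction_loss(x, r_out, d_on_fake, d_on_real,
                        weights: LossWeights = LossWeights()
                        ) -> tuple[Tensor, Tensor]:
    """(generator_side, discriminator_side) of the adversarial autoencoder.

    generator_side = MSE(r_out, x) + adv_weight * CE(D(r_out), label=real):
    the reconstructor minimises reconstruction error while pushing D to
    call its outputs real. discriminator_side = CE(D(x), real) +
    CE(D(r_out), fake).
    """
    xt, rt = _wrap(x), _wrap(r_out)
    if xt.shape != rt.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {rt.shape}")
    mse = (rt - xt).square().mean()
    adv_g = cross_entropy_pair(d_on_fake, LABEL_REAL)
    generator_side = mse + weights.adv_weight * adv_g
    discriminator_side = cross_entropy_pair(d_on_real, LABEL_REAL) + \
        cross_entropy_pair(d_on_fake, LABEL_FAKE)
    return generator_side, discriminator_side


def mix_loss(loss_s, loss_r_generator, weights: LossWeights = LossWeights()):
    """loss_s + λ * loss_r; with λ = 0 this is exactly the supervised loss."""
    if weights.lam == 0.0:
        return loss_s
    return loss_s + weights.lam * loss_r_generator
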