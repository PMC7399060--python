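"""Hybrid segmentation loss: weighted cross-entropy plus Dice.

Neurites occupy a tiny fraction of any patch, so a plain cross-entropy is
dominated by background. The hybrid objective is

    loss = sigma * loss_ce + loss_dice

with the cross-entropy term weighted by the foreground fraction
alpha = sum(g) / m and the Dice term smoothing both numerator and denominator
with epsilon:

    loss_ce   = mean_i( -alpha * g_i * log p_i )          (``as_printed``)
    loss_dice = 1 - (2 * sum(p * g) + eps) / (sum(p) + sum(g) + eps)

The ``as_printed`` cross-entropy carries no background term, so on its own it
cannot penalise false positives; a ``balanced`` variant
(-(1-alpha) g log p - alpha (1-g) log(1-p)) is available. Probabilities are
clamped to [1e-7, 1 - 1e-7] before any logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossConfig", "dice_loss", "cross_entropy_loss", "hybrid_loss",
           "hybrid_loss_grad", "logits_grad"]

_CLIP = 1e-7


@dataclass
class LossConfig:
    sigma: float = 0.5
    epsilon: float = 1.0
    ce_variant: str = "as_printed"  # or "balanced"

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.epsilon <= 0:
            raise ValueError("sigma and epsilon must be positive")
        if self.ce_variant not in ("as_printed", "balanced"):
            raise ValueError(f"unknown ce_variant: {self.ce_variant}")


def _as_arrays(pred, label) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(getattr(pred, "values", pred), dtype=np.float64)
    g = np.asarray(getattr(label, "values", label), dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs label {g.shape}")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("predictions must be probabilities in [0, 1]")
    return p, g


def dice_loss(pred, label, epsilon: float = 1.0) -> float:
    p, g = _as_arrays(pred, label)
    num = 2.0 * float((p * g).sum()) + epsilon
    den = float(p.sum()) + float(g.sum()) + epsilon
    return 1.0 - num / den


def cross_entropy_loss(pred, label, variant: str = "as_printed") -> float:
    p, g = _as_arrays(pred, label)
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    alpha = float(g.mean())
    if variant == "as_printed":
        return float(np.mean(-alpha * g * np.log(p)))
    return float(np.mean(-(1.0 - alpha) * g * np.log(p)
                         - alpha * (1.0 - g) * np.log(1.0 - p)))


def hybrid_loss(pred, label, config: LossConfig | None = None) -> float:
    """sigma-weighted cross-entropy plus Dice on the foreground channel."""
    config = config or LossConfig()
    return (config.sigma * cross_entropy_loss(pred, label, config.ce_variant)
            + dice_loss(pred, label, config.epsilon))


def hybrid_loss_grad(pred, label, config: LossConfig | None = None) -> np.ndarray:
    """d(hybrid_loss)/dp, elementwise, same shape as the prediction."""
    config = config or LossConfig()
    p, g = _as_arrays(pred, label)
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    m = p.size
    alpha = g.mean()
    if config.ce_variant == "as_printed":
        dce = -alpha * g / p / m
    else:
        dce = (-(1.0 - alpha) * g / p + alpha * (1.0 - g) / (1.0 - p)) / m
    num = 2.0 * (p * g).sum() + config.epsilon
    den = p.sum() + g.sum() + config.epsilon
    ddice = (num - 2.0 * g * den) / den ** 2
    return config.sigma * dce + ddice


def logits_grad(proba: np.ndarray, label: np.ndarray,
                config: LossConfig | None = None) -> np.ndarray:
    """Gradient of the hybrid loss w.r.t. the 2-channel logits.

    ``proba`` is the softmax output (N, 2, ...); the loss sees only the
    foreground channel p = proba[:, 1], and for a 2-class softmax
    dp/dz_fg = p (1 - p) = -dp/dz_bg.
    """
    p_fg = proba[:, 1]
    dldp = hybrid_loss_grad(p_fg, label, config)
    dz_fg = dldp * p_fg * (1.0 - p_fg)
    out = np.empty_like(proba)
    out[:, 1] = dz_fg
    out[:, 0] = -dz_fg
    return out.astype(np.float32)
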