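"""SGD training loop and sliding-window full-volume prediction."""

from __future__ import annotations

import numpy as np

from ..stackio import ImageStack, ProbabilityMap
from .loss import LossConfig, hybrid_loss, logits_grad
from .model import VoxResNet, softmax_channels
from .sampling import TrainConfig, normalize_patch

__all__ = ["TrainingDivergence", "train", "predict"]


class TrainingDivergence(RuntimeError):
    """Raised when the training loss becomes non-finite."""


class _SGD:
    """SGD with classical momentum and decoupled-in-name-only weight decay."""

    def __init__(self, params, grads, momentum: float, weight_decay: float):
        self.params, self.grads = params, grads
        self.momentum, self.weight_decay = momentum, weight_decay
        self.velocity = [np.zeros_like(p) for p in params]

    def step(self, lr: float) -> None:
        for p, g, v in zip(self.params, self.grads, self.velocity):
            v *= self.momentum
            v -= lr * (g + self.weight_decay * p)
            p += v


def train(model: VoxResNet, patches, config: TrainConfig,
          loss_config: LossConfig | None = None,
          rng: np.random.Generator | None = None) -> tuple[VoxResNet, list[float]]:
    """Train in place on a fixed pool of (patch, label) pairs.

    The learning rate follows ``lr * 0.5 ** (epoch // lr_halving_epochs)``.
    Returns the model and the per-epoch mean loss history; a non-finite loss
    aborts with :class:`TrainingDivergence`.
    """
    patches = list(patches)
    if not patches:
        raise ValueError("empty patch pool")
    loss_config = loss_config or LossConfig()
    rng = rng or np.random.default_rng(config.seed)
    opt = _SGD(model.params, model.grads, config.momentum, config.weight_decay)
    history: list[float] = []
    for epoch in range(config.max_epochs):
        lr = config.lr * 0.5 ** (epoch // config.lr_halving_epochs)
        order = rng.permutation(len(patches))
        losses = []
        for start in range(0, len(order), config.batch_size):
            idx = order[start : start + config.batch_size]
            x = np.stack([patches[i][0] for i in idx])[:, None].astype(np.float32)
            g = np.stack([patches[i][1] for i in idx]).astype(np.float32)
            logits = model.forward(x, train=True)
            proba = softmax_channels(logits)
            loss = hybrid_loss(proba[:, 1], g, loss_config)
            if not np.isfinite(loss):
                raise TrainingDivergence(
                    f"non-finite loss {loss} at epoch {epoch}; reduce the learning rate")
            model.zero_grad()
            model.backward(logits_grad(proba, g, loss_config))
            opt.step(lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return model, history


def lr_schedule(initial_lr: float, halving_epochs: int, epoch: int) -> float:
    """Epoch-indexed learning rate: halved every ``halving_epochs`` epochs."""
    return initial_lr * 0.5 ** (epoch // halving_epochs)


def predict(model: VoxResNet, image: ImageStack,
            patch_size: int | None = None) -> ProbabilityMap:
    """Full-volume foreground posterior by 50%-overlap sliding-window tiling.

    Tiles are standardized exactly as training patches were; overlapping
    predictions are averaged with uniform weights. Inference uses batch-norm
    running statistics, so repeated calls are identical.
    """
    ps = patch_size or model.config.input_patch
    shape = image.shape
    if any(s < ps for s in shape):
        raise ValueError(f"volume {shape} smaller than the {ps}^3 inference patch")
    stride = max(ps // 2, 1)
    starts = []
    for s in shape:
        pos = list(range(0, s - ps + 1, stride))
        if pos[-1] != s - ps:
            pos.append(s - ps)
        starts.append(pos)
    acc = np.zeros(shape, dtype=np.float64)
    weight = np.zeros(shape, dtype=np.float64)
    vox = image.voxels.astype(np.float32)
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                sl = (slice(z0, z0 + ps), slice(y0, y0 + ps), slice(x0, x0 + ps))
                tile = normalize_patch(vox[sl])[None, None]
                proba = model.predict_proba(tile, train=False)[0, 1]
                acc[sl] += proba
                weight[sl] += 1.0
    values = np.clip(acc / weight, 0.0, 1.0).astype(np.float32)
    return ProbabilityMap(values=values)
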