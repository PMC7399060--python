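"""Training patch sampling, filtering and augmentation.

Random cubic patches are drawn from the (image, pseudo-label) pair; patches
whose foreground voxel count is below ``alpha1 * V`` (V the patch volume) are
rejected as blank. Survivors are augmented (in-plane 90-degree rotations,
axis flips, contrast/brightness jitter, light Gaussian blur) and standardized
to zero mean, unit variance. All randomness flows from the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from ..stackio import ImageStack, LabelMask

__all__ = ["TrainConfig", "PatchSamplingError", "sample_patches", "normalize_patch"]


class PatchSamplingError(RuntimeError):
    """No patch satisfied the foreground filter within the draw budget."""


@dataclass
class TrainConfig:
    """Optimization and sampling hyperparameters.

    The optimizer is plain SGD with momentum: initial learning rate 0.01
    halved every 4 epochs, momentum 0.9, weight decay 5e-4, batch size 3.
    ``alpha1`` is the blank-patch rejection ratio. ``patches_per_epoch``
    controls the size of each epoch's sample; the desk profile keeps it small.
    """

    patch_size: int = 64
    alpha1: float = 0.001
    lr: float = 0.01
    lr_halving_epochs: int = 4
    batch_size: int = 3
    momentum: float = 0.9
    weight_decay: float = 0.0005
    max_epochs: int = 100
    augmentations: tuple[str, ...] = (
        "rotation", "flip", "contrast", "brightness", "gaussian_blur")
    seed: int = 0
    patches_per_epoch: int = 12
    max_draws_per_patch: int = 200

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha1 < 1.0):
            raise ValueError("alpha1 must be in (0, 1)")
        for name, v in (("lr", self.lr), ("momentum", self.momentum + 1e-12),
                        ("weight_decay", self.weight_decay + 1e-12),
                        ("batch_size", self.batch_size)):
            if v <= 0:
                raise ValueError(f"{name} must be positive")


def normalize_patch(patch: np.ndarray) -> np.ndarray:
    patch = patch.astype(np.float32)
    return (patch - patch.mean()) / (patch.std() + 1e-8)


def _augment(patch: np.ndarray, label: np.ndarray, augmentations,
             rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    if "rotation" in augmentations:
        k = int(rng.integers(0, 4))
        patch = np.rot90(patch, k, axes=(1, 2))
        label = np.rot90(label, k, axes=(1, 2))
    if "flip" in augmentations:
        for ax in range(3):
            if rng.random() < 0.5:
                patch = np.flip(patch, axis=ax)
                label = np.flip(label, axis=ax)
    if "contrast" in augmentations:
        patch = patch * rng.uniform(0.8, 1.25)
    if "brightness" in augmentations:
        patch = patch + rng.uniform(-0.1, 0.1) * (patch.std() + 1e-8)
    if "gaussian_blur" in augmentations and rng.random() < 0.3:
        patch = gaussian_filter(patch, sigma=float(rng.uniform(0.3, 0.8)))
    return np.ascontiguousarray(patch), np.ascontiguousarray(label)


def sample_patches(image: ImageStack, labels: LabelMask, config: TrainConfig,
                   n_patches: int | None = None,
                   rng: np.random.Generator | None = None,
                   augment: bool = True) -> list[tuple[np.ndarray, np.ndarray]]:
    """Draw accepted, augmented, standardized (patch, label-patch) pairs.

    Raises :class:`PatchSamplingError` if the foreground filter rejects every
    draw within the budget (e.g. an all-background label volume).
    """
    if image.shape != labels.shape:
        raise ValueError("image/label shape mismatch")
    ps = config.patch_size
    if any(s < ps for s in image.shape):
        raise ValueError(f"volume {image.shape} smaller than patch size {ps}")
    n_patches = config.patches_per_epoch if n_patches is None else n_patches
    rng = rng or np.random.default_rng(config.seed)
    vox = image.voxels.astype(np.float32)
    lab = labels.values
    min_fg = config.alpha1 * ps ** 3  # strict <: reject when count < alpha1*V
    out: list[tuple[np.ndarray, np.ndarray]] = []
    draws = 0
    budget = config.max_draws_per_patch * n_patches
    while len(out) < n_patches:
        if draws >= budget:
            raise PatchSamplingError(
                f"no patch met the alpha1 filter in {draws} draws")
        draws += 1
        origin = [int(rng.integers(0, s - ps + 1)) for s in image.shape]
        sl = tuple(slice(o, o + ps) for o in origin)
        lp = lab[sl]
        if float(lp.sum()) < min_fg:
            continue
        ip = vox[sl]
        if augment and config.augmentations:
            ip, lp = _augment(ip, lp, config.augmentations, rng)
        out.append((normalize_patch(ip), lp.astype(np.float32)))
    return out
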