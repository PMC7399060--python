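"""Voxelwise residual segmentation network (VoxResNet-style), in numpy.

The architecture follows the deeply supervised residual design used for
volumetric segmentation: two full-resolution convolutions, three stride-2
downsampling convolutions interleaved with six stacked residual modules
(two 3×3×3 convolutions plus an identity shortcut each), and four auxiliary
classification branches — one per resolution — each a transposed convolution
back to full resolution followed by a 1×1×1 classifier convolution. The four
auxiliary outputs are summed and softmax-normalized per voxel into a 2-channel
(background/foreground) posterior.

Layer census at the reference width (base 32, doubling to 64): 2 + 3 + 6·2 + 4
= 21 convolutional layers and 4 deconvolutional layers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import BatchNorm3d, Conv3d, ConvTranspose3d, ReLU, Sequential

__all__ = ["NetworkConfig", "VoxResNet", "build_network", "layer_census"]


@dataclass
class NetworkConfig:
    """Architecture knobs.

    ``base_channels`` is the width of the two full-resolution layers; deeper
    stages use twice that. The reference profile (32) matches GPU-scale use;
    the desk profile (8) keeps CPU training tractable. ``input_patch`` must be
    divisible by ``2**(n_aux_branches - 1)``.
    """

    base_channels: int = 32
    n_res_modules: int = 6
    kernel: int = 3
    n_aux_branches: int = 4
    input_patch: int = 64

    def __post_init__(self) -> None:
        n_down = self.n_aux_branches - 1
        if n_down < 1:
            raise ValueError("need at least two auxiliary branches")
        if self.n_res_modules % n_down:
            raise ValueError("n_res_modules must divide evenly over the down stages")
        if self.input_patch % (2 ** n_down):
            raise ValueError(f"input_patch must be divisible by {2 ** n_down}")

    @classmethod
    def desk(cls, input_patch: int = 32) -> "NetworkConfig":
        return cls(base_channels=8, input_patch=input_patch)


class ResidualModule(Sequential):
    """BN → ReLU → Conv → BN → ReLU → Conv with an identity shortcut."""

    def __init__(self, channels: int, kernel: int, rng: np.random.Generator):
        super().__init__(
            BatchNorm3d(channels), ReLU(), Conv3d(channels, channels, kernel, rng=rng),
            BatchNorm3d(channels), ReLU(), Conv3d(channels, channels, kernel, rng=rng),
        )

    def forward(self, x, train=True):
        return x + super().forward(x, train=train)

    def backward(self, dy):
        return dy + super().backward(dy)


class VoxResNet:
    """Deeply supervised multi-resolution voxel classifier."""

    def __init__(self, config: NetworkConfig, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.config = config
        c1 = config.base_channels
        c2 = 2 * config.base_channels
        k = config.kernel
        n_down = config.n_aux_branches - 1
        res_per_stage = config.n_res_modules // n_down

        self.stage0 = Sequential(
            Conv3d(1, c1, k, stride=1, rng=rng), BatchNorm3d(c1), ReLU(),
            Conv3d(c1, c1, k, stride=1, rng=rng), BatchNorm3d(c1), ReLU(),
        )
        self.stages: list[Sequential] = []
        c_prev = c1
        for _ in range(n_down):
            blocks = [Conv3d(c_prev, c2, k, stride=2, rng=rng), BatchNorm3d(c2), ReLU()]
            blocks += [ResidualModule(c2, k, rng) for _ in range(res_per_stage)]
            self.stages.append(Sequential(*blocks))
            c_prev = c2
        # one branch per resolution: deconv to full resolution, then 1x1x1 classifier
        self.branches: list[Sequential] = [
            Sequential(ConvTranspose3d(c1, 2, stride=1, rng=rng),
                       Conv3d(2, 2, kernel=1, stride=1, pad=0, rng=rng, zero_init=True))
        ]
        for i in range(n_down):
            self.branches.append(
                Sequential(ConvTranspose3d(c2, 2, stride=2 ** (i + 1), rng=rng),
                           Conv3d(2, 2, kernel=1, stride=1, pad=0, rng=rng, zero_init=True))
            )

    # ---- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Input (N, 1, D, H, W) → per-voxel 2-channel logits of the same size."""
        feats = [self.stage0.forward(x, train=train)]
        for stage in self.stages:
            feats.append(stage.forward(feats[-1], train=train))
        logits = None
        for branch, f in zip(self.branches, feats):
            o = branch.forward(f, train=train)
            logits = o if logits is None else logits + o
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dfeats = [branch.backward(dlogits) for branch in self.branches]
        grad = dfeats[-1]
        for stage, dskip in zip(reversed(self.stages), reversed(dfeats[:-1])):
            grad = stage.backward(grad) + dskip
        self.stage0.backward(grad)

    def predict_proba(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Softmax posterior (N, 2, D, H, W); channel 1 is foreground."""
        return softmax_channels(self.forward(x, train=train))

    # ---- parameter plumbing ------------------------------------------------

    def _modules(self) -> list[Sequential]:
        return [self.stage0, *self.stages, *self.branches]

    @property
    def params(self):
        return [p for m in self._modules() for p in m.params]

    @property
    def grads(self):
        return [g for m in self._modules() for g in m.grads]

    def zero_grad(self):
        for m in self._modules():
            m.zero_grad()

    def iter_layers(self):
        for m in self._modules():
            yield from m.iter_layers()

    def get_state(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, layer in enumerate(self.iter_layers()):
            for j, p in enumerate(layer.params):
                state[f"layer{i}_param{j}"] = p
            if isinstance(layer, BatchNorm3d):
                state[f"layer{i}_rmean"] = layer.running_mean
                state[f"layer{i}_rvar"] = layer.running_var
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.iter_layers()):
            for j, p in enumerate(layer.params):
                p[...] = state[f"layer{i}_param{j}"]
            if isinstance(layer, BatchNorm3d):
                layer.running_mean[...] = state[f"layer{i}_rmean"]
                layer.running_var[...] = state[f"layer{i}_rvar"]

    def save(self, path) -> None:
        np.savez(path, **self.get_state())

    @classmethod
    def load(cls, path, config: NetworkConfig) -> "VoxResNet":
        model = cls(config)
        with np.load(path) as data:
            model.set_state({k: data[k] for k in data.files})
        return model


def softmax_channels(logits: np.ndarray) -> np.ndarray:
    """Numerically stable softmax over the channel axis (axis 1)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def build_network(config: NetworkConfig,
                  rng: np.random.Generator | None = None) -> VoxResNet:
    return VoxResNet(config, rng=rng)


def layer_census(model: VoxResNet) -> tuple[int, int]:
    """(number of convolutional layers, number of deconvolutional layers)."""
    n_conv = sum(isinstance(l, Conv3d) for l in model.iter_layers())
    n_deconv = sum(isinstance(l, ConvTranspose3d) for l in model.iter_layers())
    return n_conv, n_deconv
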