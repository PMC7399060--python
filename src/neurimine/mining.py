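"""Weak-neurite mining: refine pseudo-labels from the network's probability map.

Tracers and the first-round network both miss neurite stretches whose
intensity sits near the noise floor. This module recovers them from the
predicted foreground posterior by exploiting two structural priors — neurites
are continuous, and they are tubular:

1. **Seed region** ``O_reg``: argmax classification (foreground probability
   above 0.5), with 26-connected components smaller than 200 voxels discarded
   as noise.
2. **Adaptive-threshold region growing**: each seed component is flood-grown
   over voxels whose probability exceeds ``thre``, the mean probability over
   the component's 5³−1 shell neighbourhood (124 offsets, seed excluded),
   fixed before growth. Dim stretches whose probabilities exceed this local
   background level are bridged.
3. **Thinning**: the grown region is reduced to a 1-voxel-wide medial-axis
   skeleton (topology-preserving Lee thinning) and short terminal branches —
   spurious end nodes from surface irregularity — are pruned.
4. **Relabeling**: radius-2 cylinders around the pruned skeleton become the
   next round of pseudo-labels.

``run_iterations`` wraps train → predict → refine until the pseudo-labels
converge (Dice between successive generations) or an iteration cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .pseudolabel import rasterize_cylinders
from .stackio import ImageStack, LabelMask, ProbabilityMap, check_same_shape
from .segnet import (LossConfig, NetworkConfig, TrainConfig, VoxResNet,
                     build_network, predict, sample_patches, train)

__all__ = [
    "MiningConfig", "IterationConfig",
    "seed_region", "adaptive_threshold", "grow_region", "skeletonize",
    "prune_skeleton_branches", "refine_labels", "run_iterations", "dice",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT18 = ndimage.generate_binary_structure(3, 2)


def _growth_structure(connectivity: int) -> np.ndarray:
    try:
        return {6: _STRUCT6, 18: _STRUCT18, 26: _STRUCT26}[connectivity]
    except KeyError:
        raise ValueError("grow_neighborhood must be 6, 18 or 26") from None


@dataclass
class MiningConfig:
    """Mining stage parameters.

    ``grow_neighborhood`` selects the voxel adjacency used by region growing
    (26 by default so growth can follow neurites out of plane); the
    threshold's shell neighbourhood is always the 5³−1 cube. ``thre_scope``
    selects whether the adaptive threshold is computed per seed component
    (default — weak neurites near bright ones keep a local threshold) or once
    globally.
    """

    min_object_voxels: int = 200
    grow_neighborhood: int = 26
    min_branch_nodes: int = 5
    cylinder_radius: float = 2.0
    thre_scope: str = "component"  # or "global"

    def __post_init__(self) -> None:
        if self.min_object_voxels < 0:
            raise ValueError("min_object_voxels must be >= 0")
        _growth_structure(self.grow_neighborhood)
        if self.thre_scope not in ("component", "global"):
            raise ValueError("thre_scope must be 'component' or 'global'")

    @property
    def thre_neighborhood(self) -> np.ndarray:
        """The 124 offsets of the 5³−1 shell used by the adaptive threshold."""
        offs = np.array([(i, j, k)
                         for i in range(-2, 3)
                         for j in range(-2, 3)
                         for k in range(-2, 3)
                         if (i, j, k) != (0, 0, 0)])
        return offs


@dataclass
class IterationConfig:
    """Outer-loop controls: iteration cap (3–5 in practice) and the Dice level
    at which successive pseudo-label generations count as converged."""

    max_iterations: int = 3
    convergence_dice: float = 0.995

    def __post_init__(self) -> None:
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not (0.0 <= self.convergence_dice <= 1.0):
            raise ValueError("convergence_dice must be in [0, 1]")


# --------------------------------------------------------------------------- #
# mining stages
# --------------------------------------------------------------------------- #


def seed_region(prob: ProbabilityMap, config: MiningConfig | None = None) -> LabelMask:
    """Argmax foreground (p > 0.5) with small 26-connected objects removed.

    Components with volume strictly below ``min_object_voxels`` are dropped.
    """
    config = config or MiningConfig()
    fg = prob.values > 0.5
    if config.min_object_voxels > 0 and fg.any():
        lab, n = ndimage.label(fg, structure=_STRUCT26)
        sizes = np.bincount(lab.ravel())
        small = sizes < config.min_object_voxels
        small[0] = False
        fg[small[lab]] = False
    return LabelMask(values=fg)


def adaptive_threshold(seed: LabelMask, prob: ProbabilityMap,
                       config: MiningConfig | None = None) -> float:
    """Mean probability over the seed's 5³−1 shell, excluding the seed itself.

    Computed once before growth and held fixed; it estimates the local
    probability level just outside the confidently classified region.
    """
    config = config or MiningConfig()
    check_same_shape(seed, prob)
    s = seed.values
    if not s.any():
        raise ValueError("empty seed region")
    shell = ndimage.binary_dilation(s, structure=np.ones((5, 5, 5), dtype=bool)) & ~s
    if not shell.any():
        raise ValueError("seed fills the volume; no shell neighbourhood")
    return float(prob.values[shell].mean())


def grow_region(seed: LabelMask, prob: ProbabilityMap, thre: float,
                config: MiningConfig | None = None) -> LabelMask:
    """Fixed point of threshold-gated neighbourhood expansion from the seed.

    Equivalent to a flood fill from the seed over ``{v : s(v) > thre}``
    restricted to the growth adjacency, unioned with the seed: the admissible
    components that touch (are adjacent to) the seed are annexed whole.
    """
    config = config or MiningConfig()
    check_same_shape(seed, prob)
    if not (0.0 <= thre <= 1.0):
        raise ValueError("thre must lie in [0, 1]")
    struct = _growth_structure(config.grow_neighborhood)
    admissible = prob.values > thre
    if not seed.values.any() or not admissible.any():
        return LabelMask(values=seed.values.copy())
    lab, n = ndimage.label(admissible, structure=struct)
    touch = ndimage.binary_dilation(seed.values, structure=struct)
    hit = np.unique(lab[touch & admissible])
    hit = hit[hit > 0]
    grown = seed.values | np.isin(lab, hit)
    return LabelMask(values=grown)


def skeletonize(mask: LabelMask) -> np.ndarray:
    """Topology-preserving 3D medial-axis thinning; (n, 3) voxel coordinates.

    Thinning can annihilate degenerate plate-like components (e.g. a 2-voxel
    thick bar has no interior and every voxel is iteratively deletable); any
    input component left without skeleton voxels is kept whole instead, so the
    26-connected component count is always preserved.
    """
    if not mask.values.any():
        return np.empty((0, 3), dtype=int)
    skel = _skimage_skeletonize(mask.values)
    lab, n = ndimage.label(mask.values, structure=_STRUCT26)
    if n:
        covered = np.unique(lab[skel & mask.values])
        missing = np.setdiff1d(np.arange(1, n + 1), covered)
        if len(missing):
            skel = skel | np.isin(lab, missing)
    return np.argwhere(skel)


def _adjacency(points: np.ndarray) -> dict[int, list[int]]:
    index = {tuple(p): i for i, p in enumerate(points)}
    adj: dict[int, list[int]] = {i: [] for i in range(len(points))}
    offs = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)]
    for i, p in enumerate(points):
        for o in offs:
            q = (p[0] + o[0], p[1] + o[1], p[2] + o[2])
            j = index.get(q)
            if j is not None and j > i:
                adj[i].append(j)
                adj[j].append(i)
    return adj


def prune_skeleton_branches(points: np.ndarray,
                            config: MiningConfig | None = None) -> np.ndarray:
    """Remove endpoint-to-junction paths shorter than ``min_branch_nodes``.

    Operates on the 26-adjacency graph of skeleton voxels, repeating until
    stable; unbranched chains (no junction) are never removed.
    """
    config = config or MiningConfig()
    points = np.asarray(points).reshape(-1, 3)
    if len(points) == 0:
        return points.astype(int)
    keep = np.ones(len(points), dtype=bool)
    while True:
        active = np.flatnonzero(keep)
        pts = points[active]
        adj = _adjacency(pts)
        deg = {i: len(adj[i]) for i in adj}
        removed_any = False
        for leaf in [i for i in adj if deg[i] == 1]:
            path = [leaf]
            prev, cur = None, leaf
            hit_junction = False
            while True:
                nbrs = [n for n in adj[cur] if n != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                if deg[nxt] >= 3:
                    hit_junction = True
                    break
                path.append(nxt)
                prev, cur = cur, nxt
            if hit_junction and len(path) < config.min_branch_nodes:
                keep[active[path]] = False
                removed_any = True
                break  # adjacency changed; rebuild
        if not removed_any:
            return points[keep].astype(int)


def refine_labels(prob: ProbabilityMap, config: MiningConfig | None = None,
                  shape: tuple[int, int, int] | None = None) -> LabelMask:
    """Full mining pass: seed → adaptive threshold → grow → thin → prune →
    radius-2 cylinder relabeling. Empty seeds yield empty labels."""
    config = config or MiningConfig()
    shape = shape or prob.shape
    seeds = seed_region(prob, config)
    if not seeds.values.any():
        return LabelMask(values=np.zeros(shape, dtype=bool))

    def _grow(component: LabelMask) -> np.ndarray:
        try:
            thre = adaptive_threshold(component, prob, config)
        except ValueError:
            return component.values  # no shell left: nothing to grow into
        return grow_region(component, prob, thre, config).values

    if config.thre_scope == "global":
        grown = _grow(seeds)
    else:
        lab, n = ndimage.label(seeds.values, structure=_STRUCT26)
        grown = np.zeros(shape, dtype=bool)
        for c in range(1, n + 1):
            grown |= _grow(LabelMask(values=lab == c))

    pts = skeletonize(LabelMask(values=grown))
    pts = prune_skeleton_branches(pts, config)
    return rasterize_cylinders(pts, config.cylinder_radius, shape)


def dice(a: LabelMask, b: LabelMask) -> float:
    """Dice overlap between two binary masks (1.0 when both are empty)."""
    check_same_shape(a, b)
    inter = float((a.values & b.values).sum())
    total = float(a.values.sum()) + float(b.values.sum())
    return 1.0 if total == 0 else 2.0 * inter / total


@dataclass
class IterationAudit:
    """Per-iteration trail: label masks, Dice against the previous generation,
    and training loss histories."""

    label_masks: list[LabelMask] = field(default_factory=list)
    dices: list[float] = field(default_factory=list)
    loss_histories: list[list[float]] = field(default_factory=list)


def run_iterations(image: ImageStack, initial_labels: LabelMask,
                   net_cfg: NetworkConfig, train_cfg: TrainConfig,
                   mining_cfg: MiningConfig | None = None,
                   iter_cfg: IterationConfig | None = None,
                   loss_cfg: LossConfig | None = None,
                   seed: int | None = None,
                   ) -> tuple[VoxResNet, LabelMask, IterationAudit]:
    """Iterate train → predict → refine until label convergence or the cap.

    Iteration k trains a fresh network on generation k−1 labels, predicts a
    probability map, and mines generation k. Stops early when the Dice between
    successive generations reaches ``convergence_dice``. Returns the last
    trained model, the final labels, and the audit trail (all intermediate
    masks retained).
    """
    mining_cfg = mining_cfg or MiningConfig()
    iter_cfg = iter_cfg or IterationConfig()
    check_same_shape(image, initial_labels)
    base_seed = train_cfg.seed if seed is None else seed
    audit = IterationAudit()
    labels = initial_labels
    model = None
    for k in range(1, iter_cfg.max_iterations + 1):
        rng = np.random.default_rng((base_seed + 7919 * k) % 2 ** 31)
        try:
            candidate = build_network(net_cfg, rng=rng)
            patches = sample_patches(image, labels, train_cfg, rng=rng)
            model, history = train(candidate, patches, train_cfg, loss_cfg, rng=rng)
        except Exception:
            if model is not None:
                break  # abort with the last good state
            raise
        prob = predict(model, image, patch_size=net_cfg.input_patch)
        new_labels = refine_labels(prob, mining_cfg, shape=image.shape)
        d = dice(new_labels, labels)
        audit.label_masks.append(new_labels)
        audit.dices.append(d)
        audit.loss_histories.append(history)
        labels = new_labels
        if d >= iter_cfg.convergence_dice:
            break
    return model, labels, audit
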