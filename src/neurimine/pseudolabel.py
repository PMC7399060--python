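"""Initial training labels from traced skeletons.

The first stage of the weakly supervised loop: a traced skeleton (from any
automatic tracer) is pruned of speckle-sized fragments and stubby terminal
branches, resampled so consecutive centerline voxels are 26-adjacent, and
dilated into radius-2 cylinders. The resulting binary mask is the initial
pseudo-label a segmentation network trains on — no manual annotation enters
anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .stackio import LabelMask, SkeletonForest, SwcNode

__all__ = [
    "LabelConfig",
    "prune_skeleton",
    "resample_connected",
    "rasterize_cylinders",
    "build_labels",
]


@dataclass
class LabelConfig:
    """Pseudo-label construction parameters.

    ``cylinder_radius`` is fixed at 2 voxels by convention — the low end of a
    typical neurite radius, so labels stay inside the true tube. The pruning
    thresholds drop tracer fragments produced by background speckle.
    """

    cylinder_radius: float = 2.0
    min_component_nodes: int = 10
    min_branch_nodes: int = 5

    def __post_init__(self) -> None:
        if self.cylinder_radius < 1:
            raise ValueError("cylinder_radius must be >= 1 voxel")
        if self.min_component_nodes < 0 or self.min_branch_nodes < 0:
            raise ValueError("prune thresholds must be >= 0")


def prune_skeleton(forest: SkeletonForest, config: LabelConfig) -> SkeletonForest:
    """Drop small connected components and short terminal branches.

    A terminal branch is the path from a leaf up to (but excluding) the
    nearest branch node; an unbranched whole component is never treated as a
    terminal branch. Applied repeatedly the result is a fixed point after one
    pass per rule, so the operation is idempotent.
    """
    keep = {n.id for n in forest.nodes}
    by_id = forest.by_id()
    children = forest.children()

    # rule 1: isolated short components
    for comp in forest.components():
        if len(comp) < config.min_component_nodes:
            keep -= set(comp)

    # rule 2: short terminal branches, iterated to a fixed point
    changed = True
    while changed:
        changed = False
        adj: dict[int, list[int]] = {i: [] for i in keep}
        for i in keep:
            p = by_id[i].parent
            if p != -1 and p in keep:
                adj[i].append(p)
                adj[p].append(i)
        deg = {i: len(adj[i]) for i in keep}
        for leaf in [i for i in keep if deg[i] == 1]:
            if leaf not in keep:
                continue
            # walk along the chain until a branch node (degree >= 3) or the end
            path = [leaf]
            prev, cur = None, leaf
            hit_branch = False
            while True:
                nbrs = [n for n in adj[cur] if n != prev]
                if not nbrs:
                    break  # other end of an unbranched component: not a side-branch
                nxt = nbrs[0]
                if deg[nxt] >= 3:
                    hit_branch = True
                    break
                path.append(nxt)
                prev, cur = cur, nxt
            if hit_branch and len(path) < config.min_branch_nodes:
                keep -= set(path)
                changed = True
                break  # degrees changed; recompute adjacency before continuing

    # rebuild: children of removed nodes become roots
    new_nodes = []
    for n in forest.nodes:
        if n.id not in keep:
            continue
        parent = n.parent if n.parent in keep else -1
        new_nodes.append(SwcNode(id=n.id, type=n.type, position=n.position,
                                 radius=n.radius, parent=parent))
    return SkeletonForest(nodes=new_nodes)


def _digital_line(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Rounded voxels of the segment a→b; consecutive outputs are 26-adjacent."""
    n = int(np.ceil(np.abs(b - a).max())) + 1
    t = np.linspace(0.0, 1.0, max(n, 2))
    pts = a[None, :] + t[:, None] * (b - a)[None, :]
    # round half up, per-axis, so sub-voxel ties are deterministic
    vox = np.floor(pts + 0.5).astype(int)
    # drop consecutive duplicates
    keep = np.ones(len(vox), dtype=bool)
    keep[1:] = np.any(vox[1:] != vox[:-1], axis=1)
    return vox[keep]


def resample_connected(forest: SkeletonForest) -> np.ndarray:
    """Dense voxel centerline: every parent–child segment becomes the rounded
    voxels of its digital line, so consecutive points along each edge chain are
    26-adjacent. Returns unique (z, y, x) integer coordinates, (n, 3)."""
    by_id = forest.by_id()
    pts: list[np.ndarray] = []
    for n in forest.nodes:
        x, y, z = n.position
        a = np.array([z, y, x], dtype=float)
        if n.parent == -1:
            pts.append(_digital_line(a, a))
            continue
        p = by_id[n.parent]
        px, py, pz = p.position
        b = np.array([pz, py, px], dtype=float)
        pts.append(_digital_line(b, a))
    if not pts:
        return np.empty((0, 3), dtype=int)
    allpts = np.concatenate(pts, axis=0)
    return np.unique(allpts, axis=0)


def rasterize_cylinders(points: np.ndarray, radius: float,
                        shape: tuple[int, int, int]) -> LabelMask:
    """Mask of voxels within Euclidean ``radius`` of any skeleton point.

    The tube is the union of balls along the dense centerline — exactly
    testable against a per-voxel nearest-point oracle. Out-of-bounds points
    still contribute to in-bounds voxels.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    mask = np.zeros(shape, dtype=bool)
    if len(points) == 0:
        return LabelMask(values=mask)
    tree = cKDTree(points)
    nz, ny, nx = shape
    grid = np.stack(
        np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"), axis=-1
    ).reshape(-1, 3).astype(float)
    d, _ = tree.query(grid, k=1, distance_upper_bound=radius + 1e-9)
    mask = (d <= radius).reshape(shape)
    return LabelMask(values=mask)


def build_labels(forest: SkeletonForest, shape: tuple[int, int, int],
                 config: LabelConfig | None = None) -> LabelMask:
    """Full pseudo-label construction: prune → resample → rasterize."""
    config = config or LabelConfig()
    pruned = prune_skeleton(forest, config)
    points = resample_connected(pruned)
    return rasterize_cylinders(points, config.cylinder_radius, shape)
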