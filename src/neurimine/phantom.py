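"""Synthetic 3D neurite phantoms with paired gold-standard skeletons.

Emulates the data regime this pipeline targets: tubular neurites of radius
2–4 voxels threading a noisy, low-SNR background, with along-path intensity
inhomogeneity — each path carries one contiguous "weak" stretch rendered near
the background level, the structure a threshold-based tracer misses and the
mining loop is meant to recover.

Every run is fully determined by the config seed, so phantoms double as
reproducible test fixtures; no data ships with the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .stackio import ImageStack, LabelMask, SkeletonForest, SwcNode

__all__ = ["PhantomConfig", "Phantom", "generate_phantom", "snr_of"]


@dataclass
class PhantomConfig:
    """Conditions of the synthetic imaging regime.

    Defaults mirror a dim fluorescence stack: 8-bit range, foreground peak
    about 12 noise standard deviations over background, and a 20% stretch of
    each neurite rendered one noise standard deviation above background.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    n_neurites: int = 2
    radius_range: tuple[float, float] = (2.0, 4.0)
    peak_intensity: float = 160.0
    dim_fraction: float = 0.2
    dim_intensity: float = 50.0
    background_level: float = 40.0
    gauss_sigma_noise: float = 10.0
    poisson: bool = False
    seed: int = 0
    node_spacing: float = 2.0  # SWC node spacing along the path, voxels
    straight_axial: bool = False  # axis-aligned integer centerlines (test fixtures)

    def __post_init__(self) -> None:
        if not (self.dim_intensity < self.peak_intensity):
            raise ValueError("dim_intensity must be below peak_intensity")
        lo, hi = self.radius_range
        if not (1.0 <= lo <= hi <= 6.0):
            raise ValueError("radius_range must lie within [1, 6]")
        if not (0.0 <= self.dim_fraction < 1.0):
            raise ValueError("dim_fraction must be in [0, 1)")
        if min(self.shape) < 8:
            raise ValueError("volume too small for a phantom")


@dataclass
class Phantom:
    """A generated phantom: image, gold skeleton/mask, and the tracer view.

    ``traced`` is the gold skeleton with the dim stretches removed — what an
    intensity-threshold tracer would plausibly recover — and is the natural
    starting point for pseudo-label construction.
    """

    image: ImageStack
    skeleton: SkeletonForest
    mask: LabelMask
    traced: SkeletonForest
    centerlines: list[np.ndarray] = field(default_factory=list)  # (m,3) zyx, dense
    dim_flags: list[np.ndarray] = field(default_factory=list)  # per dense point
    radii: list[float] = field(default_factory=list)

    def __iter__(self):
        # allows: image, skeleton, mask = generate_phantom(cfg)
        return iter((self.image, self.skeleton, self.mask))


def _random_path(rng: np.random.Generator, shape, n_steps: int, margin: float) -> np.ndarray:
    """A smooth, bounded-curvature random polyline inside the volume (zyx)."""
    lo = np.full(3, margin)
    hi = np.asarray(shape, dtype=float) - 1 - margin
    if np.any(hi <= lo):
        raise ValueError("volume too small to place a neurite path")
    pos = rng.uniform(lo, hi)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    pts = [pos.copy()]
    for _ in range(n_steps - 1):
        # small angular jitter keeps curvature bounded
        direction = direction + 0.15 * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        nxt = pos + direction
        # reflect off the interior margin box
        for ax in range(3):
            if nxt[ax] < lo[ax] or nxt[ax] > hi[ax]:
                direction[ax] = -direction[ax]
                nxt[ax] = np.clip(nxt[ax], lo[ax], hi[ax])
        pos = nxt
        pts.append(pos.copy())
    return np.asarray(pts)


def _densify(path: np.ndarray, spacing: float = 0.5) -> np.ndarray:
    """Resample a polyline at the given arc-length spacing (keeps endpoints)."""
    seg = np.linalg.norm(np.diff(path, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return path[:1]
    n = max(2, int(np.floor(total / spacing)) + 1)
    t = np.linspace(0.0, total, n)
    return np.column_stack([np.interp(t, arc, path[:, ax]) for ax in range(3)])


def generate_phantom(config: PhantomConfig) -> Phantom:
    """Render tubular neurites with Gaussian radial falloff into a noisy stack.

    Returns a :class:`Phantom`; iterating it yields the
    ``(image, gold skeleton, gold mask)`` triple. The gold mask is exactly the
    set of voxels within each path's radius of its (densely sampled)
    centerline. A contiguous ``dim_fraction`` stretch of every path is
    rendered at ``dim_intensity``.
    """
    rng = np.random.default_rng(config.seed)
    nz, ny, nx = config.shape
    grid = np.stack(
        np.meshgrid(np.arange(nz), np.arange(ny), np.arange(nx), indexing="ij"), axis=-1
    ).reshape(-1, 3).astype(float)

    signal = np.zeros(config.shape, dtype=np.float64)
    mask = np.zeros(config.shape, dtype=bool)
    nodes: list[SwcNode] = []
    traced_nodes: list[SwcNode] = []
    centerlines: list[np.ndarray] = []
    dim_flags: list[np.ndarray] = []
    radii: list[float] = []
    next_id = 1

    n_steps = max(20, int(1.8 * max(config.shape)))
    for _ in range(config.n_neurites):
        radius = rng.uniform(*config.radius_range)
        margin = radius + 1.0
        if config.straight_axial:
            z0 = int(rng.integers(int(np.ceil(margin)), nz - int(np.ceil(margin))))
            y0 = int(rng.integers(int(np.ceil(margin)), ny - int(np.ceil(margin))))
            path = np.array([[z0, y0, 0.0], [z0, y0, float(nx - 1)]])
        else:
            path = _random_path(rng, config.shape, n_steps, margin)
        dense = _densify(path, spacing=0.5)
        m = len(dense)

        dim = np.zeros(m, dtype=bool)
        if config.dim_fraction > 0:
            w = int(round(config.dim_fraction * m))
            if w > 0:
                start = int(rng.integers(0, m - w + 1))
                dim[start : start + w] = True

        tree = cKDTree(dense)
        d, idx = tree.query(grid, k=1)
        d = d.reshape(config.shape)
        idx = idx.reshape(config.shape)
        mask |= d <= radius

        amp = np.where(dim[idx], config.dim_intensity - config.background_level,
                       config.peak_intensity - config.background_level)
        sigma_r = radius / 2.0
        contrib = amp * np.exp(-(d ** 2) / (2.0 * sigma_r ** 2))
        np.maximum(signal, contrib, out=signal)

        # SWC nodes at node_spacing along the same path
        node_pts = _densify(path, spacing=config.node_spacing)
        node_dim = dim[tree.query(node_pts, k=1)[1]]
        parent = -1
        traced_parent = -1
        prev_traced = False
        for j, (z, y, x) in enumerate(node_pts):
            nid = next_id
            next_id += 1
            nodes.append(SwcNode(id=nid, position=(x, y, z), radius=radius, parent=parent))
            if not node_dim[j]:
                traced_nodes.append(
                    SwcNode(id=nid, position=(x, y, z), radius=radius,
                            parent=traced_parent if prev_traced else -1)
                )
                traced_parent = nid
                prev_traced = True
            else:
                prev_traced = False
            parent = nid

        centerlines.append(dense)
        dim_flags.append(dim)
        radii.append(radius)

    image = config.background_level + signal
    if config.poisson:
        image = rng.poisson(np.clip(image, 0, None)).astype(np.float64)
    if config.gauss_sigma_noise > 0:
        image = image + rng.normal(0.0, config.gauss_sigma_noise, size=config.shape)
    image = np.clip(np.rint(image), 0, 255).astype(np.uint8)

    return Phantom(
        image=ImageStack(voxels=image),
        skeleton=SkeletonForest(nodes=nodes),
        mask=LabelMask(values=mask),
        traced=SkeletonForest(nodes=traced_nodes),
        centerlines=centerlines,
        dim_flags=dim_flags,
        radii=radii,
    )


def snr_of(image: ImageStack, gold_mask: LabelMask) -> float:
    """Contrast-to-noise: (mean foreground − mean background) / std background."""
    if image.shape != gold_mask.shape:
        raise ValueError("image/mask shape mismatch")
    fg = gold_mask.values
    if not fg.any():
        raise ValueError("empty foreground")
    if fg.all():
        raise ValueError("empty background")
    vox = image.voxels.astype(np.float64)
    bg = vox[~fg]
    std = bg.std()
    if std == 0:
        raise ValueError("zero background spread; SNR undefined")
    return float((vox[fg].mean() - bg.mean()) / std)
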