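"""On-disk artifacts: image stacks, label masks, probability maps, SWC skeletons.

Conventions pinned here and used everywhere else in the package:

* volumes are numpy arrays with axis order ``(z, y, x)``, 0-based voxel indices;
* SWC node positions are stored as ``(x, y, z)`` in **voxel units**, not microns —
  cylinder radii are specified in voxels, so voxel units keep them exact; the
  physical spacing travels as metadata only;
* label masks are written as 0/255 8-bit TIFF, probability maps as 32-bit float
  TIFF, image stacks keep their integer dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "ProbabilityMap",
    "LabelMask",
    "SwcNode",
    "SkeletonForest",
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "read_prob",
    "write_prob",
    "read_swc",
    "write_swc",
    "check_same_shape",
]


class StackIOError(ValueError):
    """Raised for malformed on-disk artifacts."""


# --------------------------------------------------------------------------- #
# volume types
# --------------------------------------------------------------------------- #


@dataclass
class ImageStack:
    """A 3D single-channel intensity volume.

    Parameters
    ----------
    voxels
        Intensity grid, shape ``(nz, ny, nx)``, non-negative.
    spacing
        Physical voxel size ``(dz, dy, dx)`` in micron; metadata only.
    max_intensity
        The maximum representable intensity ``I_M`` used by image enhancement.
        Defaults to the dtype maximum for integer volumes (255 for 8-bit,
        65535 for 16-bit) and to the observed maximum otherwise.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    max_intensity: float | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise StackIOError(f"image stack must be 3D, got shape {self.voxels.shape}")
        if self.voxels.size and self.voxels.min() < 0:
            raise StackIOError("image intensities must be non-negative")
        if self.max_intensity is None:
            if np.issubdtype(self.voxels.dtype, np.integer):
                self.max_intensity = float(np.iinfo(self.voxels.dtype).max)
            else:
                self.max_intensity = float(self.voxels.max()) if self.voxels.size else 1.0
        if self.voxels.size and float(self.voxels.max()) > self.max_intensity:
            raise StackIOError("max_intensity below observed maximum")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ProbabilityMap:
    """Per-voxel foreground posterior in [0, 1], same shape as its image."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise StackIOError(f"probability map must be 3D, got {self.values.shape}")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise StackIOError("probability values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class LabelMask:
    """Binary 3D voxel mask (pseudo-labels, seed/grown regions, gold tubes)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise StackIOError(f"label mask must be 3D, got {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1, 255))):
                raise StackIOError("label mask values must be binary")
            arr = arr > 0
        self.values = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


def check_same_shape(*volumes) -> tuple[int, int, int]:
    """Raise before any computation if the volumes of one run disagree in shape."""
    shapes = {v.shape for v in volumes}
    if len(shapes) > 1:
        raise StackIOError(f"volume shape mismatch: {sorted(shapes)}")
    return next(iter(shapes))


# --------------------------------------------------------------------------- #
# skeletons
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SwcNode:
    """One SWC record: id, structure type, position (x, y, z), radius, parent id."""

    id: int
    position: tuple[float, float, float]
    radius: float = 1.0
    parent: int = -1
    type: int = 2  # axon by default; carries no semantics in this pipeline


@dataclass
class SkeletonForest:
    """A set of trees of centerline nodes, edges implied by parent links."""

    nodes: list[SwcNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [n.id for n in self.nodes]
        if len(ids) != len(set(ids)):
            raise StackIOError("duplicate node ids in skeleton")
        idset = set(ids)
        for n in self.nodes:
            if n.parent != -1 and n.parent not in idset:
                raise StackIOError(f"node {n.id} references missing parent {n.parent}")
            if n.id <= 0:
                raise StackIOError("node ids must be positive")
        # forest check: walking parent links from any node must terminate
        parent = {n.id: n.parent for n in self.nodes}
        for start in parent:
            seen = set()
            cur = start
            while cur != -1:
                if cur in seen:
                    raise StackIOError("cycle in skeleton parent links")
                seen.add(cur)
                cur = parent[cur]

    def __len__(self) -> int:
        return len(self.nodes)

    def by_id(self) -> dict[int, SwcNode]:
        return {n.id: n for n in self.nodes}

    def children(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {n.id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent != -1:
                ch[n.parent].append(n.id)
        return ch

    def roots(self) -> list[int]:
        return [n.id for n in self.nodes if n.parent == -1]

    def components(self) -> list[list[int]]:
        """Node ids grouped by tree (connected component of parent links)."""
        ch = self.children()
        comps = []
        for r in self.roots():
            comp, stack = [], [r]
            while stack:
                i = stack.pop()
                comp.append(i)
                stack.extend(ch[i])
            comps.append(comp)
        return comps

    def positions_zyx(self) -> np.ndarray:
        """Node positions as an (n, 3) float array in (z, y, x) voxel order."""
        if not self.nodes:
            return np.empty((0, 3), dtype=float)
        return np.array([(n.position[2], n.position[1], n.position[0]) for n in self.nodes])


# --------------------------------------------------------------------------- #
# TIFF i/o
# --------------------------------------------------------------------------- #

_ALLOWED_DTYPES = (np.uint8, np.uint16)


def read_stack(path: str | Path, observed_max: bool = False) -> ImageStack:
    """Read a single-channel TIFF stack.

    Rejects multi-channel/RGB input and bit depths outside 8–16. With
    ``observed_max`` the stack's ``I_M`` is the observed maximum rather than
    the dtype maximum.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        if any(page.samplesperpixel > 1 for page in tif.pages):
            raise StackIOError("multi-channel/RGB stacks are not supported")
        arr = tif.asarray()
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise StackIOError(f"expected a single-channel stack, got shape {arr.shape}")
    if arr.dtype not in [np.dtype(d) for d in _ALLOWED_DTYPES]:
        raise StackIOError(f"unsupported bit depth for image stack: {arr.dtype}")
    kwargs = {}
    if observed_max:
        kwargs["max_intensity"] = float(arr.max()) if arr.size else 0.0
    return ImageStack(voxels=arr, **kwargs)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.ascontiguousarray(stack.voxels), photometric="minisblack")
    return path


def read_labels(path: str | Path) -> LabelMask:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return LabelMask(values=arr)


def write_labels(mask: LabelMask, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (mask.values.astype(np.uint8) * 255), photometric="minisblack")
    return path


def read_prob(path: str | Path) -> ProbabilityMap:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 2:
        arr = arr[None]
    return ProbabilityMap(values=arr.astype(np.float32))


def write_prob(prob: ProbabilityMap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, prob.values.astype(np.float32), photometric="minisblack")
    return path


# --------------------------------------------------------------------------- #
# SWC i/o
# --------------------------------------------------------------------------- #


def read_swc(path: str | Path) -> SkeletonForest:
    """Parse a whitespace-delimited 7-column SWC file (comments start with '#')."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    nodes: list[SwcNode] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise StackIOError(f"{path}:{lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid, ntype = int(parts[0]), int(parts[1])
                x, y, z, r = (float(p) for p in parts[2:6])
                parent = int(parts[6])
            except ValueError as exc:
                raise StackIOError(f"{path}:{lineno}: parse failure: {exc}") from exc
            nodes.append(SwcNode(id=nid, type=ntype, position=(x, y, z), radius=r, parent=parent))
    return SkeletonForest(nodes=nodes)


def write_swc(forest: SkeletonForest, path: str | Path) -> Path:
    """Write a 7-column SWC file with every parent line preceding its children."""
    path = Path(path)
    by_id = forest.by_id()
    children = forest.children()
    ordered: list[SwcNode] = []
    for root in forest.roots():
        stack = [root]
        while stack:
            i = stack.pop()
            ordered.append(by_id[i])
            stack.extend(reversed(children[i]))
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in ordered:
            x, y, z = n.position
            fh.write(f"{n.id} {n.type} {x:g} {y:g} {z:g} {n.radius:g} {n.parent}\n")
    return path
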