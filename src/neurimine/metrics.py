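"""Skeleton-based evaluation: equal-spacing resampling, distance-matched
precision/recall, and the five neuron-distance criteria.

All comparisons operate on skeletons resampled to 1-voxel arc-length spacing.
A traced point is a true positive when its nearest gold-standard point lies
strictly closer than the match radius ``n`` (6 voxels by default, about the
neurite diameter). The neuron distances follow the bidirectional
entire-structure-average convention:

* ``ESA12`` — mean nearest-point distance from neuron 1 (gold) to neuron 2;
* ``ESA21`` — the reverse direction; ``ESA`` — their average;
* ``PDS``  — fraction of pooled points (both directions) whose nearest-point
  distance exceeds the distance threshold (2 voxels by default);
* ``DSA``  — mean nearest-point distance over those "different structure"
  points, 0 when there are none.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .stackio import SkeletonForest

__all__ = [
    "MetricsConfig", "MetricsReport",
    "resample_equal", "pooled_points", "precision_recall", "neuron_distances",
    "evaluate_forests", "mask_points",
]


@dataclass
class MetricsConfig:
    match_radius: float = 6.0
    distance_threshold: float = 2.0
    resample_spacing: float = 1.0
    directional: bool = False  # pool only gold→test distances for DSA/PDS

    def __post_init__(self) -> None:
        if min(self.match_radius, self.distance_threshold, self.resample_spacing) <= 0:
            raise ValueError("all metric parameters must be positive")


@dataclass
class MetricsReport:
    precision: float | None
    recall: float | None
    ESA12: float
    ESA21: float
    ESA: float
    DSA: float
    PDS: float
    n_matched_12: int
    n_unmatched_12: int
    n_matched_21: int
    n_unmatched_21: int

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2))
        return path


# --------------------------------------------------------------------------- #
# resampling
# --------------------------------------------------------------------------- #


def _polyline_resample(poly: np.ndarray, spacing: float) -> np.ndarray:
    """Arc-length resampling; keeps both endpoints (last gap may be shorter)."""
    if len(poly) == 1:
        return poly.copy()
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return poly[:1].copy()
    t = np.arange(0.0, total, spacing)
    if total - t[-1] > 1e-12:
        t = np.concatenate([t, [total]])
    return np.column_stack([np.interp(t, arc, poly[:, ax]) for ax in range(3)])


def resample_equal(forest: SkeletonForest, spacing: float = 1.0) -> list[np.ndarray]:
    """Every root-to-leaf polyline re-parameterized at the given arc-length
    spacing; returns a list of (m, 3) point sequences in (z, y, x) order."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    by_id = forest.by_id()
    children = forest.children()
    sequences: list[np.ndarray] = []

    def pos_zyx(i: int) -> tuple[float, float, float]:
        x, y, z = by_id[i].position
        return (z, y, x)

    for root in forest.roots():
        # depth-first enumeration of root-to-leaf node paths
        stack = [(root, [root])]
        while stack:
            cur, path = stack.pop()
            kids = children[cur]
            if not kids:
                poly = np.array([pos_zyx(i) for i in path], dtype=float)
                sequences.append(_polyline_resample(poly, spacing))
            else:
                for k in kids:
                    stack.append((k, path + [k]))
    return sequences


def pooled_points(forest: SkeletonForest, spacing: float = 1.0) -> np.ndarray:
    """All resampled points of a forest as one deduplicated (n, 3) array."""
    seqs = resample_equal(forest, spacing)
    if not seqs:
        return np.empty((0, 3), dtype=float)
    pts = np.concatenate(seqs, axis=0)
    return np.unique(pts, axis=0)


def mask_points(mask) -> np.ndarray:
    """Foreground voxel coordinates of a label mask as an (n, 3) float array."""
    return np.argwhere(np.asarray(getattr(mask, "values", mask))).astype(float)


# --------------------------------------------------------------------------- #
# matching metrics
# --------------------------------------------------------------------------- #


def _nearest(from_pts: np.ndarray, to_pts: np.ndarray) -> np.ndarray:
    if len(from_pts) == 0:
        return np.empty(0)
    d, _ = cKDTree(to_pts).query(from_pts, k=1)
    return d


def precision_recall(test: np.ndarray, gold: np.ndarray,
                     config: MetricsConfig | None = None
                     ) -> tuple[float | None, float | None]:
    """Fraction of test points strictly within the match radius of gold
    (precision) and vice versa (recall). Empty sets give ``None`` — an
    undefined metric is reported as missing, not as zero."""
    config = config or MetricsConfig()
    test = np.asarray(test, dtype=float).reshape(-1, 3)
    gold = np.asarray(gold, dtype=float).reshape(-1, 3)
    n = config.match_radius
    precision = recall = None
    if len(test) and len(gold):
        precision = float(np.mean(_nearest(test, gold) < n))
        recall = float(np.mean(_nearest(gold, test) < n))
    elif len(test) == 0 and len(gold):
        recall = 0.0
    elif len(gold) == 0 and len(test):
        precision = 0.0
    return precision, recall


def neuron_distances(gold: np.ndarray, test: np.ndarray,
                     config: MetricsConfig | None = None) -> MetricsReport:
    """The five distance criteria plus precision/recall for two point sets.

    ``gold`` is neuron 1, ``test`` neuron 2; both must be nonempty and
    resampled at unit spacing.
    """
    config = config or MetricsConfig()
    gold = np.asarray(gold, dtype=float).reshape(-1, 3)
    test = np.asarray(test, dtype=float).reshape(-1, 3)
    if len(gold) == 0 or len(test) == 0:
        raise ValueError("neuron distances need two nonempty point sets")
    d12 = _nearest(gold, test)
    d21 = _nearest(test, gold)
    esa12 = float(d12.mean())
    esa21 = float(d21.mean())
    pool = d12 if config.directional else np.concatenate([d12, d21])
    thr = config.distance_threshold
    different = pool > thr  # strict: exactly at the threshold is "same"
    pds = float(different.mean())
    dsa = float(pool[different].mean()) if different.any() else 0.0
    precision, recall = precision_recall(test, gold, config)
    nmr = config.match_radius
    return MetricsReport(
        precision=precision,
        recall=recall,
        ESA12=esa12,
        ESA21=esa21,
        ESA=(esa12 + esa21) / 2.0,
        DSA=dsa,
        PDS=pds,
        n_matched_12=int((d12 < nmr).sum()),
        n_unmatched_12=int((d12 >= nmr).sum()),
        n_matched_21=int((d21 < nmr).sum()),
        n_unmatched_21=int((d21 >= nmr).sum()),
    )


def evaluate_forests(gold: SkeletonForest, test: SkeletonForest,
                     config: MetricsConfig | None = None) -> MetricsReport:
    """Resample both skeletons at unit spacing and score test against gold."""
    config = config or MetricsConfig()
    g = pooled_points(gold, config.resample_spacing)
    t = pooled_points(test, config.resample_spacing)
    return neuron_distances(g, t, config)
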