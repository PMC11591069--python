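"""Per-view point-cloud cleanup: box crop, density clustering, outlier removal.

Three stages run in order on each raw view before registration:

1. pass-through crop — axis-aligned box around the measurement channel,
   removing everything that is obviously not the animal;
2. DBSCAN cluster filtering — keep the one cluster whose bounding-box
   extent matches a cattle body, dropping railing fragments and noise
   clumps;
3. statistical outlier removal — delete sparse stray points by mean
   k-nearest-neighbour distance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .geometry import PointCloud

__all__ = [
    "CropBox",
    "FilterParams",
    "passthrough_crop",
    "dbscan_cluster",
    "select_target_cluster",
    "statistical_outlier_removal",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CropBox:
    """Axis-aligned crop box given by two diagonal corners (metres)."""

    minimum: tuple
    maximum: tuple

    def __post_init__(self) -> None:
        lo = np.asarray(self.minimum, dtype=float).reshape(3)
        hi = np.asarray(self.maximum, dtype=float).reshape(3)
        if not np.all(lo < hi):
            raise ValueError("crop box min must be strictly below max on every axis")
        object.__setattr__(self, "minimum", tuple(lo))
        object.__setattr__(self, "maximum", tuple(hi))


@dataclass(frozen=True)
class FilterParams:
    """Denoising knobs.

    dbscan_radius
        Neighbourhood radius r of the density clustering, metres.
    dbscan_min_samples
        Minimum neighbour count N for a core point.
    sor_neighbors
        k of the k-NN mean-distance statistic.
    sor_alpha
        Sensitivity α: points with mean k-NN distance above
        mean + α·std (over the cloud) are removed.

    Defaults suit clouds with roughly centimetre point spacing. They are
    deliberately permissive: surfaces seen at grazing angles (the lower
    flank in a side view) are several times sparser than the frontal
    surface, and an aggressive N or α deletes them wholesale, widening
    the ventral data gap the girth bridge must then span. The clustering
    radius must also exceed the railing-bar width — bars cut a side view
    into stripes, and a radius below the void width disconnects them so
    the target-cluster selection would keep a single stripe.
    """

    dbscan_radius: float = 0.08
    dbscan_min_samples: int = 12
    sor_neighbors: int = 20
    sor_alpha: float = 3.0

    def __post_init__(self) -> None:
        if self.dbscan_radius <= 0:
            raise ValueError("dbscan_radius must be positive")
        if self.dbscan_min_samples < 1:
            raise ValueError("dbscan_min_samples must be >= 1")
        if self.sor_neighbors < 1:
            raise ValueError("sor_neighbors must be >= 1")
        if self.sor_alpha <= 0:
            raise ValueError("sor_alpha must be positive")


def passthrough_crop(cloud: PointCloud, box: CropBox) -> PointCloud:
    """Keep exactly the points inside the closed box, order preserved."""
    lo = np.asarray(box.minimum)
    hi = np.asarray(box.maximum)
    mask = np.all((cloud.points >= lo) & (cloud.points <= hi), axis=1)
    if not mask.any():
        warnings.warn("pass-through crop produced an empty cloud", stacklevel=2)
    out = cloud.select(mask)
    log.debug("passthrough_crop: %d -> %d points", len(cloud), len(out))
    return out


def dbscan_cluster(cloud: PointCloud, r: float, N: int) -> PointCloud:
    """Label points by density clustering (noise = -1).

    A point with at least ``N`` neighbours within radius ``r`` (the point
    itself included) is a core point; clusters are the density-connected
    components of core points, with reachable border points attached to
    the first core cluster that claims them in scan order.
    """
    if len(cloud) == 0:
        raise ValueError("empty input cloud")
    if r <= 0 or N < 1:
        raise ValueError("require r > 0 and N >= 1")
    # sklearn counts the point itself when it is its own neighbour at
    # distance 0, matching |N_r(p_i)| >= N over the closed neighbourhood.
    labels = DBSCAN(eps=r, min_samples=N).fit(cloud.points).labels_
    return PointCloud(cloud.points, cloud.normals, labels)


def select_target_cluster(cloud: PointCloud, expected_extent=(2.0, 0.8, 1.5)) -> PointCloud:
    """Pick the cluster whose bounding-box extent best matches a cattle body.

    Score is the summed absolute log-ratio of cluster extent to
    ``expected_extent``; smallest wins, ties broken by larger point count.
    """
    if cloud.labels is None:
        raise ValueError("cloud has no cluster labels; run dbscan_cluster first")
    expected = np.maximum(np.asarray(expected_extent, dtype=float), 1e-9)
    candidates = [c for c in np.unique(cloud.labels) if c != -1]
    if not candidates:
        raise ValueError("no target cluster found")
    best = None
    for c in candidates:
        member = cloud.labels == c
        extent = np.maximum(cloud.points[member].max(axis=0) - cloud.points[member].min(axis=0), 1e-9)
        score = float(np.sum(np.abs(np.log(extent / expected))))
        key = (score, -int(member.sum()))
        if best is None or key < best[0]:
            best = (key, member)
    out = cloud.select(best[1])
    log.debug("select_target_cluster: kept %d of %d points", len(out), len(cloud))
    return out


def sor_mean_knn_distance(points: np.ndarray, k: int) -> np.ndarray:
    """Per-point mean distance to the k nearest other points."""
    tree = cKDTree(points)
    dists, _ = tree.query(points, k=k + 1)  # first hit is the point itself
    return dists[:, 1:].mean(axis=1)


def statistical_outlier_removal(
    cloud: PointCloud, k: int = 20, alpha: float = 2.0, literal: bool = False
) -> PointCloud:
    """Remove sparse stray points by k-NN distance statistics.

    Default (global) rule: compute each point's mean k-NN distance μ_i and
    delete points with μ_i > mean(μ) + α·std(μ) over the cloud — stray
    points sit in sparse regions and have inflated μ_i.

    ``literal=True`` switches to the per-point rule that flags p_i when any
    of its k neighbour distances exceeds μ_i + α·σ_i of its *own* local
    statistics. That rule fires on nearly any cloud with local distance
    spread and is exposed for fidelity experiments only.
    """
    n = len(cloud)
    if n <= k:
        raise ValueError("k exceeds cloud size")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)
    neigh = dists[:, 1:]
    mu = neigh.mean(axis=1)
    if literal:
        sigma = neigh.std(axis=1)
        keep = ~(neigh.max(axis=1) > mu + alpha * sigma)
    else:
        keep = ~(mu > mu.mean() + alpha * mu.std())
    out = cloud.select(keep)
    log.debug("statistical_outlier_removal: %d -> %d points", n, len(out))
    return out
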