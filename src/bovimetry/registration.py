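"""Multi-view rigid registration.

The top view defines the reference frame; left and right views are first
coarse-aligned with their mounted-camera extrinsics, then fine-aligned to
the top cloud by point-to-plane ICP. Because adjacent views overlap only
on a narrow flank strip, ICP correspondences are restricted to the
overlap-possible region: the fraction ``fp`` of source points nearest the
target cloud (selected with a bounded max-heap of negated distances).
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .geometry import PointCloud, RigidTransform, apply_transform, compose

__all__ = [
    "OverlapParams",
    "IcpParams",
    "RegistrationResult",
    "coarse_align",
    "estimate_normals",
    "overlap_region",
    "point_to_plane_icp",
    "register_views",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OverlapParams:
    """Fraction fp in (0, 1] of query points kept as the overlap region."""

    fp: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.fp <= 1.0):
            raise ValueError("fp must be in (0, 1]")


@dataclass(frozen=True)
class IcpParams:
    max_iterations: int = 50
    convergence_delta: float = 1e-6  # Frobenius norm of the 4x4 update
    normal_k: int = 20
    # correspondences farther than this multiple of the median pair
    # distance are rejected each iteration
    rejection_factor: float = 5.0

    def __post_init__(self) -> None:
        if self.max_iterations < 1 or self.convergence_delta <= 0 or self.normal_k < 3:
            raise ValueError("IcpParams fields must be positive (normal_k >= 3)")


@dataclass
class RegistrationResult:
    transform: RigidTransform
    rms: float
    iterations: int
    converged: bool
    rms_history: List[float] = field(default_factory=list)
    overlap_indices: Optional[np.ndarray] = None


def coarse_align(cloud: PointCloud, extrinsic: RigidTransform) -> PointCloud:
    """Express a view cloud in the reference (top-camera) frame."""
    return apply_transform(cloud, extrinsic)


def estimate_normals(cloud: PointCloud, k: int, viewpoint=(0.0, 0.0, 0.0)) -> PointCloud:
    """Per-point unit normals from the best-fit plane of k nearest neighbours.

    Signs are oriented toward ``viewpoint`` (the acquiring camera's origin)
    so that neighbouring views agree on orientation over their overlap.
    """
    n = len(cloud)
    if k < 3:
        raise ValueError("normal estimation needs k >= 3")
    if n <= k:
        raise ValueError("cloud size must exceed k")
    tree = cKDTree(cloud.points)
    _, idx = tree.query(cloud.points, k=k + 1)
    neigh = cloud.points[idx]  # (n, k+1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # eigenvector of the smallest eigenvalue
    to_cam = np.asarray(viewpoint, dtype=float) - cloud.points
    flip = np.einsum("ni,ni->n", normals, to_cam) < 0
    normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(cloud.points, normals, cloud.labels)


def overlap_region(query: PointCloud, model: PointCloud, fp: float) -> np.ndarray:
    """Indices of the floor(|query|·fp) query points nearest to the model.

    Nearest distances come from a KD-tree on the model; the selection is
    maintained in a bounded max-heap keyed by negated distance so only the
    current best m candidates are stored. Ties broken by lower index;
    returned indices are sorted ascending.
    """
    if len(query) == 0 or len(model) == 0:
        raise ValueError("query and model clouds must be non-empty")
    if not (0.0 < fp <= 1.0):
        raise ValueError("fp must be in (0, 1]")
    m = int(np.floor(len(query) * fp))
    if m == 0:
        raise ValueError("fp too small for cloud size")
    dis, _ = cKDTree(model.points).query(query.points, k=1)
    # bounded max-heap: python heapq is a min-heap, so store negated
    # distance (and negated index so that among equal distances the
    # *larger* index is evicted first, i.e. lower indices win ties)
    heap: list = []
    for i, d in enumerate(dis):
        item = (-d, -i)
        if len(heap) < m:
            heapq.heappush(heap, item)
        elif item > heap[0]:
            heapq.heapreplace(heap, item)
    idx = np.sort([-i for _, i in heap])
    return idx


def _solve_point_to_plane(src: np.ndarray, tgt: np.ndarray, nrm: np.ndarray) -> np.ndarray:
    """Linearized least-squares twist xi = (omega, t) minimizing
    Σ[(R s + t − q)·n]²."""
    r = np.einsum("ni,ni->n", src - tgt, nrm)
    J = np.hstack([np.cross(src, nrm), nrm])  # (n, 6): [s×n, n]
    H = J.T @ J
    g = J.T @ r
    try:
        return np.linalg.solve(H, -g)
    except np.linalg.LinAlgError:
        return np.linalg.lstsq(H, -g, rcond=None)[0]


def _twist_transform(xi: np.ndarray, scale: float = 1.0) -> RigidTransform:
    omega = xi[:3] * scale
    angle = np.linalg.norm(omega)
    axis = omega / angle if angle > 0 else omega
    return RigidTransform.from_axis_angle(axis, angle, xi[3:] * scale)


def point_to_plane_icp(
    source: PointCloud, target: PointCloud, params: IcpParams = IcpParams()
) -> RegistrationResult:
    """Iteratively align ``source`` onto ``target`` tangent planes.

    Each iteration matches every source point to its nearest target point,
    rejects far pairs (beyond ``rejection_factor`` × median distance),
    solves the small-angle linearization of the point-to-plane objective
    in closed form and applies the update. A step that fails to reduce the
    point-to-plane RMS is backtracked (halved up to four times) before the
    iteration gives up, so the recorded RMS series is non-increasing while
    single overshooting Gauss-Newton steps at coarse misalignment cannot
    stall the registration. Stops when the 4x4 update's Frobenius change
    drops below ``convergence_delta``, no damped step improves the RMS, or
    ``max_iterations`` is reached.
    """
    if len(source) < 10 or len(target) < 10:
        raise ValueError("ICP needs at least 10 points in source and target")
    if target.normals is None:
        target = estimate_normals(target, params.normal_k)
    tree = cKDTree(target.points)

    def correspondences(moved):
        d, j = tree.query(moved, k=1)
        cutoff = params.rejection_factor * max(np.median(d), 1e-12)
        keep = d <= cutoff
        src = moved[keep]
        tgt = target.points[j[keep]]
        nrm = target.normals[j[keep]]
        residual = np.einsum("ni,ni->n", src - tgt, nrm)
        return src, tgt, nrm, float(np.sqrt(np.mean(residual**2))), int(keep.sum())

    T = RigidTransform.identity()
    moved = source.points.copy()
    src, tgt, nrm, rms, n_corr = correspondences(moved)
    rms_history: List[float] = [rms]
    converged = False
    iterations = 0

    for iterations in range(1, params.max_iterations + 1):
        if n_corr < 6:
            warnings.warn("ICP: too few correspondences after rejection", stacklevel=2)
            break
        span = nrm.max(axis=0) - nrm.min(axis=0)
        if np.all(span < 1e-9) and len(nrm) > 1:
            warnings.warn(
                "ICP: degenerate (all-parallel) normal set; result under-constrained",
                stacklevel=2,
            )
        xi = _solve_point_to_plane(src, tgt, nrm)

        accepted = None
        for scale in (1.0, 0.5, 0.25, 0.125):
            step = _twist_transform(xi, scale)
            T_cand = compose(step, T)
            moved_cand = T_cand.apply_points(source.points)
            cand = correspondences(moved_cand)
            if cand[3] <= rms + 1e-15:
                accepted = (step, T_cand, moved_cand, cand)
                break
        if accepted is None:
            converged = True  # no damped step improves: at a minimum
            break
        step, T, moved, (src, tgt, nrm, rms, n_corr) = accepted
        rms_history.append(rms)
        delta = float(np.linalg.norm(step.matrix() - np.eye(4)))
        if delta < params.convergence_delta:
            converged = True
            break

    return RegistrationResult(
        transform=T,
        rms=rms_history[-1],
        iterations=iterations,
        converged=converged,
        rms_history=rms_history,
    )


def register_views(
    top: PointCloud,
    left: PointCloud,
    right: PointCloud,
    extrinsics: Sequence[RigidTransform],
    fp: float = 0.25,
    params: IcpParams = IcpParams(),
):
    """Merge the three preprocessed view clouds into one body cloud.

    ``extrinsics`` are (left, right) camera-to-reference transforms. The
    top cloud (reference view, identity extrinsic) is the ICP target; each
    side view is coarse-aligned, its overlap-possible region against the
    top cloud selected at fraction ``fp``, ICP run with that region as the
    source, and the resulting fine transform applied to the *full* side
    cloud before concatenation.

    Returns (merged cloud, dict of per-view RegistrationResult).
    """
    if len(extrinsics) != 2:
        raise ValueError("expected extrinsics for (left, right)")
    target = estimate_normals(top, params.normal_k) if top.normals is None else top
    merged_pts = [top.points]
    results = {}
    for name, cloud, ext in (("left", left, extrinsics[0]), ("right", right, extrinsics[1])):
        coarse = coarse_align(cloud, ext)
        idx = overlap_region(coarse, target, fp)
        res = point_to_plane_icp(coarse.select(idx), target, params)
        res.overlap_indices = idx
        if not res.converged:
            log.warning("register_views: %s view ICP did not converge (rms=%.4g)", name, res.rms)
        fine = apply_transform(coarse, res.transform)
        merged_pts.append(fine.points)
        results[name] = res
    merged = PointCloud(np.vstack(merged_pts))
    log.info(
        "register_views: merged %d points (top %d, left %d, right %d)",
        len(merged), len(top), len(left), len(right),
    )
    return merged, results
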