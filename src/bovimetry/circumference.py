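"""Girth measurement from the merged body cloud.

The section plane is *posture-normalized*: its normal is the animal's own
spine direction (the aid→abdomen landmark vector from the top view), so a
yawed or obliquely standing animal yields the same transverse section as
a square stance. Points within a tolerance slab around the plane are
projected into plane coordinates (u toward +y, v upward), converted to a
polar profile ρ(θ) about an interior origin, repaired by an RBF support
vector regression (hyperparameters by random-search cross-validation),
fused across the bilateral symmetry axis, and the unobserved ventral arc
closed by a tangent-continuous cubic Bézier segment. The girth is the
polyline length of the assembled closed curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, Delaunay
from scipy.stats import loguniform
from sklearn.model_selection import KFold, RandomizedSearchCV
from sklearn.svm import SVR

from .geometry import PointCloud
from .metrics import maep as _maep
from .metrics import r_squared as _r2
from .metrics import smoothness as _smoothness

__all__ = [
    "SectionPlane",
    "CircumferenceParams",
    "GirthProfile",
    "section_plane",
    "section_origin",
    "slice_and_project",
    "to_polar",
    "from_polar",
    "fit_profile_svr",
    "split_and_fuse",
    "cubic_bezier",
    "bezier_bridge",
    "measure_circumference",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SectionPlane:
    """Transverse section plane through a reference landmark.

    ``normal`` is the unit spine direction; ``u``/``v`` span the plane
    with u toward +y (left-camera side) and v pointing up (toward −z), so
    the back sits at the top of the 2D chart. ``plane_angles_deg`` are the
    diagnostic angles of the normal to the yOz, xOz and xOy planes.
    """

    reference: np.ndarray
    normal: np.ndarray
    u: np.ndarray
    v: np.ndarray
    tau: float

    @property
    def plane_angles_deg(self) -> Tuple[float, float, float]:
        n = self.normal
        return tuple(float(np.degrees(np.arcsin(min(abs(c), 1.0)))) for c in n)


@dataclass(frozen=True)
class CircumferenceParams:
    """Tunables of the girth chain.

    tau : slab half-thickness, metres. The default (4 cm) keeps the slab
        wider than a railing bar, so a bar crossing the section never
        blanks an entire view's contribution — covering occluded
        circumference data is what the tolerance range is for.
    gap_min : data gaps wider than this many degrees are left to the
        Bézier bridge instead of being extrapolated by the SVR.
    svr_iters / cv_folds : random-search budget of the SVR fit.
    search_cap / fit_cap : point subsample ceilings for the CV search and
        the final fit (SVR cost grows superlinearly with n).
    ground_band / ground_gap : a band of points within ``ground_band`` of
        the lowest v is dropped as ground return when it is separated
        from the rest by more than ``ground_gap`` metres.
    """

    tau: float = 0.04
    gap_min: float = 15.0
    svr_iters: int = 40
    cv_folds: int = 5
    search_cap: int = 250
    fit_cap: int = 800
    ground_band: float = 0.05
    ground_gap: float = 0.10
    min_section_points: int = 50


@dataclass
class GirthProfile:
    """All intermediate products of one girth measurement."""

    plane: SectionPlane
    section2d: np.ndarray  # (m, 2) plane coordinates
    origin: np.ndarray  # polar origin (x0, y0)
    theta: np.ndarray  # data polar angles, degrees
    rho: np.ndarray  # data radii, metres
    grid_theta: np.ndarray  # supported fitted grid, degrees
    grid_rho: np.ndarray
    fused_theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    fused_rho: np.ndarray = field(default_factory=lambda: np.empty(0))
    kept_theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    kept_rho: np.ndarray = field(default_factory=lambda: np.empty(0))
    bridge: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    perimeter: float = 0.0
    diagnostics: Dict[str, float] = field(default_factory=dict)


def section_plane(ref_kp, aid_kp, abdomen_kp, tau: float = 0.04) -> SectionPlane:
    """Posture-normalized plane through ``ref_kp`` normal to aid→abdomen.

    Valid even when the reference landmark was projected onto a railing:
    railing projections lie on the same transverse plane as the ideal
    landmark, which is all the construction needs.
    """
    ref = np.asarray(ref_kp, dtype=float).reshape(3)
    aid = np.asarray(aid_kp, dtype=float).reshape(3)
    abdomen = np.asarray(abdomen_kp, dtype=float).reshape(3)
    spine = abdomen - aid
    norm = np.linalg.norm(spine)
    if norm < 1e-3:
        raise ValueError("degenerate spine direction: aid and abdomen landmarks coincide")
    n = spine / norm
    # Gram-Schmidt the chart axes: v up (toward -z), u lateral (toward +y)
    v0 = np.array([0.0, 0.0, -1.0])
    v = v0 - (v0 @ n) * n
    if np.linalg.norm(v) < 1e-6:
        raise ValueError("spine direction is vertical; section plane undefined")
    v /= np.linalg.norm(v)
    u0 = np.array([0.0, 1.0, 0.0])
    u = u0 - (u0 @ n) * n - (u0 @ v) * v
    if np.linalg.norm(u) < 1e-6:
        raise ValueError("spine direction is lateral; section plane undefined")
    u /= np.linalg.norm(u)
    if tau <= 0:
        raise ValueError("tolerance tau must be positive")
    return SectionPlane(ref, n, u, v, tau)


def slice_and_project(cloud: PointCloud, plane: SectionPlane,
                      params: CircumferenceParams = CircumferenceParams()) -> np.ndarray:
    """Project the tolerance slab onto the plane, dropping ground returns."""
    rel = cloud.points - plane.reference
    dist = rel @ plane.normal
    mask = np.abs(dist) <= plane.tau
    sel = rel[mask]
    if len(sel) == 0:
        raise ValueError("insufficient section support: empty tolerance slab")
    uv = np.column_stack([sel @ plane.u, sel @ plane.v])
    # ground exclusion: a detached band at the very bottom of the chart
    vcoord = uv[:, 1]
    band = vcoord <= vcoord.min() + params.ground_band
    rest = vcoord[~band]
    if rest.size and rest.min() - vcoord[band].max() > params.ground_gap:
        uv = uv[~band]
        log.debug("slice_and_project: dropped %d ground-return points", int(band.sum()))
    if len(uv) < params.min_section_points:
        raise ValueError(
            f"insufficient section support: {len(uv)} points "
            f"(need {params.min_section_points})"
        )
    return uv


def section_origin(section2d: np.ndarray) -> np.ndarray:
    """Polar origin for a girth section: robust mid-range of each axis.

    The centroid is a poor origin here: point density differs strongly
    between view overlaps and the ventral gap, dragging the centroid off
    the animal's bilateral symmetry axis — and the curve fusion mirrors
    about the vertical through the origin, so the origin must sit on that
    axis. The mid-range of the lateral coordinate (between the flank
    extremes) is density-free and lands on it; 0.5 % quantiles guard
    against residual stray points. Falls back to the Chebyshev centre of
    the hull if the mid-range point is not interior.
    """
    lo = np.percentile(section2d, 0.5, axis=0)
    hi = np.percentile(section2d, 99.5, axis=0)
    origin = (lo + hi) / 2.0
    if not _origin_inside_hull(section2d, origin):
        origin = _chebyshev_center(section2d)
    return origin


def _origin_inside_hull(section2d: np.ndarray, origin: np.ndarray) -> bool:
    try:
        return Delaunay(section2d).find_simplex(origin[None, :])[0] >= 0
    except Exception:
        return False


def _chebyshev_center(section2d: np.ndarray) -> np.ndarray:
    """Center of the largest circle inscribed in the convex hull."""
    hull = ConvexHull(section2d)
    A = hull.equations[:, :2]
    b = -hull.equations[:, 2]
    norms = np.linalg.norm(A, axis=1)
    res = linprog(
        c=[0.0, 0.0, -1.0],
        A_ub=np.column_stack([A, norms]),
        b_ub=b,
        bounds=[(None, None), (None, None), (0, None)],
    )
    if not res.success:
        raise ValueError("could not find an interior polar origin")
    return res.x[:2]


def to_polar(section2d: np.ndarray, origin) -> Tuple[np.ndarray, np.ndarray]:
    """Polar profile about ``origin``: θ in degrees with +x mapping to 180°.

    θ = deg(atan2(y−y0, x−x0) + π) mod 360, ρ = Euclidean distance. The
    origin must lie strictly inside the section's convex hull, otherwise
    the profile is not single-valued in θ.
    """
    pts = np.asarray(section2d, dtype=float).reshape(-1, 2)
    origin = np.asarray(origin, dtype=float).reshape(2)
    if not _origin_inside_hull(pts, origin):
        raise ValueError("polar origin lies outside the section's convex hull")
    d = pts - origin
    theta = np.degrees(np.arctan2(d[:, 1], d[:, 0]) + np.pi) % 360.0
    rho = np.linalg.norm(d, axis=1)
    return theta, rho


def from_polar(theta: np.ndarray, rho: np.ndarray, origin) -> np.ndarray:
    """Inverse polar map (exact inverse of :func:`to_polar`)."""
    origin = np.asarray(origin, dtype=float).reshape(2)
    phi = np.radians(np.asarray(theta, dtype=float)) - np.pi
    return origin + np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])


def _supported_grid(theta: np.ndarray, gap_min: float, step: float = 1.0) -> np.ndarray:
    """Integer-degree grid restricted to arcs with data support.

    Circular gaps between consecutive data angles wider than ``gap_min``
    are excluded (they belong to the bridge stage).
    """
    ts = np.sort(np.unique(theta))
    grid = np.arange(0.0, 360.0, step)
    if len(ts) < 2:
        return grid
    gaps = np.diff(np.append(ts, ts[0] + 360.0))
    keep = np.ones(len(grid), dtype=bool)
    for i, g in enumerate(gaps):
        if g > gap_min:
            lo, hi = ts[i], ts[i] + g  # may exceed 360 on wrap
            inside = ((grid - lo) % 360.0) < (g - 1e-9)
            inside &= ((grid - lo) % 360.0) > 1e-9
            keep &= ~inside
    return grid[keep]


@dataclass
class FittedProfile:
    grid_theta: np.ndarray
    grid_rho: np.ndarray
    model: SVR
    best_params: Dict[str, float]

    def predict(self, theta) -> np.ndarray:
        # the regression feature is theta in radians: on that ~unit scale
        # the gamma search decades correspond to kernel widths between
        # ~13 deg and beyond a full turn, so no hyperparameter draw can
        # oscillate below the angular sampling scale
        x = np.radians(np.asarray(theta, dtype=float)).reshape(-1, 1)
        return self.model.predict(x)


def fit_profile_svr(
    theta: np.ndarray,
    rho: np.ndarray,
    seed: int,
    params: CircumferenceParams = CircumferenceParams(),
) -> FittedProfile:
    """RBF-SVR fit of ρ on θ with random-search cross-validation.

    The data are augmented with ±60° wrap-around copies so the regression
    is continuous across the 0/360 seam. The search minimizes CV mean
    squared error over C ∈ log-U[1e−1, 1e3], γ ∈ log-U[1e−3, 10],
    ε ∈ log-U[1e−4, 1e−2] m. Deterministic given ``seed``.
    """
    theta = np.asarray(theta, dtype=float).reshape(-1)
    rho = np.asarray(rho, dtype=float).reshape(-1)
    if theta.size < 50:
        raise ValueError("need at least 50 polar points for a stable profile fit")
    if np.ptp(rho) < 1e-12:
        # degenerate but well-defined: a perfect circle needs no search
        grid = _supported_grid(theta, params.gap_min)
        model = SVR(kernel="rbf", C=1.0, gamma=1e-3, epsilon=1e-4)
        model.fit(np.radians(theta).reshape(-1, 1), rho)
        return FittedProfile(grid, np.full(len(grid), rho[0]), model, {})

    rng = np.random.default_rng(seed)
    lo = theta < 60.0
    hi = theta > 300.0
    t_aug = np.concatenate([theta, theta[lo] + 360.0, theta[hi] - 360.0])
    r_aug = np.concatenate([rho, rho[lo], rho[hi]])

    if t_aug.size > params.search_cap:
        pick = rng.choice(t_aug.size, params.search_cap, replace=False)
    else:
        pick = np.arange(t_aug.size)
    X_search = np.radians(t_aug[pick]).reshape(-1, 1)
    y_search = r_aug[pick]

    # bound the SMO iteration count: pathological (huge-C) draws otherwise
    # dominate the search wall time; a capped, under-converged fit simply
    # scores badly and loses the CV selection
    search = RandomizedSearchCV(
        SVR(kernel="rbf", cache_size=200, max_iter=100_000),
        param_distributions={
            "C": loguniform(1e-1, 1e3),
            "gamma": loguniform(1e-3, 10.0),
            "epsilon": loguniform(1e-4, 1e-2),
        },
        n_iter=params.svr_iters,
        cv=KFold(params.cv_folds, shuffle=True, random_state=int(seed) % (2**31)),
        scoring="neg_mean_squared_error",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    with np.errstate(all="ignore"):
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            search.fit(X_search, y_search)
    best = search.best_params_

    if t_aug.size > params.fit_cap:
        pick = rng.choice(t_aug.size, params.fit_cap, replace=False)
        X_fit, y_fit = np.radians(t_aug[pick]).reshape(-1, 1), r_aug[pick]
    else:
        X_fit, y_fit = np.radians(t_aug).reshape(-1, 1), r_aug
    model = SVR(kernel="rbf", cache_size=200, max_iter=2_000_000, **best)
    model.fit(X_fit, y_fit)

    grid = _supported_grid(theta, params.gap_min)
    profile = FittedProfile(grid, np.empty(0), model, best)
    profile.grid_rho = profile.predict(grid)
    return profile


def _order_curve(grid_theta: np.ndarray, grid_rho: np.ndarray):
    """Order the fitted grid along the curve, starting after the widest gap."""
    order = np.argsort(grid_theta)
    ts, rs = grid_theta[order], grid_rho[order]
    gaps = np.diff(np.append(ts, ts[0] + 360.0))
    k = int(np.argmax(gaps))
    if gaps[k] <= 1.5:  # full coverage: start at the lowest point of the curve
        phi = np.radians(ts) - np.pi
        k = int(np.argmin(rs * np.sin(phi)))
    start = (k + 1) % len(ts)
    idx = np.arange(len(ts))
    idx = np.concatenate([idx[start:], idx[:start]])
    # unwrap θ so it ascends monotonically along the curve
    t_seq = ts[idx].copy()
    wrap = np.where(np.diff(t_seq) < 0)[0]
    if wrap.size:
        t_seq[wrap[0] + 1:] += 360.0
    return t_seq, rs[idx]


def split_and_fuse(grid_theta: np.ndarray, grid_rho: np.ndarray, origin):
    """Average the two lateral halves of the fitted profile.

    The curve is split at its dorsal apex (the topmost point of the
    back-transformed Cartesian curve) into the left-view branch (the
    shaded, more distorted side) and the right-view branch. The right
    branch is mirrored about the vertical axis through the polar origin
    (bilateral symmetry of the trunk), resampled onto the left branch's
    θ-grid and averaged with it pointwise. Returns
    (fused_theta, fused_rho, kept_theta, kept_rho) with θ in curve order.
    """
    origin = np.asarray(origin, dtype=float).reshape(2)
    t_seq, r_seq = _order_curve(np.asarray(grid_theta, float), np.asarray(grid_rho, float))
    xy = from_polar(t_seq % 360.0, r_seq, origin)
    apex = int(np.argmax(xy[:, 1]))
    if apex == 0 or apex == len(t_seq) - 1:
        raise ValueError("cannot fuse one-sided profile")
    b1_t, b1_r = t_seq[: apex + 1], r_seq[: apex + 1]
    b2_t, b2_r = t_seq[apex:], r_seq[apex:]
    # identify the left-view branch (+u side) as the one to be repaired
    b1_u = from_polar(b1_t % 360.0, b1_r, origin)[:, 0].mean()
    b2_u = from_polar(b2_t % 360.0, b2_r, origin)[:, 0].mean()
    if (b1_u - origin[0]) * (b2_u - origin[0]) > 0:
        raise ValueError("cannot fuse one-sided profile")
    if b1_u < b2_u:
        b1_t, b1_r, b2_t, b2_r = b2_t, b2_r, b1_t, b1_r
        swapped = True
    else:
        swapped = False

    # mirror the kept branch about the vertical axis: θ -> (540 − θ) mod 360
    m_t = (540.0 - (b2_t % 360.0)) % 360.0
    m_order = np.argsort(m_t)
    m_t, m_r = m_t[m_order], b2_r[m_order]
    b1_mod = b1_t % 360.0
    in_range = (b1_mod >= m_t[0] - 1e-9) & (b1_mod <= m_t[-1] + 1e-9)
    mirror_r = np.interp(b1_mod[in_range], m_t, m_r)
    fused_r = b1_r.copy()
    fused_r[in_range] = 0.5 * (b1_r[in_range] + mirror_r)

    if swapped:
        # keep output in curve order: fused branch then kept branch
        return b1_t, fused_r, b2_t, b2_r
    return b1_t, fused_r, b2_t, b2_r


def cubic_bezier(p0, pc1, pc2, p1, t: np.ndarray) -> np.ndarray:
    """B(t) = (1−t)³P0 + 3(1−t)²t·Pc1 + 3(1−t)t²·Pc2 + t³P1."""
    p0, pc1, pc2, p1 = (np.asarray(p, dtype=float) for p in (p0, pc1, pc2, p1))
    t = np.asarray(t, dtype=float).reshape(-1, 1)
    return ((1 - t) ** 3) * p0 + 3 * ((1 - t) ** 2) * t * pc1 + 3 * (1 - t) * t**2 * pc2 + t**3 * p1


def bezier_bridge(p0, tangent0, p1, tangent1, n_samples: int = 64) -> np.ndarray:
    """Tangent-continuous cubic bridge from P0 to P1.

    Control points sit a third of the chord along each end tangent
    (Hermite-equivalent placement): Pc1 = P0 + (d/3)·t̂0,
    Pc2 = P1 − (d/3)·t̂1, d = |P1 − P0|, which makes the bridge's end
    derivatives match the curve directions at both ends.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = np.linalg.norm(p1 - p0)
    if d == 0:
        raise ValueError("zero-length chord between bridge endpoints")
    t0 = np.asarray(tangent0, dtype=float)
    t1 = np.asarray(tangent1, dtype=float)
    if not (np.all(np.isfinite(t0)) and np.all(np.isfinite(t1))):
        raise ValueError("bridge tangents must be finite")
    t0 = t0 / np.linalg.norm(t0)
    t1 = t1 / np.linalg.norm(t1)
    pc1 = p0 + (d / 3.0) * t0
    pc2 = p1 - (d / 3.0) * t1
    return cubic_bezier(p0, pc1, pc2, p1, np.linspace(0.0, 1.0, n_samples))


def _polyline_length(pts: np.ndarray) -> float:
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def measure_circumference(
    cloud: PointCloud,
    keypoints3d: Dict[Tuple[str, str], np.ndarray],
    which: str,
    params: CircumferenceParams = CircumferenceParams(),
    seed: int = 0,
) -> Tuple[float, GirthProfile]:
    """Abdominal or chest girth of the merged body cloud, metres.

    ``keypoints3d`` maps (view, name) to reference-frame positions; needed
    are top aid + abdomen (spine direction) and a side abdomen (for
    ``which='abdominal'``) or side chest (``which='chest'``) reference.
    The right view is preferred as reference (better lit side).
    """
    if which not in ("abdominal", "chest"):
        raise ValueError("which must be 'abdominal' or 'chest'")
    ref_name = "abdomen" if which == "abdominal" else "chest"

    def _get(stage, *keys):
        for key in keys:
            if key in keypoints3d and keypoints3d[key] is not None:
                return keypoints3d[key]
        raise ValueError(f"{stage}: missing landmark(s) {keys}")

    aid = _get("section_plane", ("top", "aid"))
    abdomen_top = _get("section_plane", ("top", "abdomen"))
    ref = _get("section_plane", ("right", ref_name), ("left", ref_name))

    def _stage(name, fn, *a, **kw):
        try:
            return fn(*a, **kw)
        except ValueError as exc:
            raise ValueError(f"{which} girth, stage {name}: {exc}") from exc

    plane = _stage("section_plane", section_plane, ref, aid, abdomen_top, params.tau)
    section = _stage("slice_and_project", slice_and_project, cloud, plane, params)
    origin = _stage("section_origin", section_origin, section)
    theta, rho = _stage("to_polar", to_polar, section, origin)
    fit = _stage("fit_profile_svr", fit_profile_svr, theta, rho, seed, params)
    fused_t, fused_r, kept_t, kept_r = _stage(
        "split_and_fuse", split_and_fuse, fit.grid_theta, fit.grid_rho, origin
    )

    fused_xy = from_polar(fused_t % 360.0, fused_r, origin)
    kept_xy = from_polar(kept_t % 360.0, kept_r, origin)
    # curve runs: fused branch (gap edge -> apex), kept branch (apex -> gap
    # edge); the bridge closes the ventral gap from the kept branch's end
    # back to the fused branch's start
    p1, p0 = fused_xy[0], kept_xy[-1]
    gap = np.linalg.norm(p1 - p0)
    if gap > 1e-9:
        t0 = kept_xy[-1] - kept_xy[-2]
        t1 = fused_xy[1] - fused_xy[0]
        bridge = _stage("bezier_bridge", bezier_bridge, p0, t0, p1, t1)
    else:
        bridge = np.empty((0, 2))

    perimeter = (
        _polyline_length(fused_xy)
        + _polyline_length(kept_xy)
        + _polyline_length(bridge)
        + float(np.linalg.norm(kept_xy[0] - fused_xy[-1]))  # apex junction
    )
    if bridge.size == 0:
        perimeter += gap  # fully observed profile closes directly

    rho_hat = fit.predict(theta)
    # pre-fusion smoothness of the repaired branch, on the same θ-grid
    gt, gr = _sorted(fit.grid_theta, fit.grid_rho)
    pre = _smoothness(np.interp(fused_t % 360.0, gt, gr))
    profile = GirthProfile(
        plane=plane,
        section2d=section,
        origin=origin,
        theta=theta,
        rho=rho,
        grid_theta=fit.grid_theta,
        grid_rho=fit.grid_rho,
        fused_theta=fused_t,
        fused_rho=fused_r,
        kept_theta=kept_t,
        kept_rho=kept_r,
        bridge=bridge,
        perimeter=perimeter,
        diagnostics={
            "r_squared": _r2(rho, rho_hat),
            "maep_pct": _maep(rho, rho_hat),
            "smoothness_pre_fusion": pre,
            "smoothness_post_fusion": _smoothness(fused_r),
            "n_section_points": float(len(section)),
            "svr_C": float(fit.best_params.get("C", np.nan)),
            "svr_gamma": float(fit.best_params.get("gamma", np.nan)),
            "svr_epsilon": float(fit.best_params.get("epsilon", np.nan)),
        },
    )
    return perimeter, profile


def _sorted(t: np.ndarray, r: np.ndarray):
    order = np.argsort(t)
    return t[order], r[order]
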