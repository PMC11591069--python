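"""Synthetic cattle-like bodies and virtual three-view captures.

The body is a swept elliptic cross-section along a straight (optionally
flexed) spine — deliberately simple so that every measurement has a
closed-form truth: girths via Ramanujan's elliptic-perimeter
approximation, lengths from the analytic landmark positions, height from
the dorsal profile. Captures emulate the physical rig (top camera 2.48 m
above ground, side cameras beyond the channel fence) with z-buffer
visibility, vertical railing occlusion stripes in the side views, an
unobserved ventral arc, illumination holes, Gaussian depth noise along
the view rays, clustered outlier blobs and a ground plane.

What this generator does NOT emulate: legs, head and neck geometry, fur
and specular artifacts, non-rigid motion between views, and the learned
keypoint detector (landmark pixels are exact projections, optionally
occluded by railing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .geometry import PointCloud, RigidTransform, compose
from .io import write_ply
from .keypoints import CameraModel, Keypoint, save_keypoints_csv

__all__ = [
    "BodyParams",
    "CaptureParams",
    "GroundTruth",
    "SyntheticBody",
    "Scene",
    "ramanujan_perimeter",
    "generate_body",
    "make_cameras",
    "virtual_capture",
    "make_scene",
    "write_scene",
    "random_body_params",
    "DEGRADED_CAPTURE",
    "CLEAN_CAPTURE",
]

H0_DEFAULT = 2.48  # top camera height above ground, metres

# landmark stations as fractions of body length
STATIONS = {"neck": 0.05, "back": 0.35, "abdomen": 0.50, "aid": 0.60, "buttocks": 0.95}
CHEST_FRACTION = 0.30
FORELEG_FRACTION = 0.15


def ramanujan_perimeter(a: float, b: float) -> float:
    """Ramanujan's approximation of the ellipse perimeter."""
    return float(np.pi * (3 * (a + b) - np.sqrt((3 * a + b) * (a + 3 * b))))


@dataclass(frozen=True)
class BodyParams:
    """Shape and pose of a synthetic trunk.

    ``axis_height`` is the spine-axis clearance above ground. Half-axes
    taper along the body with elliptical profiles peaking at
    ``a_center``/``b_center`` (fractions of length); ``taper=False``
    gives a constant-section elliptic cylinder (the analytic oracle
    body). ``yaw_deg``/``pitch_deg`` rigidly pose the body; ``flex_amp``
    bows the spine vertically.
    """

    length: float = 2.0
    axis_height: float = 0.85
    a_max: float = 0.35  # lateral half-axis at the abdomen
    b_max: float = 0.30  # vertical half-axis at the back station
    a_center: float = 0.50
    a_halfspan: float = 0.75
    b_center: float = 0.35
    b_halfspan: float = 0.80
    taper: bool = True
    yaw_deg: float = 0.0
    pitch_deg: float = 0.0
    flex_amp: float = 0.0

    def __post_init__(self) -> None:
        if min(self.length, self.axis_height, self.a_max, self.b_max) <= 0:
            raise ValueError("body dimensions must be positive")

    def half_axes(self, f) -> Tuple[np.ndarray, np.ndarray]:
        """(a, b) at station fraction(s) f ∈ [0, 1]."""
        f = np.asarray(f, dtype=float)
        if not self.taper:
            return self.a_max * np.ones_like(f), self.b_max * np.ones_like(f)
        wa = np.sqrt(np.clip(1.0 - ((f - self.a_center) / self.a_halfspan) ** 2, 0.0, None))
        wb = np.sqrt(np.clip(1.0 - ((f - self.b_center) / self.b_halfspan) ** 2, 0.0, None))
        return self.a_max * wa, self.b_max * wb


@dataclass(frozen=True)
class CaptureParams:
    """Degradation profile of a virtual capture; σ=0 and zeros = ideal."""

    noise_sigma: float = 0.0
    railing_spacing: float = 0.25
    railing_width: float = 0.0  # 0 disables railing stripes
    railing_phase: Optional[float] = None  # bar offset along x; None = drawn per scene
    belly_gap_deg: float = 0.0  # unobserved ventral arc (side views)
    n_outlier_blobs: int = 0
    blob_points: int = 50
    blob_radius: float = 0.05
    n_holes: int = 0
    hole_radius: float = 0.04
    ground: bool = True
    ground_points: int = 3000
    ground_extent: Tuple[float, float] = (3.2, 3.2)
    zbuffer_bin_px: int = 6
    extrinsic_rot_err_deg: float = 0.0
    extrinsic_trans_err_m: float = 0.0
    fence_y: float = 0.45  # railing plane distance from the channel centre

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


CLEAN_CAPTURE = CaptureParams()
# channel degradation profile: railing stripes, unobserved belly arc, 5 mm
# surface noise, outlier blobs, illumination holes, miscalibrated coarse
# extrinsics for ICP to correct
DEGRADED_CAPTURE = CaptureParams(
    noise_sigma=0.005,
    railing_width=0.05,
    railing_spacing=0.25,
    belly_gap_deg=60.0,
    n_outlier_blobs=3,
    n_holes=4,
    extrinsic_rot_err_deg=3.0,
    extrinsic_trans_err_m=0.05,
)


@dataclass
class GroundTruth:
    height: float
    straight_length: float
    slant_left: float
    slant_right: float
    slant_length: float
    girth_abdominal: float
    girth_chest: float
    keypoints3d: Dict[Tuple[str, str], np.ndarray] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, float]:
        return {
            "height": self.height,
            "straight_length": self.straight_length,
            "slant_length": self.slant_length,
            "girth_abdominal": self.girth_abdominal,
            "girth_chest": self.girth_chest,
        }


@dataclass
class SyntheticBody:
    cloud: PointCloud  # posed surface samples, reference frame
    phi: np.ndarray  # cross-section angle of each sample (0 = +y, π/2 = up)
    fraction: np.ndarray  # station fraction of each sample
    truth: GroundTruth
    params: BodyParams
    pose: RigidTransform


def _pose_transform(params: BodyParams, center: np.ndarray) -> RigidTransform:
    yaw = RigidTransform.from_axis_angle((0, 0, 1), np.radians(params.yaw_deg))
    pitch = RigidTransform.from_axis_angle((0, 1, 0), np.radians(params.pitch_deg))
    R = compose(yaw, pitch)
    # rotate about the body centre, not the camera origin
    t = center - R.rotation @ center
    return RigidTransform(R.rotation, t)


def _spine_point(params: BodyParams, f: np.ndarray, ground_z: float) -> np.ndarray:
    f = np.atleast_1d(np.asarray(f, dtype=float))
    x = (f - 0.5) * params.length
    z = ground_z - params.axis_height - params.flex_amp * np.sin(np.pi * f)
    return np.column_stack([x, np.zeros_like(x), z])


def _surface_point(params: BodyParams, f: np.ndarray, phi: np.ndarray, ground_z: float) -> np.ndarray:
    a, b = params.half_axes(f)
    c = _spine_point(params, f, ground_z)
    offset = np.column_stack(
        [np.zeros_like(a), a * np.cos(phi), -b * np.sin(phi)]  # up = -z
    )
    return c + offset


def generate_body(
    params: BodyParams = BodyParams(),
    resolution: int = 40000,
    ground_z: float = H0_DEFAULT,
) -> SyntheticBody:
    """Sample the body surface and derive its analytic ground truth."""
    if resolution < 500:
        raise ValueError("resolution too coarse: need at least 500 surface points")
    n_s = max(int(np.sqrt(resolution * params.length / (2 * np.pi * params.a_max))), 10)
    n_phi = max(resolution // n_s, 8)
    f_grid = np.linspace(0.0, 1.0, n_s)
    phi_grid = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    F, PHI = np.meshgrid(f_grid, phi_grid, indexing="ij")
    F, PHI = F.ravel(), PHI.ravel()
    pts = _surface_point(params, F, PHI, ground_z)

    # landmarks (pre-pose)
    kp: Dict[Tuple[str, str], np.ndarray] = {}
    for name, f in STATIONS.items():
        kp[("top", name)] = _surface_point(params, np.array([f]), np.array([np.pi / 2]), ground_z)[0]
    for view, sign in (("left", 1.0), ("right", -1.0)):
        def lateral(f, psi):
            a, b = params.half_axes(np.array([f]))
            c = _spine_point(params, np.array([f]), ground_z)[0]
            return c + np.array([0.0, sign * a[0] * np.cos(psi), -b[0] * np.sin(psi)])

        kp[(view, "back")] = kp[("top", "back")]
        kp[(view, "abdomen")] = lateral(STATIONS["abdomen"], 0.0)
        kp[(view, "chest")] = lateral(CHEST_FRACTION, 0.0)
        kp[(view, "foreleg")] = lateral(FORELEG_FRACTION, -np.pi / 4)
        kp[(view, "buttocks")] = lateral(STATIONS["buttocks"], np.pi / 3)

    center = _spine_point(params, np.array([0.5]), ground_z)[0]
    pose = _pose_transform(params, center)
    pts = pose.apply_points(pts)
    kp = {k: pose.apply_points(v[None, :])[0] for k, v in kp.items()}

    # truths: lengths/girths are pose-invariant; height from the posed
    # dorsal midline (dense 1D profile, exact to sampling)
    f_dense = np.linspace(0.0, 1.0, 20001)
    dorsal = pose.apply_points(_surface_point(params, f_dense, np.full_like(f_dense, np.pi / 2), ground_z))
    height = float(np.max(np.abs(dorsal[:, 2] - ground_z)))
    top_pts = np.array([kp[("top", n)] for n in ("neck", "back", "abdomen", "aid", "buttocks")])
    straight = float(np.sum(np.linalg.norm(np.diff(top_pts, axis=0), axis=1)))
    slant_l = float(np.linalg.norm(kp[("left", "foreleg")] - kp[("left", "buttocks")]))
    slant_r = float(np.linalg.norm(kp[("right", "foreleg")] - kp[("right", "buttocks")]))
    a_abd, b_abd = params.half_axes(np.array([STATIONS["abdomen"]]))
    a_ch, b_ch = params.half_axes(np.array([CHEST_FRACTION]))
    truth = GroundTruth(
        height=height,
        straight_length=straight,
        slant_left=slant_l,
        slant_right=slant_r,
        slant_length=(slant_l + slant_r) / 2,
        girth_abdominal=ramanujan_perimeter(a_abd[0], b_abd[0]),
        girth_chest=ramanujan_perimeter(a_ch[0], b_ch[0]),
        keypoints3d=kp,
    )
    return SyntheticBody(PointCloud(pts), PHI % (2 * np.pi), F, truth, params, pose)


def make_cameras(
    ground_z: float = H0_DEFAULT,
    side_y: float = 1.6,  # fence at 0.45 m + tripod 1.15 m beyond it
    side_height: float = 1.15,  # tripod height ~ back height: near-horizontal rays
    fx: float = 1000.0,
    fy: float = 1000.0,
) -> Dict[str, CameraModel]:
    """The three-view rig in the reference (top-camera) frame."""
    intr = dict(fx=fx, fy=fy, cx=1104.0, cy=621.0, width=2208, height=1242)
    top = CameraModel(extrinsic=RigidTransform.identity(), **intr)
    z_side = ground_z - side_height
    # left camera at +y looking along -y; x_cam stays along +x, y_cam down
    R_left = np.column_stack([(1, 0, 0), (0, 0, 1), (0, -1, 0)]).astype(float)
    left = CameraModel(extrinsic=RigidTransform(R_left, (0.0, side_y, z_side)), **intr)
    R_right = np.column_stack([(-1, 0, 0), (0, 0, 1), (0, 1, 0)]).astype(float)
    right = CameraModel(extrinsic=RigidTransform(R_right, (0.0, -side_y, z_side)), **intr)
    return {"top": top, "left": left, "right": right}


def _railing_mask(x_ref: np.ndarray, cp: CaptureParams, phase: float = 0.0) -> np.ndarray:
    """True where a vertical railing bar blocks the line of sight."""
    if cp.railing_width <= 0:
        return np.zeros(len(x_ref), dtype=bool)
    return ((x_ref - phase) % cp.railing_spacing) < cp.railing_width


def virtual_capture(
    body: SyntheticBody,
    cam: CameraModel,
    cp: CaptureParams,
    view: str,
    rng: np.random.Generator,
    ground_z: float = H0_DEFAULT,
    railing_phase: float = 0.0,
) -> PointCloud:
    """One view's point cloud in that camera's own frame.

    Visibility by z-buffer at a binned pixel grid; side views addtionally
    lose railing stripes and the ventral arc. Noise is applied along each
    view ray; outlier blobs and ground returns are appended afterwards.
    """
    pts_ref = body.cloud.points
    keep = np.ones(len(pts_ref), dtype=bool)
    if view in ("left", "right"):
        if cp.belly_gap_deg > 0:
            # φ = 3π/2 is straight down; the gap is the arc around it
            half = np.radians(cp.belly_gap_deg) / 2
            down = 1.5 * np.pi
            keep &= np.abs((body.phi - down + np.pi) % (2 * np.pi) - np.pi) > half
        keep &= ~_railing_mask(pts_ref[:, 0], cp, railing_phase)
    pts_ref = pts_ref[keep]

    inv = cam.extrinsic.inverse()
    p_cam = inv.apply_points(pts_ref)
    vis = p_cam[:, 2] > 0.05
    p_cam = p_cam[vis]
    if len(p_cam) == 0:
        raise ValueError("empty capture: camera faces away from the body")
    u = cam.fx * p_cam[:, 0] / p_cam[:, 2] + cam.cx
    v = cam.fy * p_cam[:, 1] / p_cam[:, 2] + cam.cy
    inside = (u >= 0) & (u < cam.width) & (v >= 0) & (v < cam.height)
    p_cam, u, v = p_cam[inside], u[inside], v[inside]
    if len(p_cam) == 0:
        raise ValueError("empty capture: body projects outside the image")

    # z-buffer on a binned pixel grid: nearest point per bin survives
    nbx = cam.width // cp.zbuffer_bin_px + 1
    flat = (u // cp.zbuffer_bin_px).astype(int) * (cam.height // cp.zbuffer_bin_px + 2) + (
        v // cp.zbuffer_bin_px
    ).astype(int)
    order = np.lexsort((p_cam[:, 2], flat))
    first = np.ones(len(order), dtype=bool)
    first[1:] = np.diff(flat[order]) != 0
    p_cam = p_cam[order[first]]

    if cp.n_holes > 0 and len(p_cam) > cp.n_holes:
        seeds = rng.choice(len(p_cam), cp.n_holes, replace=False)
        tree = cKDTree(p_cam)
        drop = set()
        for s in seeds:
            drop.update(tree.query_ball_point(p_cam[s], cp.hole_radius))
        keep_idx = np.setdiff1d(np.arange(len(p_cam)), np.fromiter(drop, dtype=int))
        p_cam = p_cam[keep_idx]

    if cp.noise_sigma > 0:
        rays = p_cam / np.linalg.norm(p_cam, axis=1, keepdims=True)
        p_cam = p_cam + rays * rng.normal(0.0, cp.noise_sigma, len(p_cam))[:, None]

    extras = [p_cam]
    if cp.n_outlier_blobs > 0:
        # detached clumps beside the body (glare/flying-pixel noise), never
        # touching the surface — stray returns hug open space, and a clump
        # welded onto the body would be a different failure mode entirely
        tree = cKDTree(p_cam)
        centroid = p_cam.mean(axis=0)
        placed = 0
        for _ in range(cp.n_outlier_blobs * 20):
            if placed == cp.n_outlier_blobs:
                break
            offset = rng.uniform(-1.0, 1.0, 3)
            offset *= (0.5 + 0.7 * rng.random()) / max(np.linalg.norm(offset), 1e-9)
            centre = centroid + offset
            if tree.query(centre[None, :])[0][0] < cp.blob_radius + 0.15:
                continue
            extras.append(centre + rng.normal(0.0, cp.blob_radius, (cp.blob_points, 3)))
            placed += 1
    if cp.ground:
        gx = rng.uniform(-cp.ground_extent[0] / 2, cp.ground_extent[0] / 2, cp.ground_points)
        gy = rng.uniform(-cp.ground_extent[1] / 2, cp.ground_extent[1] / 2, cp.ground_points)
        g_ref = np.column_stack([gx, gy, np.full_like(gx, ground_z)])
        if view in ("left", "right"):
            g_ref = g_ref[~_railing_mask(g_ref[:, 0], cp, railing_phase)]
        g_cam = inv.apply_points(g_ref)
        ok = g_cam[:, 2] > 0.05
        gu = cam.fx * g_cam[ok, 0] / g_cam[ok, 2] + cam.cx
        gv = cam.fy * g_cam[ok, 1] / g_cam[ok, 2] + cam.cy
        g_cam = g_cam[ok][(gu >= 0) & (gu < cam.width) & (gv >= 0) & (gv < cam.height)]
        if cp.noise_sigma > 0 and len(g_cam):
            rays = g_cam / np.linalg.norm(g_cam, axis=1, keepdims=True)
            g_cam = g_cam + rays * rng.normal(0.0, cp.noise_sigma, len(g_cam))[:, None]
        extras.append(g_cam)
    return PointCloud(np.vstack([e for e in extras if len(e)]))


@dataclass
class Scene:
    """One synthetic capture session: clouds, cameras, landmarks, truth."""

    views: Dict[str, PointCloud]  # camera-frame clouds
    cameras: Dict[str, CameraModel]  # with NOMINAL (possibly miscalibrated) extrinsics
    keypoints: List[Keypoint]  # 2D landmarks with depth + occlusion flags
    truth: GroundTruth
    ground_z: float
    body: Optional[SyntheticBody] = None


def _perturbed(T: RigidTransform, rot_deg: float, trans: float, rng: np.random.Generator) -> RigidTransform:
    if rot_deg == 0 and trans == 0:
        return T
    axis = rng.normal(size=3)
    err = RigidTransform.from_axis_angle(
        axis, np.radians(rot_deg), rng.normal(size=3) * trans / np.sqrt(3)
    )
    return compose(err, T)


def make_scene(
    body_params: BodyParams = BodyParams(),
    capture: CaptureParams = CLEAN_CAPTURE,
    seed: int = 0,
    resolution: int = 40000,
    ground_z: float = H0_DEFAULT,
) -> Scene:
    """Generate a full three-view capture with landmark files and truth."""
    ss = np.random.SeedSequence(seed)
    child = {name: np.random.default_rng(s) for name, s in
             zip(("top", "left", "right", "rig", "kp"), ss.spawn(5))}
    body = generate_body(body_params, resolution, ground_z)
    true_cams = make_cameras(ground_z)
    phase = capture.railing_phase
    if phase is None:
        # bar positions are arbitrary relative to where the animal stops
        phase = float(child["rig"].uniform(0.0, capture.railing_spacing))
    views = {
        name: virtual_capture(body, cam, capture, name, child[name], ground_z, phase)
        for name, cam in true_cams.items()
    }
    # the pipeline sees nominal extrinsics: top is the reference (exact by
    # construction), the side mounts carry calibration error
    nominal = {"top": true_cams["top"]}
    for name in ("left", "right"):
        cam = true_cams[name]
        ext = _perturbed(cam.extrinsic, capture.extrinsic_rot_err_deg,
                         capture.extrinsic_trans_err_m, child["rig"])
        nominal[name] = CameraModel(cam.fx, cam.fy, cam.cx, cam.cy, cam.width, cam.height, ext)

    kps: List[Keypoint] = []
    for (view, name), p_ref in body.truth.keypoints3d.items():
        cam = true_cams[view]
        p_cam = cam.extrinsic.inverse().apply_points(p_ref[None, :])[0]
        if p_cam[2] <= 0:
            continue
        px = cam.fx * p_cam[0] / p_cam[2] + cam.cx
        py = cam.fy * p_cam[1] / p_cam[2] + cam.cy
        if not (0 <= px < cam.width and 0 <= py < cam.height):
            continue
        depth = p_cam[2]
        occluded = False
        if view in ("left", "right") and capture.railing_width > 0:
            if _railing_mask(np.array([p_ref[0]]), capture, phase)[0]:
                # landmark pixel falls on a railing bar: the depth sensor
                # returns the bar, i.e. the same ray truncated at the fence
                occluded = True
                ray_ref = (p_ref - cam.extrinsic.translation)
                scale = (capture.fence_y * np.sign(cam.extrinsic.translation[1])
                         - cam.extrinsic.translation[1]) / ray_ref[1]
                depth = float(depth * scale)
        if capture.noise_sigma > 0:
            depth += float(child["kp"].normal(0.0, capture.noise_sigma))
        kps.append(Keypoint(name=name, view=view, pixel=(float(px), float(py)),
                            depth=float(depth), occluded=occluded))
    return Scene(views=views, cameras=nominal, keypoints=kps, truth=body.truth,
                 ground_z=ground_z, body=body)


def random_body_params(rng: np.random.Generator) -> BodyParams:
    """A plausible adult-cattle body with a random stance."""
    return BodyParams(
        length=float(rng.uniform(1.8, 2.3)),
        axis_height=float(rng.uniform(0.80, 0.95)),
        a_max=float(rng.uniform(0.30, 0.40)),
        b_max=float(rng.uniform(0.26, 0.34)),
        yaw_deg=float(rng.uniform(-15.0, 15.0)),
    )


def write_scene(scene: Scene, directory) -> None:
    """Persist a scene: per-view PLY, landmark CSV, truth + camera JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, cloud in scene.views.items():
        write_ply(cloud, directory / f"{name}.ply")
    save_keypoints_csv(scene.keypoints, directory / "keypoints.csv")
    (directory / "truth.json").write_text(json.dumps(scene.truth.as_dict(), indent=2))
    cams = {}
    for name, cam in scene.cameras.items():
        cams[name] = {
            "fx": cam.fx, "fy": cam.fy, "cx": cam.cx, "cy": cam.cy,
            "width": cam.width, "height": cam.height,
            "extrinsic": cam.extrinsic.matrix().tolist(),
        }
    (directory / "cameras.json").write_text(
        json.dumps({"ground_z": scene.ground_z, "cameras": cams}, indent=2)
    )
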