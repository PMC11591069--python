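"""Named anatomical landmarks and their 2D→3D mapping.

Landmark detection itself is upstream (a pose model on the RGB images);
this module ingests its output — named pixel coordinates with depth per
view — and back-projects each landmark through the pinhole model into the
reference frame.

Valid names per view:
  top:   neck, back, abdomen, aid, buttocks   (dorsal midline)
  sides: back, buttocks, foreleg, abdomen, chest
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from .geometry import RigidTransform

__all__ = [
    "CameraModel",
    "Keypoint",
    "VIEW_LANDMARKS",
    "backproject",
    "project",
    "load_keypoints",
    "save_keypoints_csv",
    "validate_keypoint_set",
    "sample_depth",
    "load_depth_map",
]

VIEW_LANDMARKS: Dict[str, tuple] = {
    "top": ("neck", "back", "abdomen", "aid", "buttocks"),
    "left": ("back", "buttocks", "foreleg", "abdomen", "chest"),
    "right": ("back", "buttocks", "foreleg", "abdomen", "chest"),
}

# Requirements per measurement: a list of groups, each group a list of
# alternatives, each alternative a tuple of (view, name) pairs that must all
# be present. Slant length needs buttocks AND foreleg from the same side;
# girths accept either side's reference landmark.
MEASUREMENT_REQUIREMENTS = {
    "straight_length": [[(("top", n),)] for n in VIEW_LANDMARKS["top"]],
    "height": [[(("top", "back"),), (("left", "back"),), (("right", "back"),)]],
    "slant_length": [
        [
            (("left", "buttocks"), ("left", "foreleg")),
            (("right", "buttocks"), ("right", "foreleg")),
        ]
    ],
    "abdominal_girth": [
        [(("top", "aid"),)],
        [(("top", "abdomen"),)],
        [(("left", "abdomen"),), (("right", "abdomen"),)],
    ],
    "chest_girth": [
        [(("top", "aid"),)],
        [(("top", "abdomen"),)],
        [(("left", "chest"),), (("right", "chest"),)],
    ],
}


@dataclass(frozen=True)
class CameraModel:
    """Pinhole intrinsics + camera-to-reference extrinsic."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = 2208
    height: int = 1242
    extrinsic: RigidTransform = field(default_factory=RigidTransform.identity)

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")


@dataclass
class Keypoint:
    name: str
    view: str
    pixel: tuple  # (x, y)
    depth: Optional[float] = None
    position3d: Optional[np.ndarray] = None
    occluded: bool = False

    def __post_init__(self) -> None:
        if self.view not in VIEW_LANDMARKS:
            raise ValueError(f"unknown view {self.view!r}; allowed: {sorted(VIEW_LANDMARKS)}")
        if self.name not in VIEW_LANDMARKS[self.view]:
            raise ValueError(
                f"unknown landmark {self.name!r} for view {self.view!r}; "
                f"allowed: {VIEW_LANDMARKS[self.view]}"
            )


def backproject(kp: Keypoint, cam: CameraModel, extrinsic: Optional[RigidTransform] = None) -> Keypoint:
    """Map a pixel+depth landmark into the reference frame.

    Camera-frame position is ((x−cx)·z/fx, (y−cy)·z/fy, z); the view's
    extrinsic (or an explicit corrected one, e.g. after fine registration)
    then carries it into the reference frame.
    """
    if kp.depth is None or kp.depth <= 0:
        raise ValueError("no depth at keypoint")
    x, y = kp.pixel
    z = kp.depth
    p_cam = np.array([(x - cam.cx) * z / cam.fx, (y - cam.cy) * z / cam.fy, z])
    T = cam.extrinsic if extrinsic is None else extrinsic
    kp.position3d = T.rotation @ p_cam + T.translation
    return kp


def project(point3d, cam: CameraModel) -> tuple:
    """Pinhole projection of a reference-frame point; returns (x, y, depth)."""
    p = cam.extrinsic.inverse().apply_points(np.asarray(point3d, dtype=float).reshape(1, 3))[0]
    if p[2] <= 0:
        raise ValueError("point is behind the camera")
    return (cam.fx * p[0] / p[2] + cam.cx, cam.fy * p[1] / p[2] + cam.cy, p[2])


def sample_depth(depth_map: np.ndarray, pixel, window: int = 5) -> float:
    """Median depth over a window around the pixel (speckle-resistant).

    ``depth_map`` is metres; non-positive entries are treated as missing.
    """
    h, w = depth_map.shape
    x, y = int(round(pixel[0])), int(round(pixel[1]))
    r = window // 2
    patch = depth_map[max(0, y - r): y + r + 1, max(0, x - r): x + r + 1]
    valid = patch[patch > 0]
    if valid.size == 0:
        raise ValueError("no depth at keypoint")
    return float(np.median(valid))


def load_depth_map(path) -> np.ndarray:
    """Read a depth image as a (h, w) float array in metres.

    Accepts PFM (single channel, metres) or 16-bit PNG (millimetres, the
    common sensor export). Use with :func:`sample_depth` to fill in
    landmark depths that the keypoint file omits.
    """
    path = Path(path)
    if path.suffix.lower() == ".pfm":
        with open(path, "rb") as fh:
            header = fh.readline().strip()
            if header not in (b"Pf", b"PF"):
                raise ValueError(f"not a PFM file (header {header!r})")
            if header == b"PF":
                raise ValueError("colour PFM is not a depth map")
            dims = fh.readline().split()
            w, h = int(dims[0]), int(dims[1])
            scale = float(fh.readline())
            dtype = "<f4" if scale < 0 else ">f4"
            data = np.frombuffer(fh.read(4 * w * h), dtype=dtype).reshape(h, w)
        return np.flipud(data).astype(float)  # PFM rows are bottom-up
    from PIL import Image

    img = np.asarray(Image.open(path))
    if img.dtype != np.uint16:
        raise ValueError(f"expected a 16-bit depth PNG, got dtype {img.dtype}")
    return img.astype(float) / 1000.0


def load_keypoints(path) -> List[Keypoint]:
    """Read landmarks from CSV (view,name,x,y,depth[,occluded]) or JSON."""
    path = Path(path)
    rows: List[dict] = []
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
    else:
        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
    kps = []
    seen = set()
    for row in rows:
        key = (row["view"], row["name"])
        if key in seen:
            raise ValueError(f"duplicate landmark {row['name']!r} in view {row['view']!r}")
        seen.add(key)
        depth = row.get("depth")
        depth = None if depth in (None, "", "nan") else float(depth)
        occluded = str(row.get("occluded", "0")).strip().lower() in ("1", "true", "yes")
        kps.append(
            Keypoint(
                name=row["name"],
                view=row["view"],
                pixel=(float(row["x"]), float(row["y"])),
                depth=depth,
                occluded=occluded,
            )
        )
    return kps


def save_keypoints_csv(kps: List[Keypoint], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["view", "name", "x", "y", "depth", "occluded"])
        for kp in kps:
            writer.writerow(
                [kp.view, kp.name, repr(kp.pixel[0]), repr(kp.pixel[1]),
                 "" if kp.depth is None else repr(kp.depth), int(kp.occluded)]
            )


def validate_keypoint_set(kps: List[Keypoint]) -> Dict[str, bool]:
    """Which measurements are computable from the given landmark set.

    Each measurement has requirement groups; a group is satisfied when at
    least one of its (view, name) alternatives is present with depth.
    """
    present = {(kp.view, kp.name) for kp in kps if kp.depth is not None}
    report = {}
    for measure, groups in MEASUREMENT_REQUIREMENTS.items():
        report[measure] = all(
            any(all(need in present for need in alt) for alt in group)
            for group in groups
        )
    return report
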