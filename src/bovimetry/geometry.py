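"""Foundational geometric types shared by every pipeline stage.

All coordinates are metres. The reference frame is the top camera's frame:
origin at the top camera, x along the animal toward the hip, y toward the
left-view camera, z pointing at the ground (so the ground plane has a
*larger* z than the animal's back and heights are reported as |z - H0|).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "PointCloud",
    "RigidTransform",
    "ReferenceFrame",
    "apply_transform",
    "compose",
]


@dataclass
class PointCloud:
    """A set of 3D points with optional per-point normals and cluster labels.

    Parameters
    ----------
    points : (n, 3) float array
        Point coordinates in metres. Order is meaningful and preserved by
        every filter.
    normals : (n, 3) float array, optional
        Unit normals; rotated (never translated) by rigid transforms.
    labels : (n,) int array, optional
        Cluster ids from density clustering; -1 marks noise.
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
            if len(self.normals) != len(self.points):
                raise ValueError("normal count must equal point count")
            norms = np.linalg.norm(self.normals, axis=1)
            if len(norms) and not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("normals must have unit length")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).reshape(-1)
            if len(self.labels) != len(self.points):
                raise ValueError("label count must equal point count")

    def __len__(self) -> int:
        return len(self.points)

    def select(self, index: np.ndarray) -> "PointCloud":
        """Sub-cloud at ``index`` (bool mask or integer indices), order kept."""
        return PointCloud(
            self.points[index],
            None if self.normals is None else self.normals[index],
            None if self.labels is None else self.labels[index],
        )

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def extent(self) -> np.ndarray:
        """Axis-aligned bounding-box edge lengths."""
        return self.points.max(axis=0) - self.points.min(axis=0)


def _check_rotation(R: np.ndarray, tol: float = 1e-9) -> None:
    if not np.allclose(R.T @ R, np.eye(3), atol=tol * 10):
        raise ValueError("rotation matrix is not orthonormal")
    if not np.isclose(np.linalg.det(R), 1.0, atol=tol * 10):
        raise ValueError("rotation matrix determinant is not +1")


@dataclass(frozen=True)
class RigidTransform:
    """4x4 homogeneous rigid transform: p -> R @ p + t."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        _check_rotation(R)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "RigidTransform":
        M = np.asarray(M, dtype=float).reshape(4, 4)
        return cls(M[:3, :3], M[:3, 3])

    @classmethod
    def from_axis_angle(
        cls, axis, angle_rad: float, translation=(0.0, 0.0, 0.0)
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0.0 or angle_rad == 0.0:
            return cls(np.eye(3), translation)
        axis = axis / norm
        K = np.array(
            [
                [0.0, -axis[2], axis[1]],
                [axis[2], 0.0, -axis[0]],
                [-axis[1], axis[0], 0.0],
            ]
        )
        R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        # re-orthonormalize to keep the invariant tight
        U, _, Vt = np.linalg.svd(R)
        return cls(U @ Vt, translation)

    def matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        return pts @ self.rotation.T + self.translation

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation, degrees (useful for error reporting)."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass(frozen=True)
class ReferenceFrame:
    """Reference spatial frame anchored at the top camera.

    ``ground_z`` is H0, the z coordinate of the ground plane (2.48 m below
    the top camera in the physical rig, hence z = +2.48 with z pointing
    down at the ground).
    """

    ground_z: float = 2.48

    def __post_init__(self) -> None:
        if not np.isfinite(self.ground_z):
            raise ValueError("ground_z must be finite")


def apply_transform(cloud: PointCloud, T: RigidTransform) -> PointCloud:
    """Rigidly move a cloud: points to R p + t, normals to R n."""
    if len(cloud) == 0:
        raise ValueError("empty input cloud")
    pts = T.apply_points(cloud.points)
    normals = None if cloud.normals is None else cloud.normals @ T.rotation.T
    return PointCloud(pts, normals, cloud.labels)


def compose(T1: RigidTransform, T2: RigidTransform) -> RigidTransform:
    """Transform equivalent to applying T2 first, then T1."""
    return RigidTransform(T1.rotation @ T2.rotation, T1.rotation @ T2.translation + T1.translation)
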