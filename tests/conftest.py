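import numpy as np
import pytest

from bovimetry.geometry import PointCloud, RigidTransform


@pytest.fixture
def rng():
    return np.random.default_rng(20241107)


def random_transform(rng, max_angle=np.pi, max_trans=2.0) -> RigidTransform:
    axis = rng.normal(size=3)
    return RigidTransform.from_axis_angle(
        axis / np.linalg.norm(axis),
        rng.uniform(-max_angle, max_angle),
        rng.uniform(-max_trans, max_trans, 3),
    )


@pytest.fixture
def random_cloud(rng):
    return PointCloud(rng.normal(size=(200, 3)))


def cylinder_cloud(
    radius_y=0.35, radius_z=0.30, length=2.0, n=4000, axis_z=1.6,
    rng=None, sigma=0.0, half=False, caps=False,
):
    """Points on an elliptic cylinder around the x-axis at height axis_z.

    ``caps=True`` adds the two end discs (a closed physical object); a
    capless cylinder is translation-ambiguous along its axis for
    point-to-plane objectives.
    """
    rng = rng or np.random.default_rng(0)
    n_side = int(n * 0.85) if caps else n
    x = rng.uniform(-length / 2, length / 2, n_side)
    phi = rng.uniform(0, np.pi if half else 2 * np.pi, n_side)
    pts = np.column_stack(
        [x, radius_y * np.cos(phi), axis_z - radius_z * np.sin(phi)]
    )
    if caps:
        n_cap = (n - n_side) // 2
        parts = [pts]
        for x_end in (-length / 2, length / 2):
            r = np.sqrt(rng.uniform(0, 1, n_cap))
            ang = rng.uniform(0, np.pi if half else 2 * np.pi, n_cap)
            parts.append(
                np.column_stack(
                    [
                        np.full(n_cap, x_end),
                        r * radius_y * np.cos(ang),
                        axis_z - r * radius_z * np.sin(ang),
                    ]
                )
            )
        pts = np.vstack(parts)
    if sigma > 0:
        pts = pts + rng.normal(0, sigma, pts.shape)
    return PointCloud(pts)
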