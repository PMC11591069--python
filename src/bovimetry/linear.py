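"""Linear body sizes: straight length, height, slant length.

Heights are magnitudes |z − H0| so either sign convention of the vertical
axis works (the reference frame points z at the ground, putting the
ground at larger z than the back).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

__all__ = [
    "LinearMeasurements",
    "body_straight_length",
    "body_height",
    "body_slant_length",
    "estimate_ground_z",
]

TOP_ORDER = ("neck", "back", "abdomen", "aid", "buttocks")


@dataclass
class LinearMeasurements:
    straight_length: float  # Ls, metres
    height: float  # Lh, metres
    slant_length: float  # Lo, metres
    slant_left: Optional[float] = None
    slant_right: Optional[float] = None
    back_heights: Dict[str, float] = field(default_factory=dict)
    fallbacks: List[str] = field(default_factory=list)


def body_straight_length(top_positions: Dict[str, np.ndarray]) -> float:
    """Dorsal-midline polyline length over the five ordered top landmarks.

    Ls = Σ |p_{i+1} − p_i| for neck → back → abdomen → aid → buttocks.
    """
    for name in TOP_ORDER:
        if name not in top_positions or top_positions[name] is None:
            raise ValueError(f"missing top-view landmark {name!r}")
    pts = np.array([np.asarray(top_positions[n], dtype=float) for n in TOP_ORDER])
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def body_height(back_z: Dict[str, float], ground_z: float) -> tuple:
    """Mean |z_i − H0| over the views whose back landmark is available.

    Only the z coordinate is used, so a back landmark projected onto a
    railing in a side view still yields the right height. Returns
    (height, fallback flags) — a flag is raised when fewer than three
    views contribute.
    """
    values = {v: z for v, z in back_z.items() if z is not None and np.isfinite(z)}
    if not values:
        raise ValueError("no view provides a back-landmark z coordinate")
    heights = [abs(z - ground_z) for z in values.values()]
    flags = []
    if len(values) < 3:
        flags.append(f"height from {len(values)} view(s) only: {sorted(values)}")
    return float(np.mean(heights)), flags


def body_slant_length(
    sides: Dict[str, Dict[str, np.ndarray]],
    occluded: Optional[Dict[str, bool]] = None,
) -> tuple:
    """Shoulder-end to sciatic-end distance, averaged over sides.

    ``sides`` maps 'left'/'right' to {'foreleg': p, 'buttocks': p}. When a
    side's pair is flagged occluded, the railing-projected points are
    measured in the x–z plane instead (dropping the lateral y component,
    which the railing projection corrupts).

    Returns (Lo, per-side dict, fallback flags).
    """
    occluded = occluded or {}
    per_side: Dict[str, float] = {}
    flags: List[str] = []
    for side, pair in sides.items():
        if pair is None:
            continue
        a = pair.get("foreleg")
        b = pair.get("buttocks")
        if a is None or b is None:
            continue
        d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
        if occluded.get(side, False):
            per_side[side] = float(np.hypot(d[0], d[2]))
            flags.append(f"{side} slant pair occluded: used x-z plane distance")
        else:
            per_side[side] = float(np.linalg.norm(d))
    if not per_side:
        raise ValueError("neither side provides a foreleg-buttocks pair")
    if len(per_side) < 2:
        flags.append(f"slant length from one side only: {sorted(per_side)}")
    lo = float(np.mean(list(per_side.values())))
    return lo, per_side, flags


def estimate_ground_z(points: np.ndarray, slab: float = 0.02) -> float:
    """H0 estimate: modal z of the deepest 2-cm slab of the merged cloud.

    Use when the rig's ground coordinate is not configured. Assumes the
    cloud still contains ground returns and z grows toward the ground.
    """
    z = np.asarray(points)[:, 2]
    zmax = z.max()
    band = z[z >= zmax - slab]
    hist, edges = np.histogram(band, bins=20)
    k = int(np.argmax(hist))
    return float((edges[k] + edges[k + 1]) / 2)
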