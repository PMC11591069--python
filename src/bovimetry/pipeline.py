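"""End-to-end orchestration: preprocess → register → map landmarks →
linear measures → girths → report.

A run consumes a :class:`~bovimetry.synthetic.Scene`-shaped bundle (three
camera-frame clouds, camera models with nominal extrinsics, 2D landmarks,
ground-plane coordinate), which can come from disk (``load_scene``) or
from the synthetic generator, and produces a JSON-serializable
measurement report in centimetres.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .circumference import CircumferenceParams, measure_circumference
from .geometry import PointCloud, RigidTransform, compose
from .io import read_ply, write_ply
from .keypoints import CameraModel, backproject, load_keypoints
from .linear import LinearMeasurements, body_height, body_slant_length, body_straight_length
from .preprocess import (
    CropBox,
    FilterParams,
    dbscan_cluster,
    passthrough_crop,
    select_target_cluster,
    statistical_outlier_removal,
)
from .registration import IcpParams, register_views
from .synthetic import Scene

__all__ = [
    "PipelineConfig",
    "MeasurementReport",
    "run_pipeline",
    "preprocess_view",
    "load_scene",
    "evaluate_batch",
]

log = logging.getLogger(__name__)

# Per-view crop boxes for the standard rig (camera frames). The channel
# and cameras are rigidly mounted, so the box is constant per view; each
# box ends just above the floor (2.48 m below the top camera, ~1.15 m
# below the side cameras' optical axes) so ground returns never enter the
# clustering stage.
DEFAULT_CROPS = {
    "top": CropBox((-1.6, -1.6, 0.3), (1.6, 1.6, 2.38)),
    "left": CropBox((-1.6, -1.6, 0.3), (1.6, 1.05, 3.0)),
    "right": CropBox((-1.6, -1.6, 0.3), (1.6, 1.05, 3.0)),
}
DEFAULT_CROP = CropBox((-1.6, -1.6, 0.3), (1.6, 1.6, 3.0))


@dataclass
class PipelineConfig:
    """All tunables of a pipeline run (defaults suit the standard rig)."""

    crop_boxes: Dict[str, CropBox] = field(default_factory=dict)
    filter_params: FilterParams = field(default_factory=FilterParams)
    expected_extent: tuple = (2.0, 0.8, 1.5)
    fp: float = 0.25
    icp_params: IcpParams = field(default_factory=IcpParams)
    circumference_params: CircumferenceParams = field(default_factory=CircumferenceParams)
    ground_z: Optional[float] = None  # H0; estimated from the cloud when None
    seed: int = 0
    animal_id: str = "unknown"
    debug_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.fp <= 1.0):
            raise ValueError("fp must be in (0, 1]")


@dataclass
class MeasurementReport:
    """Measured body sizes (centimetres) plus per-stage diagnostics."""

    animal_id: str
    measurements_cm: Dict[str, float]
    diagnostics: Dict[str, Dict[str, float]]
    warnings: List[str]
    timings_s: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "measurements_cm": {k: round(v, 1) for k, v in self.measurements_cm.items()},
            "diagnostics": self.diagnostics,
            "warnings": self.warnings,
            "timings_s": {k: round(v, 3) for k, v in self.timings_s.items()},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def preprocess_view(cloud: PointCloud, config: PipelineConfig, view: str) -> PointCloud:
    """Crop, cluster-filter and statistically denoise one raw view."""
    box = config.crop_boxes.get(view, DEFAULT_CROPS.get(view, DEFAULT_CROP))
    fp = config.filter_params
    out = passthrough_crop(cloud, box)
    out = dbscan_cluster(out, fp.dbscan_radius, fp.dbscan_min_samples)
    out = select_target_cluster(out, config.expected_extent)
    out = statistical_outlier_removal(out, fp.sor_neighbors, fp.sor_alpha)
    log.info("preprocess[%s]: %d -> %d points", view, len(cloud), len(out))
    return out


def _stage(name: str, timings: Dict[str, float]):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = time.perf_counter() - self.t0
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    return _Timer()


def run_pipeline(scene: Scene, config: PipelineConfig = PipelineConfig()) -> MeasurementReport:
    """Execute the full measurement chain on one capture session."""
    warnings_log: List[str] = []
    timings: Dict[str, float] = {}
    diagnostics: Dict[str, Dict[str, float]] = {}

    with _stage("preprocess", timings):
        clean = {v: preprocess_view(c, config, v) for v, c in scene.views.items()}

    with _stage("register", timings):
        extr = {v: scene.cameras[v].extrinsic for v in ("top", "left", "right")}
        # the top view defines the reference frame; its cloud is already there
        top_ref = PointCloud(extr["top"].apply_points(clean["top"].points))
        merged, reg = register_views(
            top_ref, clean["left"], clean["right"],
            (extr["left"], extr["right"]), config.fp, config.icp_params,
        )
        for side, res in reg.items():
            diagnostics[f"icp_{side}"] = {
                "rms_m": res.rms,
                "iterations": float(res.iterations),
                "converged": float(res.converged),
            }
            if not res.converged:
                warnings_log.append(f"register: {side} ICP not converged (rms {res.rms:.4g} m)")

    with _stage("map_keypoints", timings):
        corrected = {
            "top": extr["top"],
            "left": compose(reg["left"].transform, extr["left"]),
            "right": compose(reg["right"].transform, extr["right"]),
        }
        kps3d: Dict[tuple, np.ndarray] = {}
        occluded: Dict[tuple, bool] = {}
        for kp in scene.keypoints:
            if kp.depth is None:
                warnings_log.append(f"map_keypoints: {kp.view}/{kp.name} has no depth, skipped")
                continue
            mapped = backproject(kp, scene.cameras[kp.view], extrinsic=corrected[kp.view])
            kps3d[(kp.view, kp.name)] = mapped.position3d
            occluded[(kp.view, kp.name)] = kp.occluded

    with _stage("linear_measures", timings):
        ground_z = scene.ground_z if config.ground_z is None else config.ground_z
        top_pos = {n: kps3d.get(("top", n)) for n in ("neck", "back", "abdomen", "aid", "buttocks")}
        ls = body_straight_length(top_pos)
        back_z = {v: kps3d[(v, "back")][2] for v in ("top", "left", "right") if (v, "back") in kps3d}
        lh, h_flags = body_height(back_z, ground_z)
        sides = {}
        occ_pair = {}
        for side in ("left", "right"):
            pair = {}
            for n in ("foreleg", "buttocks"):
                if (side, n) in kps3d:
                    pair[n] = kps3d[(side, n)]
            if len(pair) == 2:
                sides[side] = pair
                occ_pair[side] = occluded.get((side, "foreleg"), False) or occluded.get(
                    (side, "buttocks"), False
                )
        lo, per_side, s_flags = body_slant_length(sides, occ_pair)
        linear = LinearMeasurements(
            straight_length=ls, height=lh, slant_length=lo,
            slant_left=per_side.get("left"), slant_right=per_side.get("right"),
            back_heights={v: float(z) for v, z in back_z.items()},
            fallbacks=h_flags + s_flags,
        )
        warnings_log.extend(linear.fallbacks)

    with _stage("girths", timings):
        girths = {}
        for which, key in (("abdominal", "girth_abdominal"), ("chest", "girth_chest")):
            girth, profile = measure_circumference(
                merged, kps3d, which, config.circumference_params, config.seed
            )
            girths[key] = girth
            diagnostics[f"{which}_girth"] = profile.diagnostics
            if config.debug_dir:
                dbg = Path(config.debug_dir)
                dbg.mkdir(parents=True, exist_ok=True)
                np.savetxt(dbg / f"{which}_section2d.csv", profile.section2d,
                           delimiter=",", header="u,v", comments="")
                np.savetxt(dbg / f"{which}_polar.csv",
                           np.column_stack([profile.theta, profile.rho]),
                           delimiter=",", header="theta_deg,rho_m", comments="")

    if config.debug_dir:
        write_ply(merged, Path(config.debug_dir) / "merged.ply")

    measurements_cm = {
        "height": linear.height * 100.0,
        "straight_length": linear.straight_length * 100.0,
        "slant_length": linear.slant_length * 100.0,
        "girth_abdominal": girths["girth_abdominal"] * 100.0,
        "girth_chest": girths["girth_chest"] * 100.0,
    }
    return MeasurementReport(
        animal_id=config.animal_id,
        measurements_cm=measurements_cm,
        diagnostics=diagnostics,
        warnings=warnings_log,
        timings_s=timings,
    )


def load_scene(directory) -> Scene:
    """Read a scene directory written by ``write_scene`` (or assembled by hand)."""
    directory = Path(directory)
    meta = json.loads((directory / "cameras.json").read_text())
    cameras = {}
    for name, c in meta["cameras"].items():
        cameras[name] = CameraModel(
            c["fx"], c["fy"], c["cx"], c["cy"], c["width"], c["height"],
            RigidTransform.from_matrix(np.array(c["extrinsic"])),
        )
    views = {}
    for name in cameras:
        path = directory / f"{name}.ply"
        if not path.exists():
            raise FileNotFoundError(
                f"missing view cloud {path}; produce it with the 'synth' subcommand "
                "or supply your own capture"
            )
        views[name] = read_ply(path)
    kps = load_keypoints(directory / "keypoints.csv")
    truth = None
    return Scene(views=views, cameras=cameras, keypoints=kps, truth=truth,
                 ground_z=float(meta["ground_z"]))


MEASURE_COLUMNS = {
    "BH": "height",
    "BL": "straight_length",
    "AC": "girth_abdominal",
    "CC": "girth_chest",
}


def evaluate_batch(reports: List[dict], truths: Dict[str, dict]) -> pd.DataFrame:
    """MAE (cm) and MRE (%) of a batch of reports against ground truths.

    ``truths`` maps animal id to a truth dict in metres (the synthetic
    scene's ``truth.json``). Raises when report ids and truth ids do not
    match one-to-one.
    """
    report_ids = {r["animal_id"] for r in reports}
    unmatched = report_ids.symmetric_difference(truths)
    if unmatched:
        raise ValueError(f"unmatched scene ids between reports and truths: {sorted(unmatched)}")
    rows = {}
    for label, key in MEASURE_COLUMNS.items():
        ref = np.array([truths[r["animal_id"]][key] * 100.0 for r in reports])
        got = np.array([r["measurements_cm"][key] for r in reports])
        err = np.abs(got - ref)
        rows[label] = {"MAE_cm": err.mean(), "MRE_pct": float(np.mean(err / ref) * 100.0)}
    return pd.DataFrame(rows).T
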