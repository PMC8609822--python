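"""End-to-end run: calibration -> tracking -> frame match -> beta prediction.

This is the full prediction chain for one subject and one trial: fit the
femoral head and acetabular spheres, build the anatomical frames from
landmarks, bind them to the standing marker posture, track hip angles through
the trial, pick the frame matching the target (statically imaged) posture by
least-squares angle error, pose the supine bone models at that frame, restore
the supine centre-to-centre distance and compute the minimum beta over the
alpha-plane stack.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import __version__
from . import io as _io
from .clearance import (
    DEFAULT_CONTOUR_BAND,
    DEFAULT_HALF_THICKNESS,
    DEFAULT_SPACING,
    DEFAULT_TOLERANCE,
    build_alpha_plane,
    build_plane_stack,
    default_count_each_side,
    min_beta,
    place_models_at_frame,
)
from .errors import InputError
from .frames import HipJointAngles, build_femur_frame, build_pelvis_frame
from .geometry import SphereFit, fit_sphere
from .mocap import calibrate_standing, match_frame, track_motion
from .synthetic import PELVIS_MARKER_LABELS, THIGH_MARKER_LABELS


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run.

    Paths may be absolute or relative to the config file's directory. The
    config is echoed (with a hash) into every output artifact.
    """

    femur: str
    head: str
    acetabulum: str
    landmarks: str
    motion: str
    target_angles: tuple  # (flexion, adduction, internal_rotation) of the imaged posture
    side: str = "right"
    pelvis_markers: tuple = PELVIS_MARKER_LABELS
    thigh_markers: tuple = THIGH_MARKER_LABELS
    calibration_frame: int = 0
    spacing: float = DEFAULT_SPACING
    half_thickness: float = DEFAULT_HALF_THICKNESS
    tolerance: float = DEFAULT_TOLERANCE
    contour_band: float = DEFAULT_CONTOUR_BAND
    reference_beta: float | None = None
    alpha: float = 0.05
    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("spacing", "half_thickness", "tolerance", "contour_band"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be positive")
        if self.half_thickness > self.spacing / 2:
            raise InputError("half_thickness must not exceed spacing/2")
        if self.side not in ("right", "left"):
            raise InputError("side must be 'right' or 'left'")
        if len(tuple(self.target_angles)) != 3:
            raise InputError("target_angles must be a (flexion, adduction, rotation) triple")
        object.__setattr__(self, "target_angles", tuple(float(a) for a in self.target_angles))
        object.__setattr__(self, "pelvis_markers", tuple(self.pelvis_markers))
        object.__setattr__(self, "thigh_markers", tuple(self.thigh_markers))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        p = Path(path)
        text = p.read_text()
        if p.suffix.lower() in (".yaml", ".yml"):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        if not isinstance(raw, dict):
            raise InputError(f"config {p} must be a mapping")
        cfg = cls(**raw)
        # resolve paths relative to the config file
        base = p.parent
        resolved = {
            k: str((base / getattr(cfg, k)))
            for k in ("femur", "head", "acetabulum", "landmarks", "motion")
            if not Path(getattr(cfg, k)).is_absolute()
        }
        return cls(**{**asdict(cfg), **resolved}) if resolved else cfg

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def predict_beta(
    femur,
    head,
    acetabulum,
    landmarks,
    neck_axis,
    shaft_axis,
    motion,
    target_angles,
    side: str = "right",
    pelvis_markers=PELVIS_MARKER_LABELS,
    thigh_markers=THIGH_MARKER_LABELS,
    calibration_frame: int = 0,
    spacing: float = DEFAULT_SPACING,
    half_thickness: float = DEFAULT_HALF_THICKNESS,
    tolerance: float = DEFAULT_TOLERANCE,
    contour_band: float = DEFAULT_CONTOUR_BAND,
) -> dict:
    """In-memory prediction chain; returns a report dict.

    `femur`/`head`/`acetabulum` are PointClouds in the supine frame,
    `landmarks` a LandmarkSet, `neck_axis`/`shaft_axis` Axis objects,
    `motion` a MarkerTrajectories whose `calibration_frame` is the standing
    reference, `target_angles` the statically imaged angle triple to match.
    """
    head_fit = fit_sphere(head)
    acet_fit = fit_sphere(acetabulum)

    pelvis_frame = build_pelvis_frame(
        landmarks if "acetabulum_center" in landmarks else _with_center(landmarks, acet_fit)
    )
    femur_frame = build_femur_frame(landmarks, head_fit, side=side)

    standing = {
        label: motion.positions[calibration_frame, motion.index(label)]
        for label in (*pelvis_markers, *thigh_markers)
    }
    calib = calibrate_standing(standing, pelvis_frame, femur_frame, pelvis_markers, thigh_markers)
    frames = track_motion(motion, calib, side=side)
    angles = [f.angles for f in frames]

    target = HipJointAngles(*target_angles, side=side)
    matched_idx, matched_lsqe = match_frame(angles, target)
    matched = frames[matched_idx]

    fem_posed, ace_posed = place_models_at_frame(
        femur,
        acetabulum,
        matched.femur_transform,
        matched.pelvis_transform,
        calib.reference_distance,
        head_fit,
        acet_fit.center,
    )
    # pose the head fit and restore the centre-distance translation on it too
    head_center_moved = matched.femur_transform.apply(head_fit.center)
    acet_posed_center = matched.pelvis_transform.apply(acet_fit.center)
    offset = head_center_moved - acet_posed_center
    direction = offset / np.linalg.norm(offset)
    head_center_adj = acet_posed_center + direction * calib.reference_distance
    head_fit_posed = SphereFit(head_center_adj, head_fit.radius, head_fit.rms_residual)

    neck_posed = neck_axis.transformed(matched.femur_transform)
    shaft_posed = shaft_axis.transformed(matched.femur_transform)
    base_plane = build_alpha_plane(head_fit_posed, neck_posed, shaft_posed)
    stack = build_plane_stack(
        base_plane,
        spacing=spacing,
        count_each_side=default_count_each_side(head_fit.radius, spacing),
        half_thickness=half_thickness,
    )
    beta = min_beta(
        fem_posed,
        ace_posed,
        stack,
        head_fit_posed,
        neck_posed,
        tolerance=tolerance,
        contour_band=contour_band,
    )

    return {
        "version": __version__,
        "head_fit": {"center": head_fit.center.tolist(), "radius": head_fit.radius,
                     "rms_residual": head_fit.rms_residual},
        "acetabulum_fit": {"center": acet_fit.center.tolist(), "radius": acet_fit.radius},
        "reference_distance": calib.reference_distance,
        "matched_frame": matched_idx,
        "matched_lsqe": matched_lsqe,
        "matched_angles": {
            "flexion": matched.angles.flexion,
            "adduction": matched.angles.adduction,
            "internal_rotation": matched.angles.internal_rotation,
        },
        "min_beta": beta.min_beta,
        "min_plane_index": beta.min_plane_index,
        "n_planes_used": len(beta.per_plane),
        "excluded_planes": [list(e) for e in beta.excluded_planes],
        "_angles": angles,
        "_stack": stack,
        "_beta_result": beta,
        "_matched": matched,
    }


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute the whole chain from files and write report artifacts."""
    femur = _io.read_point_cloud(config.femur, label="femur")
    head = _io.read_point_cloud(config.head, label="femoral_head")
    acetabulum = _io.read_point_cloud(config.acetabulum, label="acetabulum")
    landmarks = _io.read_landmarks(config.landmarks)
    neck_axis, shaft_axis = _io.read_axes(config.landmarks)
    motion = (
        _io.read_trc(config.motion)
        if str(config.motion).endswith(".trc")
        else _io.read_marker_csv(config.motion)
    )

    result = predict_beta(
        femur,
        head,
        acetabulum,
        landmarks,
        neck_axis,
        shaft_axis,
        motion,
        config.target_angles,
        side=config.side,
        pelvis_markers=config.pelvis_markers,
        thigh_markers=config.thigh_markers,
        calibration_frame=config.calibration_frame,
        spacing=config.spacing,
        half_thickness=config.half_thickness,
        tolerance=config.tolerance,
        contour_band=config.contour_band,
    )
    angles = result.pop("_angles")
    stack = result.pop("_stack")
    beta = result.pop("_beta_result")
    result.pop("_matched")

    report = dict(result)
    report["config_hash"] = config.digest()
    report["config"] = asdict(config)
    if config.reference_beta is not None:
        report["reference_beta"] = float(config.reference_beta)
        report["abs_error"] = abs(beta.min_beta - float(config.reference_beta))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    _io.write_angles_csv(out / "angles.csv", angles)
    rows = ["plane_index,offset_mm,beta_deg,usable_flag"]
    used = {i: b for i, b, _, _ in beta.per_plane}
    excluded = dict(beta.excluded_planes)
    for k in range(-stack.count_each_side, stack.count_each_side + 1):
        if k in used:
            rows.append(f"{k},{k * stack.spacing:g},{used[k]!r},usable")
        else:
            rows.append(f"{k},{k * stack.spacing:g},,{excluded.get(k, 'excluded')}")
    (out / "beta.csv").write_text("\n".join(rows) + "\n")
    return report


def _with_center(landmarks, acet_fit):
    from .frames import LandmarkSet

    d = dict(landmarks.landmarks)
    d["acetabulum_center"] = acet_fit.center
    return LandmarkSet(d)
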