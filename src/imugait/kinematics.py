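"""Three-plane joint angles, angular velocity and locomotion outcome metrics.

Segment anatomical frames are X anterior, Y left, Z up in quiet standing.
Joint rotations (distal segment relative to proximal) are decomposed with the
mobile flexion / ab-adduction / axial-rotation sequence of the standard
biomechanics convention: an intrinsic rotation about the medio-lateral axis
first (sagittal plane, flexion positive forward), then about the anterior
axis (frontal plane), then about the longitudinal axis (transverse plane).
With the axis layout above this is the intrinsic Y-X-Z sequence with the
sagittal sign flipped so that forward rotation of the distal end is positive.
Pelvis angles use the same decomposition of the segment-to-world rotation
(anterior tilt, obliquity, rotation).

ROM is max minus min of the averaged 101-point angle cycle (degrees); SPEED
is the same range on the averaged angular-velocity cycle (deg/s), the
velocity being a central finite difference of the raw angle series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

JOINTS = ("pelvis", "hip", "knee", "ankle")
PLANES = ("sagittal", "frontal", "transverse")

#: proximal segment, distal segment templates per side for each articulation
JOINT_SEGMENTS = {
    "hip": ("pelvis_L5", "thigh_{side}"),
    "knee": ("thigh_{side}", "shank_{side}"),
    "ankle": ("shank_{side}", "foot_{side}"),
}

GIMBAL_LIMIT_DEG = 85.0


class NonFiniteCurveError(ValueError):
    """A normalized cycle fed to a range metric contains non-finite points."""


# ---------------------------------------------------------------------------
# Euler convention (shared with the synthetic forward model)
# ---------------------------------------------------------------------------

def joint_rotation(angles_deg: np.ndarray) -> Rotation:
    """Rotation of a distal segment relative to its proximal one.

    ``angles_deg`` is (..., 3): sagittal, frontal, transverse in degrees.
    """
    a = np.atleast_2d(np.asarray(angles_deg, dtype=float))
    eul = np.column_stack([-a[:, 0], a[:, 1], a[:, 2]])
    r = Rotation.from_euler("YXZ", eul, degrees=True)
    return r


def rotation_to_joint_angles(r: Rotation) -> np.ndarray:
    """Inverse of :func:`joint_rotation`; returns (N, 3) degrees."""
    eul = r.as_euler("YXZ", degrees=True)
    eul = np.atleast_2d(eul)
    return np.column_stack([-eul[:, 0], eul[:, 1], eul[:, 2]])


@dataclass
class JointAngleSeries:
    """Sagittal/frontal/transverse angle series for one joint and side."""

    joint: str
    side: str                   # "L" | "R" | "" (pelvis)
    angles: np.ndarray          # (N, 3) degrees, plane order = PLANES
    fs: float
    gimbal_flags: np.ndarray = field(default=None)  # bool (N,), frontal near 90 deg

    def plane(self, name: str) -> np.ndarray:
        return self.angles[:, PLANES.index(name)]


def joint_angles(
    proximal, distal, calib_prox: np.ndarray, calib_dist: np.ndarray,
    joint: str = "hip", side: str = "R", fs: float = None,
) -> JointAngleSeries:
    """Joint angles from two sensor orientation series and their calibrations.

    ``proximal``/``distal`` are :class:`~imugait.orientation.OrientationSeries`
    (sensor->world); ``calib_*`` are 3x3 sensor->segment matrices.  The
    relative rotation of the calibrated distal segment in the calibrated
    proximal frame is decomposed with :func:`rotation_to_joint_angles`.
    Samples whose frontal angle exceeds 85 deg are flagged (gimbal proximity).
    """
    R_prox = proximal.as_rotation() * Rotation.from_matrix(calib_prox).inv()
    R_dist = distal.as_rotation() * Rotation.from_matrix(calib_dist).inv()
    rel = R_prox.inv() * R_dist
    ang = rotation_to_joint_angles(rel)
    flags = np.abs(ang[:, 1]) > GIMBAL_LIMIT_DEG
    return JointAngleSeries(
        joint=joint, side=side, angles=ang,
        fs=fs if fs is not None else proximal.fs,
        gimbal_flags=flags,
    )


def pelvis_angles(orientation, calib: np.ndarray, fs: float = None) -> JointAngleSeries:
    """Pelvis segment-to-world angles (anterior tilt, obliquity, rotation)."""
    R_seg = orientation.as_rotation() * Rotation.from_matrix(calib).inv()
    ang = rotation_to_joint_angles(R_seg)
    flags = np.abs(ang[:, 1]) > GIMBAL_LIMIT_DEG
    return JointAngleSeries(
        joint="pelvis", side="", angles=ang,
        fs=fs if fs is not None else orientation.fs, gimbal_flags=flags,
    )


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def angular_velocity(angles: np.ndarray, fs: float) -> np.ndarray:
    """Finite-difference angular velocity in deg/s.

    Central difference (x[k+1] - x[k-1]) * fs / 2 in the interior, one-sided
    at both ends; exact for polynomials of degree <= 2.  Operates on the raw
    (un-normalized) series, column-wise for 2-D input.
    """
    x = np.asarray(angles, dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    v = np.empty_like(x)
    v[1:-1] = (x[2:] - x[:-2]) * (fs / 2.0)
    v[0] = (x[1] - x[0]) * fs
    v[-1] = (x[-1] - x[-2]) * fs
    return v


def range_metric(cycle) -> float:
    """Max minus min of the averaged cycle curve (degrees or deg/s).

    Accepts a :class:`~imugait.segmentation.NormalizedCycle` or a bare
    101-point array.
    """
    mean_attr = getattr(cycle, "mean", None)
    curve = np.asarray(cycle if mean_attr is None or callable(mean_attr)
                       else mean_attr, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise NonFiniteCurveError("cycle curve contains non-finite points")
    return float(curve.max() - curve.min())


@dataclass
class CycleMetrics:
    """Outcome metrics for one task bout and side."""

    task: str
    side: str
    rom_deg: dict            # (joint, plane) -> ROM in degrees
    speed_dps: dict          # (joint, plane) -> angular speed range in deg/s
    stride_time_s: float
    cadence_cpm: float       # cycles per minute = 60 / stride_time

    def __post_init__(self) -> None:
        if self.stride_time_s > 0:
            assert abs(self.cadence_cpm * self.stride_time_s - 60.0) < 1e-6


def spatiotemporal(events, fs: float, side: str = None) -> tuple:
    """(stride_time_s, cadence_cpm) from initial-contact events.

    ``events`` is a :class:`~imugait.segmentation.GaitEvents`; intervals are
    pooled over both sides unless ``side`` selects one.  Cadence is reported
    in cycles per minute (60 / stride time).
    """
    sides = [side] if side else [s for s in ("L", "R") if len(events.contacts.get(s, ())) >= 2]
    intervals = []
    for s in sides:
        c = np.asarray(events.contacts[s], dtype=float)
        if len(c) >= 2:
            intervals.append(np.diff(c) / fs)
    if not intervals:
        raise ValueError("need at least 2 same-side contacts")
    stride = float(np.concatenate(intervals).mean())
    return stride, 60.0 / stride


@dataclass
class ClinicalMetrics:
    """Timed-walk speeds (m/s over 10 m) and 6-minute distance (m)."""

    self_selected_speed_mps: float = None
    fast_speed_mps: float = None
    six_min_distance_m: float = None


def clinical_metrics(bout_durations: dict, known_distances: dict) -> ClinicalMetrics:
    """Clinical outcomes from bout durations and known distances.

    ``bout_durations`` maps task -> seconds; ``known_distances`` maps task ->
    meters (10 m for the timed walks; for the 6-min task the ground-truth
    total distance when available, e.g. from a synthetic session sidecar).
    """
    out = ClinicalMetrics()
    for task, attr in (("walk_self", "self_selected_speed_mps"),
                       ("walk_fast", "fast_speed_mps")):
        if task in bout_durations:
            dur = bout_durations[task]
            if dur <= 0:
                raise ValueError(f"{task}: non-positive bout duration")
            dist = known_distances.get(task, 10.0)
            setattr(out, attr, dist / dur)
    if "walk_6min" in known_distances:
        out.six_min_distance_m = float(known_distances["walk_6min"])
    return out
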