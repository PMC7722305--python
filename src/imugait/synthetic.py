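"""Synthetic lower-limb kinematics and forward-simulated 7-sensor IMU sessions.

The generator produces ground-truth joint-angle curves for five locomotor
tasks (self-selected walk, fast walk, stairs up, stairs down, 6-min walk) as
sums of at most three cycle-locked harmonics per joint and plane, scaled so
the continuous curve's range is exactly twice the requested amplitude.  A
rigid-body chain (pelvis, thighs, shanks, feet) converts the angles into
segment orientations and sensor positions, from which accelerometer (gravity
plus linear acceleration, in g), gyroscope (body rates, deg/s) and
magnetometer (rotated Earth field, G) signals are synthesized, with white
noise, constant gyro bias, a sinusoidal soft-tissue wobble of the sensor on
its segment, and a damped heel-strike transient on the shank and foot
accelerometers at every true initial contact.

Harmonic phases are chosen so that at initial contact the hip is near peak
flexion and the knee is extending (the pattern the event detector exploits),
and so that the sagittal-plane angular rate is uncorrelated with the other
planes' rates over a cycle, which conditions the functional calibration
well.  No claim of physiological realism is made beyond matching published
summary metrics (ROM, stride time, cadence, walking speed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from . import reference
from .io_sessions import (
    ACCEL_RANGE_G, GYRO_RANGE_DPS, MAG_RANGE_G, DEFAULT_FS,
    ImuStream, SessionRecording, PLACEMENTS,
)
from .orientation import MAG_REFERENCE
from .kinematics import joint_rotation, PLANES

G_MPS2 = 9.80665

#: heel-strike transient: amplitude (g), Gaussian envelope SD (s), ring frequency (Hz)
IMPACT_AMP_G = 1.5
IMPACT_TAU_S = 0.012
IMPACT_FREQ_HZ = 16.0


class SyntheticParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Waveform family
# ---------------------------------------------------------------------------
# Each (joint, plane) shape is a list of (cycles-per-stride, amplitude, phase)
# harmonics: sum of a * cos(2*pi*f*phi + psi).  f = 0 encodes a constant.
# Phases put peak hip flexion at contact (phi = 0), knee extension velocity
# at contact, and make sagittal rates orthogonal to frontal/transverse rates.
# Sagittal shapes live in the {sin 2*pi*phi, cos 4*pi*phi} rate family and all
# frontal/transverse shapes are +/- sin 2*pi*phi (rate family cos 2*pi*phi), so
# medio-lateral segment rates are uncorrelated with the other axes.  Signs
# alternate down the chain (pelvis +, hip -, knee +, ankle -) so out-of-plane
# joint excursions largely cancel at the segment level, as pelvis list/rotation
# and hip ab-adduction do in gait.
_S = {
    ("pelvis", "sagittal"): [(2, 1.0, -math.pi / 2)],
    ("pelvis", "frontal"): [(1, 1.0, -math.pi / 2)],
    ("pelvis", "transverse"): [(1, 1.0, -math.pi / 2)],
    ("hip", "sagittal"): [(1, 1.0, 0.0)],
    ("hip", "frontal"): [(1, 1.0, math.pi / 2)],
    ("hip", "transverse"): [(1, 1.0, math.pi / 2)],
    ("knee", "sagittal"): [(1, 1.0, -1.4 * math.pi), (2, 0.2, -0.8 * math.pi)],
    ("knee", "frontal"): [(1, 1.0, -math.pi / 2)],
    ("knee", "transverse"): [(1, 1.0, -math.pi / 2)],
    ("ankle", "sagittal"): [(1, 1.0, -1.1 * math.pi), (2, 0.2, -0.2 * math.pi)],
    ("ankle", "frontal"): [(1, 1.0, math.pi / 2)],
    ("ankle", "transverse"): [(1, 1.0, math.pi / 2)],
}

#: baseline offset of the normalized curve, in units of amplitude: the knee
#: oscillates in [0, 2A] (never hyper-extends); other joints about zero.
_BASELINE = {("knee", "sagittal"): 1.0}

_DENSE = np.linspace(0.0, 1.0, 4096, endpoint=False)


def _raw_shape(joint: str, plane: str, phi, extra_phase: float = 0.0):
    val = np.zeros_like(np.asarray(phi, dtype=float))
    for f, a, psi in _S[(joint, plane)]:
        val = val + a * np.cos(2 * math.pi * f * np.asarray(phi) + psi + extra_phase * (f != 0))
    return val


def unit_shape(joint: str, plane: str, phi, extra_phase: float = 0.0):
    """Periodic shape normalized to half-range exactly 1 over a cycle."""
    dense = _raw_shape(joint, plane, _DENSE, extra_phase)
    lo, hi = dense.min(), dense.max()
    half = (hi - lo) / 2.0
    mid = (hi + lo) / 2.0
    if half < 1e-12:
        return np.zeros_like(np.asarray(phi, dtype=float))
    return (_raw_shape(joint, plane, phi, extra_phase) - mid) / half


def true_speed_range(joint: str, plane: str, amplitude_deg: float,
                     stride_time_s: float, extra_phase: float = 0.0) -> float:
    """Range of the continuous angular velocity (deg/s) of one plane's curve."""
    dense = unit_shape(joint, plane, _DENSE, extra_phase)
    dphi = _DENSE[1] - _DENSE[0]
    vel = np.gradient(dense, dphi) / stride_time_s
    return float(amplitude_deg * (vel.max() - vel.min()))


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass
class GaitProfileParams:
    """Ground-truth kinematic parameters for one task bout.

    ``amplitudes`` maps (joint, plane) to the half-range A in degrees: the
    generated continuous curve has max - min = 2 A.  ``phases`` adds a phase
    offset (radians) to the cycle-locked harmonics of that joint/plane.
    """

    task: str = "walk_self"
    stride_time_s: float = 1.20
    n_cycles: int = 10
    fs: float = DEFAULT_FS
    amplitudes: dict = field(default_factory=dict)   # (joint, plane) -> deg
    phases: dict = field(default_factory=dict)       # (joint, plane) -> rad
    lr_phase_lag: float = 0.5                        # fraction of cycle
    lead_in_s: float = 2.0
    lead_out_s: float = 2.0
    speed_mps: float = 1.1                           # steady progression speed
    stride_jitter_sd_s: float = 0.0
    ramp_s: float = 0.4

    def validate(self) -> None:
        if self.stride_time_s <= 0:
            raise SyntheticParameterError("stride_time must be positive")
        if self.n_cycles < 1:
            raise SyntheticParameterError("n_cycles must be >= 1")
        if self.stride_time_s * self.fs < 20:
            raise SyntheticParameterError("stride_time * fs must be >= 20 samples")
        if self.lead_in_s < 0 or self.lead_out_s < 0:
            raise SyntheticParameterError("lead_in/lead_out must be >= 0")
        if not 0.0 <= self.lr_phase_lag < 1.0:
            raise SyntheticParameterError("lr_phase_lag must be in [0, 1)")
        for key, a in self.amplitudes.items():
            if a < 0:
                raise SyntheticParameterError(f"negative amplitude for {key}")


#: fallback half-range amplitudes (deg) for planes without a published ROM row
_EXTRA_AMPLITUDES = {
    ("knee", "frontal"): 4.0,
    ("knee", "transverse"): 5.0,
    ("ankle", "frontal"): 5.0,
    ("ankle", "transverse"): 6.0,
}


def task_defaults(task: str, group: str = "healthy") -> GaitProfileParams:
    """Default parameters for a task, seeded from published group summaries.

    ``group`` selects the column: "healthy", "pre" (patients before
    treatment) or "post".
    """
    kin_task = {"walk_fast": "walk_self", "walk_6min": "walk_self"}.get(task, task)
    col = {"healthy": "healthy_mean", "pre": "pre_mean", "post": "post_mean"}[group]
    amps = {}
    for row in reference.rows(metric="rom", task=kin_task):
        amps[(row.joint, row.plane)] = getattr(row, col) / 2.0
    amps.update(_EXTRA_AMPLITUDES)
    stride = getattr(reference.get_row(kin_task, "stride_time"), col)
    if task == "walk_fast":
        speed = getattr(reference.get_row("walk_fast", "clinical"), col)
        stride = stride * 0.9
    elif task == "walk_6min":
        speed = getattr(reference.get_row("walk_6min", "clinical"), col) / 360.0
    elif task == "walk_self":
        speed = getattr(reference.get_row("walk_self", "clinical"), col)
    else:
        speed = 0.5   # stairs progression; not an outcome
    return GaitProfileParams(
        task=task, stride_time_s=float(stride), amplitudes=amps,
        speed_mps=float(speed),
    )


@dataclass
class NoiseModel:
    """Sensor error model; identical seed implies identical output."""

    accel_sd_g: float = 0.02
    gyro_sd_dps: float = 0.4
    gyro_bias_dps: float = 0.5          # per-axis bias drawn U(-b, b) per sensor
    mag_sd_g: float = 0.05
    soft_tissue_amp_deg: float = 0.5    # sinusoidal sensor wobble on the segment
    soft_tissue_freq_hz: float = 6.0
    mounting_sd_deg: float = 3.0        # re-donning misalignment (used by cohorts)
    seed: int = 0

    def validate(self) -> None:
        for name in ("accel_sd_g", "gyro_sd_dps", "gyro_bias_dps", "mag_sd_g",
                     "soft_tissue_amp_deg", "mounting_sd_deg"):
            if getattr(self, name) < 0:
                raise SyntheticParameterError(f"{name} must be >= 0")


ZERO_NOISE = NoiseModel(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0)


@dataclass
class SegmentGeometry:
    """Rigid-segment lengths, sensor offsets and mounting rotations."""

    pelvis_half_width_m: float = 0.12
    hip_drop_m: float = 0.10
    thigh_len_m: float = 0.40
    shank_len_m: float = 0.40
    foot_len_m: float = 0.15
    pelvis_height_m: float = 1.0
    mounting: dict = field(default_factory=dict)   # placement -> Rotation (sensor->segment)

    def sensor_offset(self, placement: str) -> np.ndarray:
        if placement == "pelvis_L5":
            return np.array([-0.10, 0.0, 0.0])
        if placement.startswith("thigh"):
            return np.array([0.05, 0.0, -0.5 * self.thigh_len_m])
        if placement.startswith("shank"):
            return np.array([0.04, 0.0, -0.5 * self.shank_len_m])
        return np.array([0.5 * self.foot_len_m, 0.0, -0.05])


def random_mountings(sd_deg: float, rng: np.random.Generator) -> dict:
    """Random small sensor-on-segment rotations (re-donning misalignment)."""
    mountings = {}
    for p in PLACEMENTS:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = math.radians(abs(rng.normal(0.0, sd_deg))) if sd_deg > 0 else 0.0
        mountings[p] = Rotation.from_rotvec(axis * angle)
    return mountings


# ---------------------------------------------------------------------------
# Ground-truth kinematics
# ---------------------------------------------------------------------------

@dataclass
class GroundTruthKinematics:
    """Known-truth kinematics, the oracle for every recovery test."""

    fs: float
    time: np.ndarray
    angles: dict                  # (joint, side) -> (N, 3) deg; pelvis side ""
    seg_rot: dict                 # placement/segment -> scipy Rotation (N,)
    pelvis_pos: np.ndarray        # (N, 3) m
    events_time: dict             # side -> contact times (s)
    events: dict                  # side -> contact sample indices
    annotations: list             # (task, start_s, end_s)
    truth: dict                   # task -> {rom, speed, stride_time_s, ...}

    @property
    def n_samples(self) -> int:
        return self.time.shape[0]

    def validate(self) -> None:
        for seg, rot in self.seg_rot.items():
            q = rot.as_quat()
            if np.any(np.abs(np.linalg.norm(q, axis=1) - 1.0) > 1e-9):
                raise ValueError(f"{seg}: non-unit quaternion")
        for side, c in self.events.items():
            if np.any(np.diff(c) <= 0):
                raise ValueError(f"{side}: contacts not strictly increasing")


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(math.pi * u)


def make_gait_profile(params: GaitProfileParams, seed: int = 0) -> GroundTruthKinematics:
    """Generate ground-truth kinematics for one task bout.

    The bout is framed by standing lead-in/lead-out; the angle curves ramp in
    over the last ``ramp_s`` of the lead-in, run for ``n_cycles`` strides
    (the left side lags by ``lr_phase_lag`` of a cycle and finishes inside
    the lead-out), and ramp back to standing.  True initial contacts are at
    the cycle boundaries, ``n_cycles + 1`` per side.
    """
    params.validate()
    rng = np.random.default_rng(seed)
    fs = params.fs
    n_cyc = params.n_cycles

    strides = np.full(n_cyc, params.stride_time_s)
    if params.stride_jitter_sd_s > 0:
        strides = strides + rng.normal(0.0, params.stride_jitter_sd_s, size=n_cyc)
        strides = np.clip(strides, 0.5 * params.stride_time_s, 1.5 * params.stride_time_s)
    bounds = params.lead_in_s + np.concatenate([[0.0], np.cumsum(strides)])  # T_0..T_n

    duration = bounds[-1] + params.lead_out_s
    n = int(round(duration * fs)) + 1
    t = np.arange(n) / fs

    # piecewise-linear cycle fraction phi(t), extended periodically outside
    phi = np.interp(t, bounds, np.arange(n_cyc + 1, dtype=float))
    phi = np.where(t < bounds[0], (t - bounds[0]) / strides[0], phi)
    phi = np.where(t > bounds[-1], n_cyc + (t - bounds[-1]) / strides[-1], phi)

    lag = params.lr_phase_lag
    t_act_end = bounds[-1] + lag * strides[-1]
    w = np.ones(n)
    w = np.where(t < bounds[0], _smoothstep((t - (bounds[0] - params.ramp_s)) / params.ramp_s), w)
    w = np.where(t > t_act_end, 1.0 - _smoothstep((t - t_act_end) / params.ramp_s), w)

    angles = {}
    for joint in ("pelvis", "hip", "knee", "ankle"):
        sides = [""] if joint == "pelvis" else ["R", "L"]
        for side in sides:
            out = np.zeros((n, 3))
            for pi, plane in enumerate(PLANES):
                amp = params.amplitudes.get((joint, plane), 0.0)
                if amp == 0.0:
                    continue
                psi = params.phases.get((joint, plane), 0.0)
                base = _BASELINE.get((joint, plane), 0.0)
                ph = phi if side != "L" else phi - lag
                curve = w * amp * (base + unit_shape(joint, plane, ph, psi))
                # anatomical mirroring: left-side out-of-sagittal rotations
                # are opposite-signed about the shared axes
                if side == "L" and plane != "sagittal":
                    curve = -curve
                out[:, pi] = curve
            angles[(joint, side)] = out

    # forward rigid-chain orientations
    r_pelvis = joint_rotation(angles[("pelvis", "")])
    seg_rot = {"pelvis_L5": r_pelvis}
    for side in ("R", "L"):
        r_thigh = r_pelvis * joint_rotation(angles[("hip", side)])
        r_shank = r_thigh * joint_rotation(angles[("knee", side)])
        r_foot = r_shank * joint_rotation(angles[("ankle", side)])
        seg_rot[f"thigh_{side}"] = r_thigh
        seg_rot[f"shank_{side}"] = r_shank
        seg_rot[f"foot_{side}"] = r_foot

    # pelvis translation: steady progression along +X with a small vertical bob
    v = params.speed_mps * w
    x = np.concatenate([[0.0], np.cumsum((v[1:] + v[:-1]) * 0.5 / fs)])
    z = 1.0 + 0.015 * w * np.sin(4 * math.pi * phi)
    pelvis_pos = np.column_stack([x, np.zeros(n), z])

    ev_r = bounds.copy()
    ev_l = bounds + lag * np.concatenate([strides, [strides[-1]]])
    events_time = {"R": ev_r, "L": ev_l}
    events = {s: np.round(v_ * fs).astype(int) for s, v_ in events_time.items()}

    rom = {}
    speed_rng = {}
    for (joint, plane), shapes in _S.items():
        amp = params.amplitudes.get((joint, plane), 0.0)
        rom[(joint, plane)] = 2.0 * amp
        psi = params.phases.get((joint, plane), 0.0)
        speed_rng[(joint, plane)] = true_speed_range(
            joint, plane, amp, float(np.mean(strides)), psi)

    stride_mean = float(np.mean(strides))
    truth = {
        params.task: {
            "rom": rom,
            "speed": speed_rng,
            "stride_time_s": stride_mean,
            "cadence_cpm": 60.0 / stride_mean,
            "speed_mps": params.speed_mps,
            "distance_m": (params.speed_mps * 360.0 if params.task == "walk_6min"
                           else float(x[-1] - x[0])),
            "bout_duration_s": float(bounds[-1] - bounds[0]),
        }
    }
    annotations = [(params.task, float(bounds[0]), float(t_act_end))]

    gt = GroundTruthKinematics(
        fs=fs, time=t, angles=angles, seg_rot=seg_rot, pelvis_pos=pelvis_pos,
        events_time=events_time, events=events, annotations=annotations,
        truth=truth,
    )
    gt.validate()
    return gt


def concat_kinematics(parts: list) -> GroundTruthKinematics:
    """Chain task bouts into one recording (stand-to-stand continuity)."""
    assert parts
    fs = parts[0].fs
    times, angles, pelvis, events_t = [], {k: [] for k in parts[0].angles}, [], {"R": [], "L": []}
    seg_rot = {k: [] for k in parts[0].seg_rot}
    annotations, truth = [], {}
    t_off, x_off = 0.0, 0.0
    for part in parts:
        times.append(part.time + t_off)
        for k in angles:
            angles[k].append(part.angles[k])
        for k in seg_rot:
            seg_rot[k].append(part.seg_rot[k])
        p = part.pelvis_pos.copy()
        p[:, 0] += x_off
        pelvis.append(p)
        for s in ("R", "L"):
            events_t[s].append(part.events_time[s] + t_off)
        for task, t0, t1 in part.annotations:
            annotations.append((task, t0 + t_off, t1 + t_off))
        truth.update(part.truth)
        x_off += part.pelvis_pos[-1, 0] - part.pelvis_pos[0, 0]
        t_off += (part.n_samples) / fs

    time = np.concatenate(times)
    events_time = {s: np.concatenate(v) for s, v in events_t.items()}
    gt = GroundTruthKinematics(
        fs=fs, time=time,
        angles={k: np.concatenate(v) for k, v in angles.items()},
        seg_rot={k: Rotation.concatenate(v) for k, v in seg_rot.items()},
        pelvis_pos=np.concatenate(pelvis),
        events_time=events_time,
        events={s: np.round(v * fs).astype(int) for s, v in events_time.items()},
        annotations=annotations, truth=truth,
    )
    gt.validate()
    return gt


# ---------------------------------------------------------------------------
# IMU forward simulation
# ---------------------------------------------------------------------------

def _body_rates_dps(rot: Rotation, fs: float) -> np.ndarray:
    """Per-sample body rates: mean rate over [k, k+1], last value replicated."""
    rel = rot[:-1].inv() * rot[1:]
    w = rel.as_rotvec(degrees=True) * fs
    return np.vstack([w, w[-1:]])


def _second_derivative(pos: np.ndarray, fs: float) -> np.ndarray:
    acc = np.zeros_like(pos)
    acc[1:-1] = (pos[2:] - 2.0 * pos[1:-1] + pos[:-2]) * fs * fs
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def _impact_series(time: np.ndarray, contact_times: np.ndarray) -> np.ndarray:
    """Heel-strike transient (g, world-vertical) peaking at each contact."""
    out = np.zeros_like(time)
    for tc in contact_times:
        lo = np.searchsorted(time, tc - 5 * IMPACT_TAU_S)
        hi = np.searchsorted(time, tc + 5 * IMPACT_TAU_S)
        dt = time[lo:hi] - tc
        out[lo:hi] += IMPACT_AMP_G * np.exp(-0.5 * (dt / IMPACT_TAU_S) ** 2) * \
            np.cos(2 * math.pi * IMPACT_FREQ_HZ * dt)
    return out


def simulate_imu_session(
    gt: GroundTruthKinematics,
    noise: NoiseModel = None,
    geometry: SegmentGeometry = None,
    subject: str = "S00",
    visit: str = "pre",
) -> SessionRecording:
    """Forward-simulate the seven sensor streams from ground-truth kinematics."""
    if noise is None:
        noise = NoiseModel()
    if geometry is None:
        geometry = SegmentGeometry()
    noise.validate()
    rng = np.random.default_rng(noise.seed)
    fs = gt.fs
    n = gt.n_samples
    t = gt.time

    # joint centers from the rigid chain
    r_pel = gt.seg_rot["pelvis_L5"]
    centers = {"pelvis_L5": gt.pelvis_pos}
    for side in ("R", "L"):
        sign = -1.0 if side == "R" else 1.0
        hip = gt.pelvis_pos + r_pel.apply(
            np.array([0.0, sign * geometry.pelvis_half_width_m, -geometry.hip_drop_m]))
        knee = hip + gt.seg_rot[f"thigh_{side}"].apply(
            np.array([0.0, 0.0, -geometry.thigh_len_m]))
        ankle = knee + gt.seg_rot[f"shank_{side}"].apply(
            np.array([0.0, 0.0, -geometry.shank_len_m]))
        centers[f"thigh_{side}"] = hip
        centers[f"shank_{side}"] = knee
        centers[f"foot_{side}"] = ankle

    impact = {s: _impact_series(t, gt.events_time[s]) for s in ("R", "L")}

    streams = {}
    for placement in PLACEMENTS:
        seg = gt.seg_rot[placement]
        mount = geometry.mounting.get(placement, Rotation.identity())

        # sensor orientation: segment o mounting o soft-tissue wobble; the
        # wobble is motion-driven, scaling with the segment's angular speed
        # (no artifact while standing still)
        r_sensor = seg * mount
        if noise.soft_tissue_amp_deg > 0:
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            psi = rng.uniform(0.0, 2 * math.pi)
            seg_rate = np.linalg.norm(_body_rates_dps(seg, fs), axis=1)
            env = np.clip(seg_rate / 50.0, 0.0, 1.0)
            wob = env * math.radians(noise.soft_tissue_amp_deg) * np.sin(
                2 * math.pi * noise.soft_tissue_freq_hz * t + psi)
            r_sensor = r_sensor * Rotation.from_rotvec(axis[None, :] * wob[:, None])

        pos = centers[placement] + seg.apply(geometry.sensor_offset(placement))

        gyro = _body_rates_dps(r_sensor, fs)
        bias = rng.uniform(-noise.gyro_bias_dps, noise.gyro_bias_dps, size=3) \
            if noise.gyro_bias_dps > 0 else np.zeros(3)
        if noise.gyro_sd_dps > 0:
            gyro = gyro + rng.normal(0.0, noise.gyro_sd_dps, size=(n, 3))
        gyro = np.clip(gyro + bias, -GYRO_RANGE_DPS, GYRO_RANGE_DPS)

        f_world = _second_derivative(pos, fs) / G_MPS2
        f_world[:, 2] += 1.0
        side = placement[-1]
        if placement.startswith(("shank", "foot")) and side in impact:
            f_world[:, 2] += impact[side]
        accel = r_sensor.inv().apply(f_world)
        if noise.accel_sd_g > 0:
            accel = accel + rng.normal(0.0, noise.accel_sd_g, size=(n, 3))
        accel = np.clip(accel, -ACCEL_RANGE_G, ACCEL_RANGE_G)

        mag = r_sensor.inv().apply(MAG_REFERENCE)
        if noise.mag_sd_g > 0:
            mag = mag + rng.normal(0.0, noise.mag_sd_g, size=(n, 3))
        mag = np.clip(mag, -MAG_RANGE_G, MAG_RANGE_G)

        streams[placement] = ImuStream(
            placement=placement, time=np.arange(n) / fs,
            accel=accel, gyro=gyro, mag=mag, fs=fs,
        )

    meta = {}
    for task, info in gt.truth.items():
        meta[f"distance_m.{task}"] = format(info["distance_m"], ".10g")
        meta[f"speed_mps.{task}"] = format(info["speed_mps"], ".10g")
    return SessionRecording(
        subject=subject, visit=visit, streams=streams,
        annotations=list(gt.annotations), meta=meta,
    )


def write_ground_truth(gt: GroundTruthKinematics, path) -> None:
    """JSON sidecar with true events and per-task metrics."""
    payload = {
        "fs": gt.fs,
        "events": {s: np.asarray(v).tolist() for s, v in gt.events.items()},
        "events_time": {s: np.asarray(v).tolist() for s, v in gt.events_time.items()},
        "annotations": [[task, t0, t1] for task, t0, t1 in gt.annotations],
        "truth": {
            task: {
                "rom": {f"{j}.{p}": v for (j, p), v in info["rom"].items()},
                "speed": {f"{j}.{p}": v for (j, p), v in info["speed"].items()},
                **{k: v for k, v in info.items() if k not in ("rom", "speed")},
            }
            for task, info in gt.truth.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def simulate_metric_pairs(
    n_subjects: int,
    base_mean: float = 0.0,
    base_sd: float = 1.0,
    effect: float = 0.0,
    diff_sd: float = 1.0,
    seed: int = 0,
) -> tuple:
    """Metric-level paired cohort: (pre, post) vectors of one outcome.

    Subject baselines are N(base_mean, base_sd); paired differences are
    N(effect, diff_sd).  Used for calibration studies of the paired-test
    machinery at replication counts where full IMU simulation is pointless.
    """
    rng = np.random.default_rng(seed)
    pre = rng.normal(base_mean, base_sd, size=n_subjects)
    post = pre + rng.normal(effect, diff_sd, size=n_subjects)
    return pre, post


def simulate_retest_metric(
    n_subjects: int,
    between_sd: float = 1.0,
    error_sd: float = 0.5,
    mean: float = 0.0,
    trial_offset: float = 0.0,
    seed: int = 0,
) -> tuple:
    """Two-trial metric draws from the two-variance-component model.

    The population ICC is between_sd**2 / (between_sd**2 + error_sd**2);
    ``trial_offset`` adds a systematic shift to trial 2 (which a consistency
    ICC must ignore).
    """
    rng = np.random.default_rng(seed)
    subj = rng.normal(mean, between_sd, size=n_subjects)
    t1 = subj + rng.normal(0.0, error_sd, size=n_subjects)
    t2 = subj + trial_offset + rng.normal(0.0, error_sd, size=n_subjects)
    return t1, t2


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class EffectSpec:
    """Treatment effects applied to the post-session ground truth.

    ``rom`` maps (task, joint, plane) to the ROM change in degrees;
    ``rom_diff_sd`` gives the between-subject SD of that paired difference.
    ``stride_time`` / ``speed`` shift stride time (s) and progression speed
    (m/s) per task.
    """

    rom: dict = field(default_factory=dict)
    rom_diff_sd: dict = field(default_factory=dict)
    stride_time: dict = field(default_factory=dict)
    stride_time_diff_sd: dict = field(default_factory=dict)
    speed: dict = field(default_factory=dict)
    speed_diff_sd: dict = field(default_factory=dict)

    @classmethod
    def zero(cls) -> "EffectSpec":
        return cls()

    @staticmethod
    def _implied_diff_sd(diff: float, p: float, n: int = reference.N_PATIENTS) -> float:
        """SD of the paired differences implied by a printed mean difference
        and its paired-t p-value: sd = |diff| * sqrt(n) / t_{1-p/2, n-1}.

        Validated against the rows where a diff SD was printed (self-selected
        speed diff 0.15, p 0.005 implies SD 0.17 vs the printed 0.14)."""
        from scipy.stats import t as tdist
        if abs(diff) < 1e-12 or not 0 < p < 1:
            return 0.0
        tq = tdist.ppf(1.0 - p / 2.0, n - 1)
        return abs(diff) * math.sqrt(n) / tq

    @classmethod
    def from_reference(cls) -> "EffectSpec":
        """Published pre/post effects: printed mean paired differences, with
        between-subject diff SDs implied by the printed p-values."""
        rom, rom_sd, stride, stride_sd, speed, speed_sd = {}, {}, {}, {}, {}, {}
        for r in reference.rows(metric="rom"):
            rom[(r.task, r.joint, r.plane)] = r.diff
            rom_sd[(r.task, r.joint, r.plane)] = cls._implied_diff_sd(r.diff, r.p)
        for r in reference.rows(metric="stride_time"):
            stride[r.task] = r.diff
            stride_sd[r.task] = cls._implied_diff_sd(r.diff, r.p)
        for r in reference.rows(metric="clinical"):
            d = r.post_mean - r.pre_mean
            sd = cls._implied_diff_sd(d, r.p)
            if r.task == "walk_6min":
                speed[r.task] = d / 360.0
                speed_sd[r.task] = sd / 360.0
            else:
                speed[r.task] = d
                speed_sd[r.task] = sd
        return cls(rom=rom, rom_diff_sd=rom_sd, stride_time=stride,
                   stride_time_diff_sd=stride_sd, speed=speed, speed_diff_sd=speed_sd)


def _ml_dominant(params_by_task: dict, min_fraction: float = 0.65) -> bool:
    """Analytic check that each limb segment's angular rate is dominated by
    the medio-lateral axis for every task (small-angle chain composition).

    Walking functional calibration presupposes hinge-like limb rotation; a
    cohort whose members it could not calibrate could not have produced the
    published tables, so subject draws are conditioned on this property.
    """
    phi = np.linspace(0.0, 1.0, 512, endpoint=False)
    chains = {"thigh": ("pelvis", "hip"),
              "shank": ("pelvis", "hip", "knee"),
              "foot": ("pelvis", "hip", "knee", "ankle")}
    for p in params_by_task.values():
        for joints in chains.values():
            var = {}
            for plane in PLANES:
                series = np.zeros_like(phi)
                for joint in joints:
                    amp = p.amplitudes.get((joint, plane), 0.0)
                    if amp > 0:
                        psi = p.phases.get((joint, plane), 0.0)
                        series = series + amp * unit_shape(joint, plane, phi, psi)
                var[plane] = np.var(np.gradient(series))
            total = sum(var.values())
            if total > 0 and var["sagittal"] / total < min_fraction:
                return False
    return True


def _default_between_sd(column: str) -> dict:
    """Between-subject ROM SDs from the published tables; planes without a
    published row get a nominal 30% coefficient of variation."""
    out = {(r.task, r.joint, r.plane): getattr(r, column)
           for r in reference.rows(metric="rom")}
    for task in ("walk_self", "stairs_up", "stairs_down"):
        for (joint, plane), amp in _EXTRA_AMPLITUDES.items():
            out[(task, joint, plane)] = 0.3 * 2.0 * amp
    return out


def _subject_params(
    tasks, group: str, rng: np.random.Generator,
    between_subject_sd, n_cycles: int,
) -> dict:
    for _ in range(25):
        params = _draw_subject_params(tasks, group, rng, between_subject_sd,
                                      n_cycles)
        if _ml_dominant(params):
            return params
    return params   # pathological SD configuration: accept the last draw


def _draw_subject_params(
    tasks, group: str, rng: np.random.Generator,
    between_subject_sd, n_cycles: int,
) -> dict:
    """Per-subject task parameters: group defaults plus subject random effects.

    One standardized factor is drawn per movement plane and applied
    multiplicatively to every joint of that plane in every task
    (amplitude = mean * (1 + z * sd/ROM_mean)): between-subject ROM
    variation is strongly correlated along the kinematic chain, and scaling
    preserves the amplitude ratios that keep simulated limb segments
    sagittally dominated, as real limb segments are.  Stride time and
    progression speed get their own factors.  Factors are truncated at
    +/- 1.75 SD.
    """
    z = {plane: float(np.clip(rng.normal(), -1.75, 1.75))
         for plane in ("sagittal", "frontal", "transverse")}
    z_stride = float(np.clip(rng.normal(), -1.75, 1.75))
    z_speed = float(np.clip(rng.normal(), -1.75, 1.75))
    col = {"healthy": "healthy_sd", "pre": "pre_sd", "post": "pre_sd"}[group]
    params = {}
    for task in tasks:
        p = task_defaults(task, group=group)
        p = replace(p, n_cycles=n_cycles,
                    amplitudes=dict(p.amplitudes), phases=dict(p.phases))
        kin_task = {"walk_fast": "walk_self", "walk_6min": "walk_self"}.get(task, task)
        # one pooled CV per plane: every joint of a plane scales by the same
        # factor, so chain-level amplitude ratios (and hence segment-level
        # axis dominance) survive the subject draw
        cv_plane = {}
        for plane in ("sagittal", "frontal", "transverse"):
            cvs = []
            for (joint, pl), base in p.amplitudes.items():
                if pl != plane or base <= 0:
                    continue
                if isinstance(between_subject_sd, dict):
                    sd = between_subject_sd.get((kin_task, joint, pl), 0.0)
                else:
                    sd = float(between_subject_sd)
                if sd > 0:
                    cvs.append(sd / (2.0 * base))
            cv_plane[plane] = float(np.median(cvs)) if cvs else 0.0
        for key in list(p.amplitudes):
            _, plane = key
            if cv_plane[plane] > 0:
                p.amplitudes[key] *= max(0.3, 1.0 + z[plane] * cv_plane[plane])
        strow = reference.get_row(kin_task, "stride_time")
        # published stride SDs are inflated by outliers (healthy 0.69 s on a
        # 1.15 s mean); between-subject stride CV is capped at a
        # physiological 12%
        cv_t = min(getattr(strow, col) / strow.pre_mean, 0.12)
        p.stride_time_s *= max(0.5, 1.0 + z_stride * cv_t)
        p.speed_mps *= max(0.4, 1.0 + z_speed * 0.25)
        params[task] = p
    return params


def _apply_effect(params: dict, effect: EffectSpec, rng: np.random.Generator) -> dict:
    for _ in range(25):
        out = _draw_effect(params, effect, rng)
        if _ml_dominant(out):
            return out
    return out


def _effect_draw(mean: float, sd: float, rng: np.random.Generator) -> float:
    """Per-subject treatment effect, truncated at +/- 1.75 SD."""
    if sd <= 0:
        return mean
    return mean + sd * float(np.clip(rng.normal(), -1.75, 1.75))


def _draw_effect(params: dict, effect: EffectSpec, rng: np.random.Generator) -> dict:
    """Post parameters: pre parameters shifted by per-subject effect draws,
    clipped into the published post-treatment marginal range (mean +/- 1.75
    SD) so no simulated patient leaves the observed post population."""
    out = {}
    for task, p in params.items():
        kin_task = {"walk_fast": "walk_self", "walk_6min": "walk_self"}.get(task, task)
        p2 = replace(p, amplitudes=dict(p.amplitudes), phases=dict(p.phases))
        for key in list(p2.amplitudes):
            joint, plane = key
            ek = (kin_task, joint, plane)
            if ek in effect.rom:
                d = _effect_draw(effect.rom[ek], effect.rom_diff_sd.get(ek, 0.0), rng)
                base = p2.amplitudes[key]
                post_amp = base + d / 2.0
                try:
                    row = reference.get_row(kin_task, "rom", joint, plane)
                    lo = (row.post_mean - 1.75 * row.post_sd) / 2.0
                    hi = (row.post_mean + 1.75 * row.post_sd) / 2.0
                    post_amp = float(np.clip(post_amp, max(0.25, lo), max(hi, lo)))
                except KeyError:
                    pass
                p2.amplitudes[key] = max(0.25, 0.3 * base, post_amp)
        if kin_task in effect.stride_time:
            d = _effect_draw(effect.stride_time[kin_task],
                             effect.stride_time_diff_sd.get(kin_task, 0.0), rng)
            row = reference.get_row(kin_task, "stride_time")
            cv_post = min(row.post_sd / row.post_mean, 0.12)
            p2.stride_time_s = float(np.clip(
                p2.stride_time_s + d,
                row.post_mean * (1 - 1.75 * cv_post),
                row.post_mean * (1 + 1.75 * cv_post)))
        if task in effect.speed:
            d = _effect_draw(effect.speed[task],
                             effect.speed_diff_sd.get(task, 0.0), rng)
            p2.speed_mps = max(0.2, p2.speed_mps + d)
        out[task] = p2
    return out


def _session_from_params(
    params: dict, tasks, noise: NoiseModel, geometry: SegmentGeometry,
    subject: str, visit: str, seed: int,
) -> tuple:
    parts = [make_gait_profile(params[task], seed=seed + i) for i, task in enumerate(tasks)]
    gt = concat_kinematics(parts)
    session = simulate_imu_session(gt, noise=noise, geometry=geometry,
                                   subject=subject, visit=visit)
    return session, gt


def make_paired_cohort(
    effect_spec: EffectSpec,
    n_subjects: int = reference.N_PATIENTS,
    between_subject_sd=None,
    seed: int = 0,
    noise: NoiseModel = None,
    tasks=("walk_self",),
    n_cycles: int = 8,
    return_truth: bool = False,
) -> list:
    """Pre/post session pairs for a treated cohort.

    The post ground truth is the pre ground truth shifted by ``effect_spec``
    (with per-subject variation from the diff SDs); subject-level random
    effects use ``between_subject_sd`` (scalar ROM SD in degrees, or a dict
    keyed by (task, joint, plane); default: published pre-treatment SDs).
    """
    if n_subjects < 1:
        raise SyntheticParameterError("n_subjects must be >= 1")
    if noise is None:
        noise = NoiseModel()
    if between_subject_sd is None:
        between_subject_sd = _default_between_sd("pre_sd")
    root = np.random.default_rng(seed)
    pairs = []
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(root.integers(2 ** 31))
        pre_params = _subject_params(tasks, "pre", sub_rng, between_subject_sd, n_cycles)
        post_params = _apply_effect(pre_params, effect_spec, sub_rng)
        sid = f"OA{i + 1:02d}"
        out = []
        for visit, params in (("pre", pre_params), ("post", post_params)):
            geom = SegmentGeometry(
                mounting=random_mountings(noise.mounting_sd_deg, sub_rng))
            sess_noise = replace(noise, seed=int(sub_rng.integers(2 ** 31)))
            out.append(_session_from_params(
                params, tasks, sess_noise, geom, sid, visit,
                seed=int(sub_rng.integers(2 ** 31))))
        (pre_s, pre_gt), (post_s, post_gt) = out
        pairs.append(((pre_s, pre_gt), (post_s, post_gt)) if return_truth
                     else (pre_s, post_s))
    return pairs


def make_test_retest(
    n_subjects: int = reference.N_HEALTHY,
    noise: NoiseModel = None,
    seed: int = 0,
    tasks=("walk_self",),
    n_cycles: int = 8,
    between_subject_sd=None,
    return_truth: bool = False,
) -> list:
    """Trial pairs sharing subject-level ground truth; trial noise (sensor
    noise and re-donned mounting rotations) differs between trials."""
    if n_subjects < 3:
        raise SyntheticParameterError("n_subjects must be >= 3")
    if noise is None:
        noise = NoiseModel()
    if between_subject_sd is None:
        between_subject_sd = _default_between_sd("healthy_sd")
    root = np.random.default_rng(seed)
    pairs = []
    for i in range(n_subjects):
        sub_rng = np.random.default_rng(root.integers(2 ** 31))
        params = _subject_params(tasks, "healthy", sub_rng, between_subject_sd, n_cycles)
        kin_seed = int(sub_rng.integers(2 ** 31))
        sid = f"H{i + 1:02d}"
        out = []
        for visit in ("trial1", "trial2"):
            geom = SegmentGeometry(
                mounting=random_mountings(noise.mounting_sd_deg, sub_rng))
            sess_noise = replace(noise, seed=int(sub_rng.integers(2 ** 31)))
            out.append(_session_from_params(
                params, tasks, sess_noise, geom, sid, visit, seed=kin_seed))
        (t1_s, t1_gt), (t2_s, t2_gt) = out
        pairs.append(((t1_s, t1_gt), (t2_s, t2_gt)) if return_truth
                     else (t1_s, t2_s))
    return pairs
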