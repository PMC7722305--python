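"""Sensor orientation estimation and functional sensor-to-segment calibration.

Orientation of each sensor relative to a fixed world frame (Z up along
gravity, X along the horizontal component of the Earth magnetic field) is
estimated with a gradient-corrected complementary filter: gyroscope rates are
integrated and continuously nudged toward the accelerometer gravity direction
(tilt) and the magnetometer heading, with a single scalar gain.  The
accelerometer correction is down-weighted whenever the measured specific
force departs from 1 g, so that linear accelerations during locomotion do not
tilt the estimate; the magnetometer only ever corrects heading.

Sensor-to-segment calibration maps each sensor frame onto the anatomical
frame of the segment it is strapped to (X anterior, Y left, Z up in quiet
standing).  For thigh, shank and foot sensors the medio-lateral axis is
recovered functionally from walking: lower-limb rotation during gait is
dominated by flexion-extension, so the principal direction of the gyroscope
signal over a walking bout estimates the segment's Y axis, with the vertical
axis taken from the gravity direction during standing.  The pelvis rotates
too little and too isotropically for that rule, so its anterior axis is
instead taken from the estimated heading while standing, assuming the
subject faces the direction of progression.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .io_sessions import ImuStream, SessionRecording, PLACEMENTS

logger = logging.getLogger("imugait")

#: Earth magnetic field reference in the world frame, unit norm with the
#: horizontal component along +X and 60 deg downward inclination (Z is up).
MAG_REFERENCE = np.array([0.5, 0.0, -math.sqrt(3.0) / 2.0])

#: Segment name for each sensor placement (1:1 here; the pelvis sensor sits at L5).
SEGMENT_OF_PLACEMENT = {p: p for p in PLACEMENTS}


class CalibrationError(RuntimeError):
    """Raised when the functional calibration cannot be trusted."""


class InitializationError(RuntimeError):
    """Raised when the orientation filter cannot initialize (e.g. free fall)."""


@dataclass
class FusionParams:
    """Tunables of the complementary filter.

    gain
        Correction rate in 1/s pulling the integrated orientation toward the
        accelerometer/magnetometer references.
    init_window_s
        Length of the initial window averaged to seed the orientation.
    accel_band_g
        Half-width of the accelerometer trust band: the tilt correction
        weight falls linearly from 1 to 0 as | ||a|| - 1 g | grows to this.
    gyro_quiet_dps
        The tilt correction is additionally down-weighted in proportion to
        the gyro magnitude, vanishing above this rate, so the accelerometer
        is trusted mostly in the quieter phases of movement where it
        actually points along gravity.
    gyro_bias_dps
        Per-axis gyroscope bias subtracted before integration (deg/s),
        typically estimated from a static interval.
    """

    gain: float = 0.1
    init_window_s: float = 1.0
    accel_band_g: float = 0.1
    gyro_quiet_dps: float = 100.0
    gyro_bias_dps: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class OrientationSeries:
    """Unit quaternions (scalar-first, sensor frame -> world frame) on a time grid."""

    time: np.ndarray
    quat: np.ndarray     # (N, 4), w-first, unit norm, hemisphere-continuous
    fs: float

    def as_rotation(self) -> Rotation:
        # scipy uses xyzw ordering
        return Rotation.from_quat(np.column_stack([self.quat[:, 1:4], self.quat[:, :1]]))

    def validate(self) -> None:
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("quaternions not unit norm")
        dots = np.sum(self.quat[:-1] * self.quat[1:], axis=1)
        if np.any(dots < 0):
            raise ValueError("quaternion hemisphere discontinuity")


@dataclass
class SegmentCalibration:
    """Fixed sensor-frame -> anatomical-segment-frame rotations per segment.

    ``rotations[segment]`` is a proper orthonormal 3x3 matrix C with
    v_segment = C @ v_sensor.  ``qc[segment]`` is in [0, 1]: for the limb
    segments it is the fraction of walking gyroscope variance carried by the
    principal axis; for the pelvis, the confidence of the standing heading.
    """

    rotations: dict
    qc: dict

    def validate(self) -> None:
        for seg, C in self.rotations.items():
            if np.max(np.abs(C @ C.T - np.eye(3))) > 1e-9:
                raise ValueError(f"{seg}: calibration not orthonormal")
            if abs(np.linalg.det(C) - 1.0) > 1e-9:
                raise ValueError(f"{seg}: calibration determinant != +1")


# ---------------------------------------------------------------------------
# Static interval detection
# ---------------------------------------------------------------------------

def detect_static_interval(
    stream: ImuStream,
    gyro_thr_dps: float = 5.0,
    accel_thr_g: float = 0.05,
    min_duration_s: float = 0.3,
    max_gap_s: float = 0.1,
) -> list:
    """Intervals (start, end) of sample indices where the sensor is at rest.

    A sample is static when the gyroscope norm is below ``gyro_thr_dps`` and
    the accelerometer norm deviates from 1 g by less than ``accel_thr_g``;
    sub-threshold gaps shorter than ``max_gap_s`` (isolated noise blips) are
    closed, and maximal static runs at least ``min_duration_s`` long are
    returned.
    """
    if len(stream) < int(0.5 * stream.fs):
        raise ValueError("need at least 0.5 s of data")
    gnorm = np.linalg.norm(stream.gyro, axis=1)
    anorm = np.linalg.norm(stream.accel, axis=1)
    ok = (gnorm < gyro_thr_dps) & (np.abs(anorm - 1.0) < accel_thr_g)
    max_gap = int(round(max_gap_s * stream.fs))
    if max_gap > 0:
        bad = np.flatnonzero(np.diff(np.concatenate([[1], ok.view(np.int8), [1]])))
        for s, e in zip(bad[::2], bad[1::2]):
            if e - s <= max_gap and s > 0 and e < ok.size:
                ok[s:e] = True
    min_len = max(2, int(round(min_duration_s * stream.fs)))
    intervals = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], ok.view(np.int8), [0]])))
    for s, e in zip(edges[::2], edges[1::2]):
        if e - s >= min_len:
            intervals.append((int(s), int(e)))
    return intervals


def estimate_gyro_bias(stream: ImuStream, intervals=None) -> np.ndarray:
    """Mean gyroscope output over the first static interval (deg/s).

    The interval edges (10% each side) are trimmed so that movement onset
    bleeding into the detected static run cannot masquerade as bias.
    """
    if intervals is None:
        intervals = detect_static_interval(stream)
    if not intervals:
        return np.zeros(3)
    s, e = intervals[0]
    margin = (e - s) // 10
    return stream.gyro[s + margin:e - margin].mean(axis=0)


# ---------------------------------------------------------------------------
# Complementary filter
# ---------------------------------------------------------------------------

def _init_orientation(accel: np.ndarray, mag: np.ndarray) -> tuple:
    """Initial quaternion from mean accel (tilt) and mean mag (heading)."""
    a = accel.mean(axis=0)
    an = np.linalg.norm(a)
    if an < 0.2:
        raise InitializationError(
            "accelerometer near zero over the init window (free fall?)"
        )
    z_b = a / an                              # world Z expressed in body frame
    m = mag.mean(axis=0)
    m_h = m - (m @ z_b) * z_b
    mn = np.linalg.norm(m_h)
    if mn < 1e-6:
        # No usable heading; pick an arbitrary horizontal X.
        ref = np.array([1.0, 0.0, 0.0])
        if abs(z_b[0]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        x_b = ref - (ref @ z_b) * z_b
        x_b /= np.linalg.norm(x_b)
    else:
        x_b = m_h / mn                        # world X (mag horizontal) in body frame
    y_b = np.cross(z_b, x_b)
    R = np.vstack([x_b, y_b, z_b])            # rows = world axes in body coords
    q = Rotation.from_matrix(R)
    xq, yq, zq, wq = q.as_quat()
    return (wq, xq, yq, zq)


def estimate_orientation(stream: ImuStream, params: FusionParams = None) -> OrientationSeries:
    """Run the complementary filter over one stream.

    Returns sensor->world quaternions on the stream's time grid.  The gyro
    rate at sample k is treated as the mean body rate over [k, k+1], the
    discretization the synthetic simulator also uses.
    """
    if params is None:
        params = FusionParams()
    n = len(stream)
    fs = stream.fs
    if n < int(fs):
        raise ValueError("need at least 1 s of data")

    n_init = max(1, min(n, int(round(params.init_window_s * fs))))
    w0, x0, y0, z0 = _init_orientation(stream.accel[:n_init], stream.mag[:n_init])

    dt = 1.0 / fs
    gain = params.gain
    band = params.accel_band_g
    bias = np.asarray(params.gyro_bias_dps, dtype=float)
    d2r = math.pi / 180.0

    gx_all = (stream.gyro[:, 0] - bias[0]) * d2r
    gy_all = (stream.gyro[:, 1] - bias[1]) * d2r
    gz_all = (stream.gyro[:, 2] - bias[2]) * d2r
    acc = stream.accel
    mag = stream.mag

    quat = np.empty((n, 4))
    qw, qx, qy, qz = w0, x0, y0, z0
    quat[0] = (qw, qx, qy, qz)

    for k in range(n - 1):
        # world Z and world X expressed in the body frame (rows 3 and 1 of R)
        vzx = 2.0 * (qx * qz - qw * qy)
        vzy = 2.0 * (qy * qz + qw * qx)
        vzz = 1.0 - 2.0 * (qx * qx + qy * qy)
        ex = ey = ez = 0.0

        gx, gy, gz = gx_all[k], gy_all[k], gz_all[k]
        gmag = math.sqrt(gx * gx + gy * gy + gz * gz) * 180.0 / math.pi
        wg = 1.0 - gmag / params.gyro_quiet_dps
        ax, ay, az = acc[k]
        an = math.sqrt(ax * ax + ay * ay + az * az)
        if an > 1e-9 and wg > 0.0:
            wa = (1.0 - abs(an - 1.0) / band) * wg
            if wa > 0.0:
                inv = 1.0 / an
                hx, hy, hz = ax * inv, ay * inv, az * inv
                ex += wa * (hy * vzz - hz * vzy)
                ey += wa * (hz * vzx - hx * vzz)
                ez += wa * (hx * vzy - hy * vzx)

        mx, my, mz = mag[k]
        dotg = mx * vzx + my * vzy + mz * vzz
        hx, hy, hz = mx - dotg * vzx, my - dotg * vzy, mz - dotg * vzz
        hn = math.sqrt(hx * hx + hy * hy + hz * hz)
        if hn > 1e-9:
            inv = 1.0 / hn
            hx, hy, hz = hx * inv, hy * inv, hz * inv
            vxx = 1.0 - 2.0 * (qy * qy + qz * qz)
            vxy = 2.0 * (qx * qy - qw * qz)
            vxz = 2.0 * (qx * qz + qw * qy)
            cx = hy * vxz - hz * vxy
            cy = hz * vxx - hx * vxz
            cz = hx * vxy - hy * vxx
            # heading-only: keep the component about the vertical axis
            dv = cx * vzx + cy * vzy + cz * vzz
            ex += dv * vzx
            ey += dv * vzy
            ez += dv * vzz

        wx = gx + gain * ex
        wy = gy + gain * ey
        wz = gz + gain * ez
        th = math.sqrt(wx * wx + wy * wy + wz * wz) * dt
        if th > 1e-14:
            half = 0.5 * th
            c = math.cos(half)
            s = math.sin(half) / th * dt
            dw, dx, dy, dz = c, wx * s, wy * s, wz * s
        else:
            dw, dx, dy, dz = 1.0, 0.5 * wx * dt, 0.5 * wy * dt, 0.5 * wz * dt
        nw = qw * dw - qx * dx - qy * dy - qz * dz
        nx = qw * dx + qx * dw + qy * dz - qz * dy
        ny = qw * dy - qx * dz + qy * dw + qz * dx
        nz = qw * dz + qx * dy - qy * dx + qz * dw
        norm = math.sqrt(nw * nw + nx * nx + ny * ny + nz * nz)
        inv = 1.0 / norm
        qw, qx, qy, qz = nw * inv, nx * inv, ny * inv, nz * inv
        quat[k + 1] = (qw, qx, qy, qz)

    # hemisphere continuity
    dots = np.sum(quat[:-1] * quat[1:], axis=1)
    flips = np.cumsum(np.concatenate([[0], (dots < 0).astype(int)])) % 2
    quat[flips == 1] *= -1.0
    return OrientationSeries(time=stream.time.copy(), quat=quat, fs=fs)


# ---------------------------------------------------------------------------
# Functional sensor-to-segment calibration
# ---------------------------------------------------------------------------

def _orthonormal_from_zy(z_s: np.ndarray, y_s: np.ndarray) -> np.ndarray:
    """Rows [x; y; z] of the calibration matrix from segment Z and Y in sensor coords."""
    z = z_s / np.linalg.norm(z_s)
    y = y_s - (y_s @ z) * z
    y /= np.linalg.norm(y)
    x = np.cross(y, z)
    return np.vstack([x, y, z])


def functional_calibration(
    session: SessionRecording,
    orientations: dict,
    walk_interval: tuple,
    static_interval: tuple,
    min_variance_fraction: float = 0.6,
) -> SegmentCalibration:
    """Derive per-segment sensor-to-segment rotations from a walking bout.

    Parameters
    ----------
    orientations
        placement -> :class:`OrientationSeries` (sensor->world) for the session.
    walk_interval, static_interval
        (start, end) sample indices of a walking bout (>= 5 cycles) and of a
        quiet-standing interval.

    For limb segments the anatomical Z comes from the mean standing gravity
    direction and the medio-lateral Y from the principal direction of the
    walking gyroscope signal; the sign of Y is fixed so it points to the
    subject's left, using the estimated world heading (progression along
    world X).  This makes flexion positive forward.  Pelvis: Z from gravity,
    X anterior from the standing heading.

    Raises
    ------
    CalibrationError
        If the principal axis carries less than ``min_variance_fraction`` of
        the gyro variance on a limb segment.
    """
    s0, s1 = static_interval
    w0, w1 = walk_interval
    rotations = {}
    qc = {}
    y_world = np.array([0.0, 1.0, 0.0])   # left, for progression along +X

    for placement in PLACEMENTS:
        stream = session.streams[placement]
        z_s = stream.accel[s0:s1].mean(axis=0)
        if np.linalg.norm(z_s) < 0.2:
            raise CalibrationError(f"{placement}: no usable gravity in static interval")
        R_ws = orientations[placement].as_rotation()

        if placement == "pelvis_L5":
            # anterior = world X seen from the sensor while standing
            x_world_in_b = R_ws[s0:s1].inv().apply(np.array([1.0, 0.0, 0.0]))
            x_s = x_world_in_b.mean(axis=0)
            conf = float(np.clip(np.linalg.norm(x_s), 0.0, 1.0))
            z = z_s / np.linalg.norm(z_s)
            x = x_s - (x_s @ z) * z
            x /= np.linalg.norm(x)
            y = np.cross(z, x)
            rotations[placement] = np.vstack([x, y, z])
            qc[placement] = conf
            continue

        gyro = stream.gyro[w0:w1]
        g0 = gyro - gyro.mean(axis=0)
        # rate-magnitude-squared weighting emphasizes the swing phase, where
        # the rotation is most purely about the medio-lateral axis
        wts = np.sum(g0 * g0, axis=1)
        wsum = max(wts.sum(), 1e-12)
        cov = (g0 * wts[:, None]).T @ g0 / wsum
        evals, evecs = np.linalg.eigh(cov)
        frac = float(evals[-1] / max(evals.sum(), 1e-12))
        u = evecs[:, -1]
        if frac < min_variance_fraction:
            raise CalibrationError(
                f"{placement}: principal gyro axis carries only {frac:.2f} of the "
                f"variance (< {min_variance_fraction}); calibration rejected"
            )
        # Sign: the medio-lateral axis, carried to the world frame over the
        # walking bout, must point left of the progression direction.
        u_world = R_ws[w0:w1].apply(u).mean(axis=0)
        if u_world @ y_world < 0:
            u = -u
        # With the vertical axis pinned by gravity, only the azimuth of the
        # medio-lateral axis remains free.  The gyro principal axis vets the
        # hinge-likeness of the movement (QC above) but its azimuth carries a
        # rigid-body coupling bias (omega_x ~ flexion rate x axial tilt), so
        # the azimuth is taken from the straight-walking constraint instead:
        # the mean medio-lateral direction is horizontal and perpendicular to
        # the progression heading.
        y_s = R_ws[w0:w1].inv().apply(y_world).mean(axis=0)
        if np.degrees(np.arccos(np.clip(abs(u @ y_s / np.linalg.norm(y_s)), 0, 1))) > 30.0:
            logger.warning("%s: gyro principal axis deviates >30 deg from the "
                           "heading-derived medio-lateral axis", placement)
        rotations[placement] = _orthonormal_from_zy(z_s, y_s)
        qc[placement] = frac

    calib = SegmentCalibration(rotations=rotations, qc=qc)
    calib.validate()
    return calib


def calibration_angle_deg(C: np.ndarray, M: np.ndarray) -> float:
    """Rotation angle (deg) between two calibration matrices; 0 = identical."""
    return float(np.degrees(np.abs(Rotation.from_matrix(C @ M.T).magnitude())))
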