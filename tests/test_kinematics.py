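import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import imugait as ig
from imugait.kinematics import (
    NonFiniteCurveError, joint_rotation, rotation_to_joint_angles,
)
from imugait.segmentation import NormalizedCycle


class _OS:
    """Minimal orientation-series stand-in wrapping a scipy Rotation."""

    def __init__(self, rot, fs=128.0):
        self._r, self.fs = rot, fs

    def as_rotation(self):
        return self._r


# ---------------------------------------------------------------------------
# Euler convention and joint angles
# ---------------------------------------------------------------------------

@given(st.tuples(st.floats(-80, 80), st.floats(-60, 60), st.floats(-80, 80)))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_joint_rotation_round_trip(angles):
    back = rotation_to_joint_angles(joint_rotation(np.array(angles)))
    np.testing.assert_allclose(back[0], angles, atol=1e-9)


def test_identical_orientations_give_zero_angles():
    r = Rotation.from_euler("xyz", np.random.default_rng(0).normal(size=(50, 3)))
    ja = ig.joint_angles(_OS(r), _OS(r), np.eye(3), np.eye(3), joint="knee")
    np.testing.assert_allclose(ja.angles, 0.0, atol=1e-8)


def test_pure_hinge_maps_to_sagittal_only():
    """Hinge rotation theta(t) about the shared flexion axis: sagittal equals
    theta, frontal and transverse stay zero."""
    theta = np.linspace(-40, 70, 200)
    prox = Rotation.identity(200)
    dist = joint_rotation(np.column_stack([theta, np.zeros(200), np.zeros(200)]))
    ja = ig.joint_angles(_OS(prox), _OS(dist), np.eye(3), np.eye(3))
    np.testing.assert_allclose(ja.plane("sagittal"), theta, atol=1e-6)
    np.testing.assert_allclose(ja.plane("frontal"), 0.0, atol=1e-6)
    np.testing.assert_allclose(ja.plane("transverse"), 0.0, atol=1e-6)


def test_gimbal_proximity_flagged():
    ang = np.zeros((5, 3))
    ang[2, 1] = 88.0
    dist = joint_rotation(ang)
    ja = ig.joint_angles(_OS(Rotation.identity(5)), _OS(dist), np.eye(3), np.eye(3))
    assert ja.gimbal_flags[2] and not ja.gimbal_flags[0]


def test_full_pipeline_angle_rms_under_2_degrees(clean_session, clean_orientations,
                                                 clean_calibration, walk_gt):
    """Noise-free synthetic gait: recovered joint angles within 2 deg RMS of
    the generator truth in every plane."""
    segs = {"hip": ("pelvis_L5", "thigh_R"), "knee": ("thigh_R", "shank_R"),
            "ankle": ("shank_R", "foot_R")}
    sl = slice(256, 1792)   # walking portion
    for joint, (ps, ds) in segs.items():
        ja = ig.joint_angles(clean_orientations[ps], clean_orientations[ds],
                             clean_calibration.rotations[ps],
                             clean_calibration.rotations[ds], joint=joint)
        err = ja.angles[sl] - walk_gt.angles[(joint, "R")][sl]
        rms = np.sqrt(np.mean(err ** 2, axis=0))
        assert np.all(rms < 2.0), f"{joint}: {rms}"
    pa = ig.pelvis_angles(clean_orientations["pelvis_L5"],
                          clean_calibration.rotations["pelvis_L5"])
    err = pa.angles[sl] - walk_gt.angles[("pelvis", "")][sl]
    assert np.all(np.sqrt(np.mean(err ** 2, axis=0)) < 2.0)


# ---------------------------------------------------------------------------
# Angular velocity
# ---------------------------------------------------------------------------

def test_velocity_exact_on_linear_ramp():
    fs = 128.0
    x = 3.7 * np.arange(100) / fs
    v = ig.angular_velocity(x, fs)
    np.testing.assert_allclose(v[1:-1], 3.7, atol=1e-9)


def test_velocity_peak_of_sine_closed_form():
    """A sin(2 pi f t) with A=30 deg, f=1 Hz at 128 Hz: peak velocity within
    0.1% of 2 pi f A = 188.50 deg/s."""
    fs, A, f = 128.0, 30.0, 1.0
    t = np.arange(int(4 * fs)) / fs
    v = ig.angular_velocity(A * np.sin(2 * np.pi * f * t), fs)
    assert v.max() == pytest.approx(2 * np.pi * f * A, rel=1e-3)


def test_velocity_matches_loop_oracle():
    rng = np.random.default_rng(3)
    x = rng.normal(size=257)
    fs = 128.0
    v = ig.angular_velocity(x, fs)
    expected = np.empty_like(x)
    for k in range(1, len(x) - 1):
        expected[k] = (x[k + 1] - x[k - 1]) * fs / 2.0
    expected[0] = (x[1] - x[0]) * fs
    expected[-1] = (x[-1] - x[-2]) * fs
    np.testing.assert_allclose(v, expected, atol=1e-12)


# ---------------------------------------------------------------------------
# Range metric
# ---------------------------------------------------------------------------

def test_range_constant_curve_is_zero():
    assert ig.range_metric(np.full(101, 7.5)) == 0.0


def test_range_of_sine_is_twice_amplitude():
    x = 4.65 * np.sin(2 * np.pi * np.linspace(0, 1, 101))
    assert ig.range_metric(x) == pytest.approx(9.3, abs=1e-6)


def test_range_matches_exhaustive_scan():
    rng = np.random.default_rng(9)
    x = rng.normal(size=101)
    best = -np.inf
    for a in x:
        for b in x:
            best = max(best, a - b)
    assert ig.range_metric(x) == pytest.approx(best, abs=1e-12)


def test_range_rejects_non_finite():
    x = np.zeros(101)
    x[3] = np.nan
    with pytest.raises(NonFiniteCurveError):
        ig.range_metric(x)


@given(st.floats(-100, 100), st.floats(0.1, 10))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_range_shift_invariant_and_scale_linear(shift, scale):
    rng = np.random.default_rng(0)
    x = rng.normal(size=101)
    base = ig.range_metric(x)
    assert ig.range_metric(x + shift) == pytest.approx(base, rel=1e-9, abs=1e-9)
    assert ig.range_metric(x * scale) == pytest.approx(base * scale, rel=1e-9)


def test_range_accepts_normalized_cycle():
    cyc = NormalizedCycle(mean=np.linspace(0, 5, 101), sd=np.zeros(101), n_cycles=3)
    assert ig.range_metric(cyc) == pytest.approx(5.0)


# ---------------------------------------------------------------------------
# Spatiotemporal and clinical metrics
# ---------------------------------------------------------------------------

def test_regular_contacts_give_exact_stride_and_cadence():
    """Contacts every 1.20 s: stride 1.20 s, cadence 50 cycles/min."""
    fs = 128.0
    events = ig.GaitEvents(contacts={"R": (np.arange(6) * 1.2 * fs).astype(int)},
                           fs=fs)
    stride, cad = ig.spatiotemporal(events, fs)
    assert stride == pytest.approx(1.2, abs=1e-3)
    assert cad == pytest.approx(60.0 / stride, abs=1e-9)


def test_irregular_contacts_average():
    fs = 1000.0
    c = np.cumsum([0.0, 1.0, 1.2, 1.4]) * fs
    events = ig.GaitEvents(contacts={"R": c.astype(int)}, fs=fs)
    stride, _ = ig.spatiotemporal(events, fs)
    assert stride == pytest.approx(1.2, abs=1e-3)


def test_single_contact_is_an_error():
    events = ig.GaitEvents(contacts={"R": np.array([100])}, fs=128.0)
    with pytest.raises(ValueError):
        ig.spatiotemporal(events, 128.0)


def test_cadence_times_stride_is_sixty(walk_gt, clean_session):
    m = ig.analyze_session(clean_session, ig.PipelineConfig(tasks=("walk_self",)))
    for task in m.stride_time:
        assert m.cadence[task] * m.stride_time[task] == pytest.approx(60.0, abs=1e-6)


def test_ten_meter_speed():
    """10 m in 12.35 s is 0.81 m/s."""
    clin = ig.clinical_metrics({"walk_self": 12.35}, {})
    assert clin.self_selected_speed_mps == pytest.approx(0.81, abs=0.005)


def test_zero_duration_is_an_error():
    with pytest.raises(ValueError):
        ig.clinical_metrics({"walk_self": 0.0}, {})


def test_six_min_distance_passthrough():
    clin = ig.clinical_metrics({}, {"walk_6min": 286.0})
    assert clin.six_min_distance_m == 286.0
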