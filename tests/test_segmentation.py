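import numpy as np
import pytest

import imugait as ig
from imugait.segmentation import (
    InsufficientCyclesError, SegmentationError, select_stable_cycles,
)


# ---------------------------------------------------------------------------
# Task segmentation
# ---------------------------------------------------------------------------

def test_single_walk_bout_boundaries(clean_session, walk_gt):
    """Stand-walk-stand: one auto bout within 0.25 s of the true span."""
    bouts = ig.segment_tasks(clean_session, ["walk_self"])
    assert len(bouts) == 1
    b = bouts[0]
    assert b.source == "auto"
    task, t0, t1 = walk_gt.annotations[0]
    fs = clean_session.fs
    # motion begins/ends one transition ramp outside the annotated cycles
    ramp = 0.4
    assert abs(b.start / fs - (t0 - ramp)) <= 0.25
    assert abs(b.end / fs - (t1 + ramp)) <= 0.25


def test_all_static_session_has_no_bouts(static_stream):
    n = len(static_stream)
    streams = {p: ig.ImuStream(placement=p, time=static_stream.time,
                               accel=np.tile([0, 0, 1.0], (n, 1)),
                               gyro=np.zeros((n, 3)),
                               mag=np.tile(ig.MAG_REFERENCE, (n, 1)))
               for p in ig.PLACEMENTS}
    sess = ig.SessionRecording(subject="X", visit="pre", streams=streams)
    with pytest.raises(SegmentationError, match="0 active bout"):
        ig.segment_tasks(sess, ["walk_self"])


def test_two_walks_separated_by_stand(walk_params):
    """Two walk bouts around a 3 s stand come back ordered and labeled."""
    import dataclasses
    p1 = dataclasses.replace(walk_params, n_cycles=6, lead_out_s=3.0,
                             amplitudes=dict(walk_params.amplitudes))
    p2 = dataclasses.replace(walk_params, n_cycles=6, lead_in_s=0.0,
                             amplitudes=dict(walk_params.amplitudes))
    gt = ig.concat_kinematics([ig.make_gait_profile(p1, seed=0),
                               ig.make_gait_profile(p2, seed=1)])
    sess = ig.simulate_imu_session(gt, noise=ig.ZERO_NOISE)
    bouts = ig.segment_tasks(sess, ["walk_self", "walk_fast"])
    assert [b.task for b in bouts] == ["walk_self", "walk_fast"]
    assert bouts[0].end <= bouts[1].start


# ---------------------------------------------------------------------------
# Initial-contact detection
# ---------------------------------------------------------------------------

def _detect(session, gt, side="R"):
    ors = {p: ig.estimate_orientation(s) for p, s in session.streams.items()}
    statics = ig.detect_static_interval(session.streams["pelvis_L5"])
    bout = ig.segment_tasks(session, ["walk_self"])[0]
    calib = ig.functional_calibration(session, ors, (bout.start, bout.end),
                                      statics[0])
    vert = ors[f"shank_{side}"].as_rotation().apply(
        session.streams[f"shank_{side}"].accel)[:, 2] - 1.0
    hip = ig.joint_angles(ors["pelvis_L5"], ors[f"thigh_{side}"],
                          calib.rotations["pelvis_L5"],
                          calib.rotations[f"thigh_{side}"]).plane("sagittal")
    knee = ig.joint_angles(ors[f"thigh_{side}"], ors[f"shank_{side}"],
                           calib.rotations[f"thigh_{side}"],
                           calib.rotations[f"shank_{side}"]).plane("sagittal")
    sl = slice(bout.start, bout.end)
    return ig.detect_initial_contacts(vert[sl], hip[sl], knee[sl],
                                      session.fs) + bout.start


@pytest.mark.parametrize("side", ["R", "L"])
def test_noise_free_contacts_exact(clean_session, walk_gt, side):
    """10-cycle noise-free walk: 11 contacts per side within +/- 3 samples."""
    detected = _detect(clean_session, walk_gt, side)
    true = walk_gt.events[side]
    assert len(detected) == 11
    offsets = np.abs(detected[:, None] - true[None, :]).min(axis=1)
    assert np.all(offsets <= 3)


def test_noisy_contacts_matched_without_spurious(noisy_session, walk_gt):
    """Default noise: >= 90% of true contacts within +/- 5 samples and no
    spurious extras after gating."""
    for side in ("R", "L"):
        detected = _detect(noisy_session, walk_gt, side)
        true = walk_gt.events[side]
        per_true = np.abs(detected[:, None] - true[None, :]).min(axis=0)
        assert np.mean(per_true <= 5) >= 0.9
        per_det = np.abs(detected[:, None] - true[None, :]).min(axis=1)
        assert np.all(per_det <= 5), "spurious detections"


def test_constant_signals_are_insufficient():
    with pytest.raises(InsufficientCyclesError):
        ig.detect_initial_contacts(np.zeros(1280), np.zeros(1280),
                                   np.zeros(1280), 128.0)


# ---------------------------------------------------------------------------
# Cycle selection and normalization
# ---------------------------------------------------------------------------

def _brute_force_selection(durations, n_select):
    med = np.median(durations)
    best, best_cost = None, np.inf
    n_win = len(durations) - n_select + 1
    center = (n_win - 1) / 2
    for i in range(n_win):
        cost = np.abs(np.asarray(durations[i:i + n_select]) - med).sum()
        key = (round(cost, 12), abs(i - center), i)
        if best is None or key < best_key:
            best, best_key = i, key
    return best


def test_duration_stable_triple_selection():
    """Durations {1.1, 1.2, 1.2, 1.2, 1.4} s: cycles 2-4 are selected."""
    contacts = np.cumsum([0.0, 1.1, 1.2, 1.2, 1.2, 1.4]) * 128
    i0, i1 = select_stable_cycles(contacts, n_select=3)
    assert (i0, i1) == (1, 4)


@pytest.mark.parametrize("seed", range(5))
def test_selection_matches_brute_force(seed):
    rng = np.random.default_rng(seed)
    durations = rng.uniform(0.9, 1.5, size=8)
    contacts = np.concatenate([[0.0], np.cumsum(durations)]) * 128
    i0, _ = select_stable_cycles(contacts, n_select=3)
    assert i0 == _brute_force_selection(durations, 3)


def test_identical_cycles_average_to_one_cycle():
    """Identical cycles: mean equals any single cycle, SD is 0 pointwise."""
    period = 128
    x = np.sin(2 * np.pi * np.arange(5 * period + 1) / period)
    contacts = np.arange(0, 5 * period + 1, period)
    cyc = ig.extract_normalized_cycles(x, contacts, n_select=3)
    single = np.interp(np.linspace(0, period, 101), np.arange(len(x)), x)
    np.testing.assert_allclose(cyc.mean, single, atol=1e-9)
    np.testing.assert_allclose(cyc.sd, 0.0, atol=1e-12)
    assert cyc.n_cycles == 3


def test_periodic_signal_endpoints_close():
    period = 150
    x = np.sin(2 * np.pi * np.arange(6 * period + 1) / period)
    contacts = np.arange(0, 6 * period + 1, period)
    cyc = ig.extract_normalized_cycles(x, contacts)
    assert abs(cyc.mean[0] - cyc.mean[100]) < 1e-3


def test_renormalization_is_idempotent():
    rng = np.random.default_rng(1)
    curve = np.cumsum(rng.normal(size=101))
    again = ig.extract_normalized_cycles(curve, np.array([0, 100]), n_select=1)
    np.testing.assert_allclose(again.mean, curve, atol=1e-9)


def test_selection_independent_for_periodic_signals():
    """For a signal periodic with the event period, the average does not
    depend on which cycles are selected."""
    period = 128
    x = np.sin(2 * np.pi * np.arange(8 * period + 1) / period) + \
        0.3 * np.cos(4 * np.pi * np.arange(8 * period + 1) / period)
    contacts = np.arange(0, 8 * period + 1, period)
    ref = None
    for start in range(5):
        cyc = ig.extract_normalized_cycles(x, contacts[start:start + 4], n_select=3)
        if ref is None:
            ref = cyc.mean
        np.testing.assert_allclose(cyc.mean, ref, atol=1e-6)


def test_too_few_cycles_error_states_count():
    with pytest.raises(InsufficientCyclesError, match="2"):
        ig.extract_normalized_cycles(np.arange(300.0), np.array([0, 100, 200]),
                                     n_select=3)
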