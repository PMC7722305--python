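"""Task segmentation, initial-contact detection and gait-cycle normalization.

Tasks are segmented with threshold rules on the accelerometer signals: flat
zones (quiet standing) are found on the pelvis sensor, and the spans between
flat zones count as active bouts when the shank accelerometer shows a
sufficient rate of step peaks.  Initial contacts are the heel-strike
transients of the world-vertical shank acceleration, gated by the hip and
knee sagittal angles (at contact the hip is near its cycle maximum of
flexion and the knee is extending).  A gait cycle runs from one foot contact
to the next contact of the same foot; selected cycles are linearly resampled
onto 101 points (0..100% of the cycle) and averaged pointwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .io_sessions import SessionRecording
from .orientation import detect_static_interval

logger = logging.getLogger("imugait")


class SegmentationError(RuntimeError):
    pass


class InsufficientCyclesError(SegmentationError):
    pass


@dataclass
class TaskBout:
    task: str
    start: int            # sample index, inclusive
    end: int              # sample index, exclusive
    source: str = "auto"  # "auto" | "annotation"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("bout end must be after start")

    @property
    def n_samples(self) -> int:
        return self.end - self.start


@dataclass
class GaitEvents:
    """Strictly increasing initial-contact sample indices per side."""

    contacts: dict                     # side "L"/"R" -> int array
    fs: float = 128.0

    def __post_init__(self) -> None:
        for side, c in self.contacts.items():
            c = np.asarray(c, dtype=int)
            self.contacts[side] = c
            if len(c) >= 2:
                gaps = np.diff(c) / self.fs
                if np.any(gaps <= 0):
                    raise ValueError(f"{side}: contacts not strictly increasing")
                if np.any(gaps < 0.4) or np.any(gaps > 5.0):
                    raise ValueError(
                        f"{side}: inter-contact interval outside [0.4, 5] s"
                    )


@dataclass
class NormalizedCycle:
    """Pointwise mean and SD of cycles resampled on 0..100% (101 points)."""

    mean: np.ndarray
    sd: np.ndarray
    n_cycles: int

    def __post_init__(self) -> None:
        if self.mean.shape[0] != 101 or self.sd.shape[0] != 101:
            raise ValueError("normalized cycles have exactly 101 points")
        if np.any(self.sd < -1e-12):
            raise ValueError("pointwise SD must be non-negative")


# ---------------------------------------------------------------------------
# Task segmentation
# ---------------------------------------------------------------------------

def segment_tasks(
    session: SessionRecording,
    task_order: list,
    gyro_thr_dps: float = 5.0,
    accel_thr_g: float = 0.05,
    min_flat_s: float = 0.5,
    min_step_rate_hz: float = 0.4,
    min_bout_s: float = 1.0,
) -> list:
    """Flat-zone / peak-rate task segmentation.

    Flat zones are static intervals of the pelvis sensor; candidate bouts are
    the maximal spans between flat zones.  A span is kept when either shank's
    accelerometer-norm peak rate (peaks above median + 3 MAD, 0.4 s apart)
    exceeds ``min_step_rate_hz``.  Kept bouts are labeled in ``task_order``;
    finding fewer bouts than tasks is an error listing what was found.
    """
    pelvis = session.streams["pelvis_L5"]
    fs = session.fs
    flats = detect_static_interval(
        pelvis, gyro_thr_dps=gyro_thr_dps, accel_thr_g=accel_thr_g,
        min_duration_s=min_flat_s,
    )
    n = len(pelvis)
    active = np.ones(n, dtype=bool)
    for s, e in flats:
        active[s:e] = False

    edges = np.flatnonzero(np.diff(np.concatenate([[0], active.view(np.int8), [0]])))
    spans = [(int(s), int(e)) for s, e in zip(edges[::2], edges[1::2])
             if e - s >= int(min_bout_s * fs)]

    bouts = []
    for s, e in spans:
        rate = 0.0
        for shank in ("shank_L", "shank_R"):
            anorm = np.linalg.norm(session.streams[shank].accel[s:e], axis=1)
            med = np.median(anorm)
            mad = np.median(np.abs(anorm - med))
            # cap the adaptive threshold relative to the span's own peaks so
            # that very dynamic bouts (stairs) still count their step impacts
            thr = med + min(3.0 * max(mad, 1e-6), 0.6 * (anorm.max() - med))
            peaks, _ = find_peaks(anorm, height=thr, distance=int(0.4 * fs))
            rate = max(rate, len(peaks) / ((e - s) / fs))
        if rate >= min_step_rate_hz:
            bouts.append((s, e))

    if len(bouts) < len(task_order):
        raise SegmentationError(
            f"found {len(bouts)} active bout(s) {bouts} but expected "
            f"{len(task_order)} tasks {list(task_order)}"
        )
    if len(bouts) > len(task_order):
        logger.warning("more active bouts (%d) than tasks (%d); keeping the longest",
                       len(bouts), len(task_order))
        bouts = sorted(sorted(bouts, key=lambda b: b[0] - b[1])[: len(task_order)])
    return [TaskBout(task=t, start=s, end=e, source="auto")
            for t, (s, e) in zip(task_order, bouts)]


# ---------------------------------------------------------------------------
# Initial-contact detection
# ---------------------------------------------------------------------------

def detect_initial_contacts(
    shank_vertical_accel: np.ndarray,
    hip_sagittal: np.ndarray,
    knee_sagittal: np.ndarray,
    fs: float,
    mad_k: float = 3.0,
    refractory_s: float = 0.4,
    hip_gate_fraction: float = 0.3,
    gate_window_s: float = 0.45,
    relative_height: float = 0.35,
) -> np.ndarray:
    """Initial contacts for one side within one bout, as sample indices.

    Candidates are peaks of the world-vertical shank acceleration above an
    adaptive threshold (median + ``mad_k`` * MAD) separated by at least the
    refractory period.  A candidate is accepted when, in a +/-
    ``gate_window_s`` local window, the hip sagittal angle is within
    ``hip_gate_fraction`` of that window's maximum (hip flexion peaks around
    contact) and the knee sagittal angle is decreasing (knee extending).  A
    second adaptive pass drops candidates smaller than ``relative_height``
    times the typical (median of upper half) candidate height, so smooth
    movement transients do not masquerade as heel strikes.
    """
    a = np.asarray(shank_vertical_accel, dtype=float)
    n = a.shape[0]
    if n < 3 or np.ptp(a) < 1e-12:
        raise InsufficientCyclesError("signal too short or constant")
    med = np.median(a)
    mad = np.median(np.abs(a - med))
    # adaptive threshold, capped relative to the signal's own peaks so that
    # very dynamic bouts keep their heel-strike candidates
    thr = med + min(mad_k * max(mad, 1e-9), 0.6 * (a.max() - med))
    peaks, _ = find_peaks(a, height=thr, distance=max(1, int(refractory_s * fs)))
    if peaks.size:
        heights = a[peaks]
        top = np.sort(heights)[heights.size // 2:]
        peaks = peaks[heights >= relative_height * np.median(top)]

    # smoothed knee slope for the "extending" gate
    knee_v = np.gradient(np.asarray(knee_sagittal, dtype=float))
    if n >= 7:
        kernel = np.ones(7) / 7.0
        knee_v = np.convolve(knee_v, kernel, mode="same")

    half = max(1, int(gate_window_s * fs))
    accepted = []
    for p in peaks:
        lo, hi = max(0, p - half), min(n, p + half + 1)
        win = hip_sagittal[lo:hi]
        rng = np.ptp(win)
        hip_ok = rng < 1e-9 or hip_sagittal[p] >= win.max() - hip_gate_fraction * rng
        knee_ok = knee_v[p] < 0
        if hip_ok and knee_ok:
            accepted.append(int(p))
    if len(accepted) < 2:
        raise InsufficientCyclesError(
            f"only {len(accepted)} initial contact(s) detected"
        )
    return np.asarray(accepted, dtype=int)


# ---------------------------------------------------------------------------
# Cycle extraction and normalization
# ---------------------------------------------------------------------------

def select_stable_cycles(contacts: np.ndarray, n_select: int = 3) -> tuple:
    """Indices (first, last+1) of the ``n_select`` consecutive cycles whose
    durations deviate least (summed absolute deviation) from the median cycle
    duration; ties prefer the most mid-bout window, then the earliest."""
    durations = np.diff(np.asarray(contacts, dtype=float))
    n_cyc = len(durations)
    if n_cyc < n_select:
        raise InsufficientCyclesError(
            f"need {n_select} complete cycles, only {n_cyc} available"
        )
    med = np.median(durations)
    n_win = n_cyc - n_select + 1
    costs = np.array([np.abs(durations[i:i + n_select] - med).sum()
                      for i in range(n_win)])
    best = np.min(costs)
    candidates = np.flatnonzero(np.abs(costs - best) < 1e-12)
    center = (n_win - 1) / 2.0
    start = int(min(candidates, key=lambda i: (abs(i - center), i)))
    return start, start + n_select


def extract_normalized_cycles(
    signal: np.ndarray,
    contacts: np.ndarray,
    n_select: int = 3,
) -> NormalizedCycle:
    """Resample the selected cycles of ``signal`` onto 101 points and average.

    ``contacts`` are same-side initial-contact sample indices delimiting the
    cycles; each selected cycle is linearly interpolated at 101 equally
    spaced cycle fractions (endpoints inclusive).
    """
    sig = np.asarray(signal, dtype=float)
    contacts = np.asarray(contacts, dtype=float)
    i0, i1 = select_stable_cycles(contacts, n_select=n_select)
    frac = np.linspace(0.0, 1.0, 101)
    grid = np.arange(sig.shape[0], dtype=float)
    curves = np.empty((n_select, 101))
    for j, k in enumerate(range(i0, i1)):
        a, b = contacts[k], contacts[k + 1]
        curves[j] = np.interp(a + frac * (b - a), grid, sig)
    return NormalizedCycle(
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=0),
        n_cycles=n_select,
    )
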