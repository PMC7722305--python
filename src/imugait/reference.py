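"""Published cohort reference statistics used as generator targets.

Group summary values from a clinical study of genicular nerve blockade in 14
knee-osteoarthritis patients (assessed 1 h before and 1 h after the
injection, most painful leg) with a 12-subject healthy test-retest reference
group.  Each row carries pre / post mean (SD), the paired-test p-value, the
printed mean difference, the SEM from the healthy test-retest analysis, and
the healthy group mean (SD).

These numbers serve three purposes in this package: they parameterize the
synthetic demo cohort (effect sizes, stride times, ROM magnitudes), they
populate the healthy-reference column of the report tables, and they are the
inputs to the difference / percent-change arithmetic recomputed by the
acceptance script.  Note that a few printed differences are not equal to
post minus pre of the printed means (group means were presumably rounded, or
pairs deleted); the pipeline always computes paired differences from raw
pairs and never back-fills from these summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

TASKS = ("walk_self", "walk_fast", "stairs_up", "stairs_down", "walk_6min")

N_PATIENTS = 14
N_HEALTHY = 12


@dataclass(frozen=True)
class ReferenceRow:
    task: str          # walking | stairs_up | stairs_down | clinical task id
    metric: str        # "rom" | "speed" | "stride_time" | "cadence" | "clinical"
    joint: str         # pelvis | hip | knee | ankle | "" for non-joint rows
    plane: str         # sagittal | frontal | transverse | ""
    pre_mean: float
    pre_sd: float
    post_mean: float
    post_sd: float
    p: float
    diff: float        # printed mean paired difference (post - pre)
    sem: float         # standard error of measurement (healthy test-retest)
    healthy_mean: float
    healthy_sd: float


_R = ReferenceRow

ROWS = [
    # --- clinical -----------------------------------------------------------
    _R("walk_6min", "clinical", "", "", 286, 137, 319, 127, 0.037, 58, 36, 530, 139),
    _R("walk_fast", "clinical", "", "", 1.07, 0.35, 1.19, 0.35, 0.004, 0.17, 0.12, 1.45, 0.33),
    _R("walk_self", "clinical", "", "", 0.81, 0.27, 0.96, 0.27, 0.005, 0.15, 0.11, 1.19, 0.29),
    # --- walking: spatiotemporal and ROM (deg) ------------------------------
    _R("walk_self", "stride_time", "", "", 1.20, 0.14, 1.15, 0.07, 0.248, -0.05, 0.03, 1.15, 0.69),
    _R("walk_self", "cadence", "", "", 50.7, 5.8, 52.4, 3.4, 0.319, 1.7, 1.5, 60.4, 16.8),
    _R("walk_self", "rom", "pelvis", "sagittal", 5.9, 2.8, 6.2, 3.0, 0.484, 0.3, 1.5, 7.1, 2.6),
    _R("walk_self", "rom", "pelvis", "frontal", 5.3, 2.2, 6.2, 3.2, 0.321, 0.9, 1.6, 7.5, 1.8),
    _R("walk_self", "rom", "pelvis", "transverse", 7.5, 3.4, 8.4, 3.5, 0.152, 0.9, 1.9, 7.6, 3.2),
    _R("walk_self", "rom", "hip", "sagittal", 28.6, 9.3, 37.9, 7.3, 0.004, 9.3, 4.6, 20.3, 6.0),
    _R("walk_self", "rom", "hip", "frontal", 13.6, 5.2, 16.6, 9.1, 0.287, 2.9, 3.3, 9.5, 2.5),
    _R("walk_self", "rom", "hip", "transverse", 15.0, 6.5, 18.4, 7.3, 0.041, 3.5, 3.5, 15.6, 4.6),
    _R("walk_self", "rom", "knee", "sagittal", 47.0, 17.1, 55.8, 6.0, 0.094, 8.8, 7.1, 68.2, 8.6),
    _R("walk_self", "rom", "ankle", "sagittal", 27.5, 6.5, 31.6, 6.1, 0.244, 4.1, 6.2, 49.4, 8.6),
    # --- stairs up ----------------------------------------------------------
    _R("stairs_up", "stride_time", "", "", 1.84, 0.79, 1.45, 0.42, 0.001, -0.4, 0.1, 1.26, 0.43),
    _R("stairs_up", "cadence", "", "", 36.4, 10.7, 44.1, 9.8, 0.001, 7.7, 3.6, 51.0, 11.5),
    _R("stairs_up", "rom", "pelvis", "sagittal", 12.0, 6.9, 9.4, 4.3, 0.063, -2.6, 0.7, 6.5, 1.7),
    _R("stairs_up", "rom", "pelvis", "frontal", 12.0, 4.8, 11.5, 5.7, 0.646, -0.6, 1.6, 6.7, 3.2),
    _R("stairs_up", "rom", "pelvis", "transverse", 17.9, 6.1, 14.5, 5.7, 0.035, -3.3, 2.3, 6.9, 3.8),
    _R("stairs_up", "rom", "hip", "sagittal", 51.7, 9.8, 48.7, 8.7, 0.349, -3.1, 2.1, 44.1, 8.5),
    _R("stairs_up", "rom", "hip", "frontal", 23.7, 7.1, 20.8, 6.4, 0.242, -2.9, 4.0, 12.1, 6.1),
    _R("stairs_up", "rom", "hip", "transverse", 26.0, 7.8, 21.5, 7.7, 0.074, -4.4, 3.8, 14.2, 4.2),
    _R("stairs_up", "rom", "knee", "sagittal", 67.9, 10.4, 69.9, 12.7, 0.638, 1.9, 2.9, 69.7, 8.2),
    _R("stairs_up", "rom", "ankle", "sagittal", 37.3, 14.4, 27.3, 7.6, 0.08, -10.0, 4.0, 36.7, 16.0),
    # --- stairs down --------------------------------------------------------
    _R("stairs_down", "stride_time", "", "", 1.66, 0.91, 1.31, 0.41, 0.005, -0.35, 0.2, 1.15, 0.69),
    _R("stairs_down", "cadence", "", "", 41.5, 12.1, 49.1, 12.0, 0.005, 7.6, 5.1, 60.4, 16.8),
    _R("stairs_down", "rom", "pelvis", "sagittal", 9.6, 2.7, 9.1, 4.3, 0.485, -0.5, 1.2, 7.1, 2.6),
    _R("stairs_down", "rom", "pelvis", "frontal", 10.6, 4.7, 9.4, 4.5, 0.383, -1.3, 0.9, 7.5, 1.8),
    _R("stairs_down", "rom", "pelvis", "transverse", 17.8, 9.0, 15.6, 7.3, 0.215, -2.2, 0.8, 7.6, 3.2),
    _R("stairs_down", "rom", "hip", "sagittal", 26.5, 7.4, 24.5, 7.5, 0.244, -2.0, 3.6, 20.3, 6.0),
    _R("stairs_down", "rom", "hip", "frontal", 14.2, 5.3, 16.3, 5.7, 0.394, 2.1, 2.1, 9.5, 2.5),
    _R("stairs_down", "rom", "hip", "transverse", 26.4, 9.3, 25.3, 10.3, 0.484, -1.2, 2.4, 15.6, 4.6),
    _R("stairs_down", "rom", "knee", "sagittal", 61.0, 14.3, 63.6, 16.1, 0.722, 2.6, 2.7, 68.2, 8.6),
    _R("stairs_down", "rom", "ankle", "sagittal", 52.3, 16.5, 46.3, 12.4, 0.206, -6.0, 2.1, 49.4, 8.6),
    # --- SPEED (deg/s): walking ---------------------------------------------
    _R("walk_self", "speed", "pelvis", "sagittal", 59.4, 25.8, 65.7, 29.1, 0.59, 6.3, 17.4, 81.8, 33.6),
    _R("walk_self", "speed", "pelvis", "frontal", 59.2, 26.7, 71.1, 32.8, 0.133, 11.9, 8.8, 107.9, 38.5),
    _R("walk_self", "speed", "pelvis", "transverse", 58.7, 17.3, 61.8, 23.8, 0.152, 3.1, 7.8, 89.9, 31.8),
    _R("walk_self", "speed", "hip", "sagittal", 191.5, 63.8, 245.7, 46.6, 0.002, 54.2, 29.7, 316.3, 85.6),
    _R("walk_self", "speed", "hip", "frontal", 137.0, 55.1, 166.4, 80.6, 0.233, 29.4, 27.6, 131.1, 43.2),
    _R("walk_self", "speed", "hip", "transverse", 180.7, 69.2, 226.4, 105.6, 0.002, 45.7, 34.9, 197.4, 61.6),
    _R("walk_self", "speed", "knee", "sagittal", 518.5, 179.1, 593.3, 97.4, 0.244, 75.1, 64.1, 655.2, 133.3),
    _R("walk_self", "speed", "ankle", "sagittal", 316.8, 129.1, 364.5, 104.8, 0.138, 47.7, 66.0, 394.5, 106.9),
    # --- SPEED: stairs up ----------------------------------------------------
    _R("stairs_up", "speed", "pelvis", "sagittal", 65.2, 27.2, 65.2, 25.2, 0.997, 0.0, 7.2, 53.6, 14.4),
    _R("stairs_up", "speed", "pelvis", "frontal", 59.3, 22.3, 73.4, 25.5, 0.646, 14.0, 19.1, 59.5, 26.0),
    _R("stairs_up", "speed", "pelvis", "transverse", 79.8, 22.4, 83.4, 22.0, 0.035, 3.6, 12.9, 53.7, 21.8),
    _R("stairs_up", "speed", "hip", "sagittal", 251.1, 45.2, 278.7, 53.1, 0.349, 27.6, 12.6, 272.2, 40.9),
    _R("stairs_up", "speed", "hip", "frontal", 138.5, 48.9, 156.5, 37.8, 0.215, 18.0, 21.2, 103.7, 50.7),
    _R("stairs_up", "speed", "hip", "transverse", 205.5, 73.5, 226.2, 78.8, 0.074, 20.6, 26.4, 158.7, 65.9),
    _R("stairs_up", "speed", "knee", "sagittal", 436.1, 109.9, 492.6, 81.1, 0.638, 56.6, 44.2, 521.6, 125.5),
    _R("stairs_up", "speed", "ankle", "sagittal", 354.5, 93.5, 340.3, 101.3, 0.08, -14.2, 24.1, 362.1, 120.7),
    # --- SPEED: stairs down --------------------------------------------------
    _R("stairs_down", "speed", "pelvis", "sagittal", 70.7, 30.3, 92.9, 40.6, 0.137, 22.2, 11.1, 93.2, 50.8),
    _R("stairs_down", "speed", "pelvis", "frontal", 76.6, 39.0, 83.1, 30.1, 0.542, 6.5, 15.4, 92.2, 37.5),
    _R("stairs_down", "speed", "pelvis", "transverse", 101.0, 33.9, 114.0, 24.9, 0.19, 13.0, 16.7, 84.7, 27.7),
    _R("stairs_down", "speed", "hip", "sagittal", 172.7, 55.3, 221.9, 64.4, 0.063, 49.2, 40.6, 245.1, 89.1),
    _R("stairs_down", "speed", "hip", "frontal", 109.3, 36.3, 163.0, 63.0, 0.015, 53.7, 15.9, 109.2, 39.4),
    _R("stairs_down", "speed", "hip", "transverse", 192.2, 85.1, 229.3, 79.4, 0.158, 37.1, 57.9, 219.1, 69.4),
    _R("stairs_down", "speed", "knee", "sagittal", 407.0, 139.0, 501.4, 93.9, 0.018, 94.5, 37.3, 567.9, 145.6),
    _R("stairs_down", "speed", "ankle", "sagittal", 414.0, 137.7, 462.7, 123.7, 0.232, 48.7, 39.8, 512.4, 117.4),
]


def get_row(task: str, metric: str, joint: str = "", plane: str = "") -> ReferenceRow:
    for r in ROWS:
        if (r.task, r.metric, r.joint, r.plane) == (task, metric, joint, plane):
            return r
    raise KeyError((task, metric, joint, plane))


def rows(metric: str = None, task: str = None) -> list:
    out = ROWS
    if metric is not None:
        out = [r for r in out if r.metric == metric]
    if task is not None:
        out = [r for r in out if r.task == task]
    return list(out)
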