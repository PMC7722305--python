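"""End-to-end orchestration: session analysis, demo study, report bundle.

``analyze_session`` runs one recording through the full chain: orientation
estimation -> functional calibration -> task segmentation -> initial-contact
detection -> cycle normalization -> ROM / SPEED / spatiotemporal / clinical
metrics.  ``run_pipeline`` applies it to a cohort (pre/post pairs and
healthy test-retest pairs), producing the comparison and reliability tables.
``make_demo_study`` writes a fully synthetic study to disk: 14 pre/post
patient sessions with published effect sizes and 12 healthy test-retest
pairs; the demo is deterministic under a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, fields as dc_fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import reference, stats, synthetic
from .io_sessions import SessionRecording, read_session, write_session
from .kinematics import (
    JOINT_SEGMENTS, PLANES, angular_velocity, clinical_metrics,
    joint_angles, pelvis_angles, range_metric, spatiotemporal,
)
from .orientation import (
    FusionParams, detect_static_interval, estimate_gyro_bias,
    estimate_orientation, functional_calibration,
)
from .segmentation import (
    GaitEvents, SegmentationError, detect_initial_contacts,
    extract_normalized_cycles, segment_tasks,
)

logger = logging.getLogger("imugait")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Schema-validated configuration; unknown keys are rejected."""

    tasks: tuple = reference.TASKS
    side: str = "R"                   # the reported (most painful) leg
    seed: int = 0
    n_subjects: int = reference.N_PATIENTS
    n_retest: int = reference.N_HEALTHY
    n_cycles: int = 6
    n_select: int = 3                 # cycles averaged per bout
    fusion_gain: float = 0.1
    fusion_init_window_s: float = 1.0
    event_mad_k: float = 3.0
    event_refractory_s: float = 0.4
    alpha: float = 0.05
    sem_formula: str = "wagner"
    holm: bool = False
    lowpass_hz: float = 0.0           # 0 disables pre-differentiation filtering

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**{k: (tuple(v) if k == "tasks" else v) for k, v in data.items()})
        if cfg.side not in ("L", "R"):
            raise PipelineError("side must be 'L' or 'R'")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


# ---------------------------------------------------------------------------
# Single-session analysis
# ---------------------------------------------------------------------------

@dataclass
class SessionMetrics:
    subject: str
    visit: str
    rom: dict = field(default_factory=dict)        # (task, joint, plane) -> deg
    speed: dict = field(default_factory=dict)      # (task, joint, plane) -> deg/s
    stride_time: dict = field(default_factory=dict)  # task -> s
    cadence: dict = field(default_factory=dict)      # task -> cycles/min
    clinical: dict = field(default_factory=dict)     # metric -> value
    qc: dict = field(default_factory=dict)

    def flat(self) -> dict:
        """metric-id -> value, the layout used by the report tables."""
        out = {}
        for (task, joint, plane), v in self.rom.items():
            out[f"{task}:rom:{joint}.{plane}"] = v
        for (task, joint, plane), v in self.speed.items():
            out[f"{task}:speed:{joint}.{plane}"] = v
        for task, v in self.stride_time.items():
            out[f"{task}:stride_time"] = v
        for task, v in self.cadence.items():
            out[f"{task}:cadence"] = v
        for name, v in self.clinical.items():
            out[f"clinical:{name}"] = v
        return out


def analyze_session(session: SessionRecording, config: PipelineConfig = None) -> SessionMetrics:
    """Full-chain analysis of one session recording."""
    cfg = config or PipelineConfig()
    fs = session.fs
    side = cfg.side

    statics = detect_static_interval(session.streams["pelvis_L5"])
    if not statics:
        raise PipelineError("no static interval found; cannot calibrate")
    static = statics[0]

    orientations = {}
    for placement, stream in session.streams.items():
        bias = estimate_gyro_bias(stream, [static])
        params = FusionParams(gain=cfg.fusion_gain,
                              init_window_s=cfg.fusion_init_window_s,
                              gyro_bias_dps=bias)
        orientations[placement] = estimate_orientation(stream, params)

    task_order = ([a[0] for a in session.annotations]
                  if session.annotations else list(cfg.tasks))
    bouts = segment_tasks(session, task_order)

    walk_bouts = [b for b in bouts if b.task.startswith("walk")]
    if not walk_bouts:
        raise PipelineError("no walking bout available for functional calibration")
    wb = walk_bouts[0]
    calib = functional_calibration(session, orientations,
                                   walk_interval=(wb.start, wb.end),
                                   static_interval=static)

    # joint angle series over the whole recording, reported side only
    ang = {"pelvis": pelvis_angles(orientations["pelvis_L5"],
                                   calib.rotations["pelvis_L5"], fs=fs)}
    for joint, (prox_t, dist_t) in JOINT_SEGMENTS.items():
        prox = prox_t.format(side=side)
        dist = dist_t.format(side=side)
        ang[joint] = joint_angles(
            orientations[prox], orientations[dist],
            calib.rotations[prox], calib.rotations[dist],
            joint=joint, side=side, fs=fs,
        )
    # contralateral hip/knee needed for contralateral event gating
    other = "L" if side == "R" else "R"
    ang_other = {}
    for joint in ("hip", "knee"):
        prox_t, dist_t = JOINT_SEGMENTS[joint]
        ang_other[joint] = joint_angles(
            orientations[prox_t.format(side=other)],
            orientations[dist_t.format(side=other)],
            calib.rotations[prox_t.format(side=other)],
            calib.rotations[dist_t.format(side=other)],
            joint=joint, side=other, fs=fs,
        )

    # world-vertical shank acceleration per side (gravity removed)
    vert = {}
    for s in ("L", "R"):
        st = session.streams[f"shank_{s}"]
        a_w = orientations[f"shank_{s}"].as_rotation().apply(st.accel)
        vert[s] = a_w[:, 2] - 1.0

    out = SessionMetrics(subject=session.subject, visit=session.visit,
                         qc={"calibration_qc": dict(calib.qc)})
    durations = {}
    for bout in bouts:
        sl = slice(bout.start, bout.end)
        contacts = {}
        for s in ("L", "R"):
            hip = (ang["hip"] if s == side else ang_other["hip"]).plane("sagittal")[sl]
            knee = (ang["knee"] if s == side else ang_other["knee"]).plane("sagittal")[sl]
            try:
                c = detect_initial_contacts(
                    vert[s][sl], hip, knee, fs,
                    mad_k=cfg.event_mad_k, refractory_s=cfg.event_refractory_s)
                contacts[s] = c + bout.start
            except SegmentationError as err:
                logger.warning("%s/%s %s side %s: %s", session.subject,
                               session.visit, bout.task, s, err)
        if side not in contacts:
            raise PipelineError(
                f"{bout.task}: no contacts on reported side {side}")
        events = GaitEvents(contacts=contacts, fs=fs)
        stride, cad = spatiotemporal(events, fs)
        out.stride_time[bout.task] = stride
        out.cadence[bout.task] = cad

        c_local = contacts[side] - bout.start
        for joint in ("pelvis", "hip", "knee", "ankle"):
            series = ang[joint].angles[sl]
            vel = angular_velocity(series, fs)
            for pi, plane in enumerate(PLANES):
                cyc = extract_normalized_cycles(series[:, pi], c_local,
                                                n_select=cfg.n_select)
                out.rom[(bout.task, joint, plane)] = range_metric(cyc)
                vcyc = extract_normalized_cycles(vel[:, pi], c_local,
                                                 n_select=cfg.n_select)
                out.speed[(bout.task, joint, plane)] = range_metric(vcyc)
        durations[bout.task] = bout.n_samples / fs

    # clinical metrics from annotations (preferred: exact bout spans) + sidecar
    known = {}
    ann_durations = dict(durations)
    for task, t0, t1 in session.annotations:
        ann_durations[task] = t1 - t0
    for key, val in session.meta.items():
        if key.startswith("track_m."):
            known[key[len("track_m."):]] = float(val)
        elif key.startswith("distance_m.") and key.endswith("walk_6min"):
            known["walk_6min"] = float(val)
    clin = clinical_metrics(ann_durations, known)
    if clin.self_selected_speed_mps is not None:
        out.clinical["self_selected_speed_mps"] = clin.self_selected_speed_mps
    if clin.fast_speed_mps is not None:
        out.clinical["fast_speed_mps"] = clin.fast_speed_mps
    if clin.six_min_distance_m is not None:
        out.clinical["six_min_distance_m"] = clin.six_min_distance_m
    return out


# ---------------------------------------------------------------------------
# Demo study generation
# ---------------------------------------------------------------------------

def make_demo_study(
    out_dir,
    seed: int = 0,
    n_subjects: int = reference.N_PATIENTS,
    n_retest: int = reference.N_HEALTHY,
    tasks=reference.TASKS,
    n_cycles: int = 6,
) -> dict:
    """Write the synthetic demo study to disk; returns the session-dir map."""
    out_dir = Path(out_dir)
    effect = synthetic.EffectSpec.from_reference()
    pairs = synthetic.make_paired_cohort(
        effect, n_subjects=n_subjects, seed=seed, tasks=tasks,
        n_cycles=n_cycles, return_truth=True)
    retest = synthetic.make_test_retest(
        n_subjects=n_retest, seed=seed + 1, tasks=tasks,
        n_cycles=n_cycles, return_truth=True)

    layout = {"paired": [], "retest": []}
    for (pre_s, pre_gt), (post_s, post_gt) in pairs:
        entry = []
        for sess, gt in ((pre_s, pre_gt), (post_s, post_gt)):
            d = out_dir / "cohort" / f"{sess.subject}_{sess.visit}"
            _write_with_truth(sess, gt, d)
            entry.append(d)
        layout["paired"].append(tuple(entry))
    for (t1_s, t1_gt), (t2_s, t2_gt) in retest:
        entry = []
        for sess, gt in ((t1_s, t1_gt), (t2_s, t2_gt)):
            d = out_dir / "retest" / f"{sess.subject}_{sess.visit}"
            _write_with_truth(sess, gt, d)
            entry.append(d)
        layout["retest"].append(tuple(entry))
    return layout


def _write_with_truth(session: SessionRecording, gt, directory) -> None:
    # the annotated track distance makes the 10 m-style speed recoverable;
    # the 6-min task instead carries its ground-truth total distance
    meta = dict(session.meta)
    for task, t0, t1 in session.annotations:
        info = gt.truth.get(task)
        if info and task != "walk_6min":
            meta[f"track_m.{task}"] = format(info["speed_mps"] * (t1 - t0), ".10g")
    session = replace(session, meta=meta)
    write_session(session, directory)
    synthetic.write_ground_truth(gt, Path(directory) / "ground_truth.json")


# ---------------------------------------------------------------------------
# Cohort analysis and report bundle
# ---------------------------------------------------------------------------

def _healthy_reference_map() -> dict:
    out = {}
    for r in reference.ROWS:
        if r.metric in ("rom", "speed"):
            mid = f"{'walk_self' if r.task == 'walk_self' else r.task}:{r.metric}:{r.joint}.{r.plane}"
        elif r.metric in ("stride_time", "cadence"):
            mid = f"{r.task}:{r.metric}"
        else:
            mid = {"walk_self": "clinical:self_selected_speed_mps",
                   "walk_fast": "clinical:fast_speed_mps",
                   "walk_6min": "clinical:six_min_distance_m"}[r.task]
        out[mid] = (r.healthy_mean, r.healthy_sd)
    return out


def analyze_cohort(layout: dict, config: PipelineConfig) -> dict:
    """Analyze a demo-study layout (paths) into the report bundle frames."""
    rows = []
    paired_flat = []
    for pre_dir, post_dir in layout["paired"]:
        pre_m = analyze_session(read_session(pre_dir), config)
        post_m = analyze_session(read_session(post_dir), config)
        paired_flat.append((pre_m.flat(), post_m.flat()))
        for m in (pre_m, post_m):
            for mid, v in m.flat().items():
                rows.append({"subject": m.subject, "visit": m.visit,
                             "metric": mid, "value": v})
    retest_flat = []
    for d1, d2 in layout["retest"]:
        m1 = analyze_session(read_session(d1), config)
        m2 = analyze_session(read_session(d2), config)
        retest_flat.append((m1.flat(), m2.flat()))
        for m in (m1, m2):
            for mid, v in m.flat().items():
                rows.append({"subject": m.subject, "visit": m.visit,
                             "metric": mid, "value": v})
    metrics_df = pd.DataFrame(rows)

    comparisons = {}
    if paired_flat:
        metric_ids = sorted(paired_flat[0][0])
        for mid in metric_ids:
            pre = np.array([p.get(mid, np.nan) for p, _ in paired_flat])
            post = np.array([q.get(mid, np.nan) for _, q in paired_flat])
            try:
                comparisons[mid] = stats.paired_compare(pre, post, metric=mid,
                                                        alpha=config.alpha)
            except stats.StatsInputError as err:
                logger.warning("comparison %s skipped: %s", mid, err)

    reliabilities = {}
    if retest_flat:
        metric_ids = sorted(retest_flat[0][0])
        for mid in metric_ids:
            t1 = np.array([p.get(mid, np.nan) for p, _ in retest_flat])
            t2 = np.array([q.get(mid, np.nan) for _, q in retest_flat])
            try:
                reliabilities[mid] = stats.reliability(
                    t1, t2, metric=mid, sem_formula=config.sem_formula)
            except stats.StatsInputError as err:
                logger.warning("reliability %s skipped: %s", mid, err)

    table = stats.summary_table(comparisons, reliabilities, _healthy_reference_map())
    rel_rows = [{"metric": mid, "n": r.n, "icc": r.icc, "sem": r.sem}
                for mid, r in reliabilities.items()]
    return {
        "metrics": metrics_df,
        "comparison": table,
        "reliability": pd.DataFrame(rel_rows).set_index("metric") if rel_rows
        else pd.DataFrame(columns=["n", "icc", "sem"]),
        "comparisons": comparisons,
        "reliabilities": reliabilities,
    }


def run_pipeline(config: PipelineConfig, out_dir, demo: bool = True,
                 session_root=None) -> dict:
    """Execute the full pipeline and write the report bundle.

    In demo mode the synthetic study is generated under ``out_dir/sessions``
    first; otherwise ``session_root`` must contain ``cohort`` and/or
    ``retest`` subdirectories laid out like the demo.  Writes metrics.csv,
    comparison_table.csv, reliability_table.csv, qc_log.txt and a manifest
    of completed stages; raises :class:`PipelineError` on fatal stage
    failures (partial outputs and the manifest are retained).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = []

    def _stage(name):
        manifest.append(name)
        (out_dir / "manifest.txt").write_text("\n".join(manifest) + "\n")

    try:
        if demo:
            layout = make_demo_study(
                out_dir / "sessions", seed=config.seed,
                n_subjects=config.n_subjects, n_retest=config.n_retest,
                tasks=config.tasks, n_cycles=config.n_cycles)
            _stage("simulate")
        else:
            root = Path(session_root)
            if not root.is_dir():
                raise PipelineError(f"session directory not found: {root}")
            layout = {"paired": [], "retest": []}
            cohort = sorted((root / "cohort").glob("*_pre")) if (root / "cohort").is_dir() else []
            for pre in cohort:
                post = pre.parent / pre.name.replace("_pre", "_post")
                if post.is_dir():
                    layout["paired"].append((pre, post))
            rt = sorted((root / "retest").glob("*_trial1")) if (root / "retest").is_dir() else []
            for t1 in rt:
                t2 = t1.parent / t1.name.replace("_trial1", "_trial2")
                if t2.is_dir():
                    layout["retest"].append((t1, t2))
            _stage("discover")

        bundle = analyze_cohort(layout, config)
        _stage("analyze")

        bundle["metrics"].to_csv(out_dir / "metrics.csv", index=False,
                                 float_format="%.10g")
        bundle["comparison"].to_csv(out_dir / "comparison_table.csv",
                                    float_format="%.10g")
        bundle["reliability"].to_csv(out_dir / "reliability_table.csv",
                                     float_format="%.10g")
        _stage("report")
        return bundle
    except Exception:
        (out_dir / "manifest.txt").write_text(
            "\n".join(manifest + ["FAILED"]) + "\n")
        raise


def tree_digest(root) -> str:
    """SHA-256 over all file names and bytes under ``root`` (determinism check)."""
    root = Path(root)
    h = hashlib.sha256()
    for path in sorted(p for p in root.rglob("*") if p.is_file()):
        h.update(str(path.relative_to(root)).encode())
        h.update(path.read_bytes())
    return h.hexdigest()
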