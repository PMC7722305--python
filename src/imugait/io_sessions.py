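"""Reading and writing of seven-sensor IMU session recordings.

A session is one subject-visit recorded with seven body-worn inertial
measurement units (pelvis/L5, both thighs, both shanks, both feet), each
delivering tri-axial accelerometer (g), gyroscope (deg/s) and magnetometer (G)
channels at a nominal 128 Hz.  On disk a session is a directory with one CSV
per placement plus a flat key-value metadata file; the dialect is
comma-separated, dot-decimal, seconds since session start, with a single
header line ``time,ax,ay,az,gx,gy,gz,mx,my,mz`` preceded by a ``#`` comment
line declaring the units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger("imugait")

#: Canonical sensor placements, in file/column order.
PLACEMENTS = (
    "pelvis_L5",
    "thigh_L",
    "thigh_R",
    "shank_L",
    "shank_R",
    "foot_L",
    "foot_R",
)

#: Full-scale ranges of the sensor family (accel in g, gyro in deg/s, mag in G).
ACCEL_RANGE_G = 6.0
GYRO_RANGE_DPS = 2000.0
MAG_RANGE_G = 8.1

DEFAULT_FS = 128.0

_CSV_HEADER = "time,ax,ay,az,gx,gy,gz,mx,my,mz"
_UNITS_COMMENT = "# units: time=s accel=g gyro=deg/s mag=G"


class SessionFormatError(ValueError):
    """Raised when a session directory or stream violates the format contract."""


@dataclass
class ImuStream:
    """One sensor's synchronized accelerometer/gyroscope/magnetometer series.

    ``time`` is regularized to the nominal grid k/fs on read; the raw timing
    jitter (median absolute deviation from the grid, in seconds) is retained
    in ``jitter_s`` as a QC metric only.
    """

    placement: str
    time: np.ndarray          # seconds, strictly increasing
    accel: np.ndarray         # (N, 3) in g
    gyro: np.ndarray          # (N, 3) in deg/s
    mag: np.ndarray           # (N, 3) in G
    fs: float = DEFAULT_FS
    jitter_s: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.mag = np.asarray(self.mag, dtype=float)
        self.validate()

    def __len__(self) -> int:
        return self.time.shape[0]

    def validate(self) -> None:
        if self.placement not in PLACEMENTS:
            raise SessionFormatError(f"unknown placement {self.placement!r}")
        n = self.time.shape[0]
        for name, arr in (("accel", self.accel), ("gyro", self.gyro), ("mag", self.mag)):
            if arr.shape != (n, 3):
                raise SessionFormatError(
                    f"{self.placement}: {name} shape {arr.shape} does not match "
                    f"time length {n}"
                )
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise SessionFormatError(f"{self.placement}: time is not strictly increasing")
            if abs(np.median(dt) - 1.0 / self.fs) >= 0.1 / self.fs:
                raise SessionFormatError(
                    f"{self.placement}: median sample interval {np.median(dt):.6f}s "
                    f"inconsistent with fs={self.fs} Hz"
                )
        for name, arr, lim in (
            ("accel", self.accel, ACCEL_RANGE_G),
            ("gyro", self.gyro, GYRO_RANGE_DPS),
            ("mag", self.mag, MAG_RANGE_G),
        ):
            if np.any(np.abs(arr) > lim + 1e-9):
                raise SessionFormatError(
                    f"{self.placement}: {name} exceeds full-scale range +/-{lim}"
                )


@dataclass
class SessionRecording:
    """Seven placed IMU streams plus optional task annotations for one visit."""

    subject: str
    visit: str                       # pre | post | trial1 | trial2
    streams: dict                    # placement -> ImuStream
    annotations: list = field(default_factory=list)  # (task, start_s, end_s)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [p for p in PLACEMENTS if p not in self.streams]
        if missing:
            raise SessionFormatError(f"missing placement(s): {', '.join(missing)}")
        extra = [p for p in self.streams if p not in PLACEMENTS]
        if extra:
            raise SessionFormatError(f"unknown placement(s): {', '.join(extra)}")
        n = len(self.streams[PLACEMENTS[0]])
        for p in PLACEMENTS:
            if len(self.streams[p]) != n:
                raise SessionFormatError("streams differ in length across placements")
        t_end = self.streams[PLACEMENTS[0]].time[-1] if n else 0.0
        prev_end = -np.inf
        for task, t0, t1 in self.annotations:
            if not (0.0 <= t0 < t1 <= t_end + 1e-9):
                raise SessionFormatError(
                    f"annotation {task!r} [{t0}, {t1}] outside recording bounds"
                )
            if t0 < prev_end - 1e-9:
                raise SessionFormatError("annotations overlap")
            prev_end = t1

    @property
    def fs(self) -> float:
        return self.streams[PLACEMENTS[0]].fs

    @property
    def n_samples(self) -> int:
        return len(self.streams[PLACEMENTS[0]])


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    # >= 9 significant digits so the write->read round trip is lossless at
    # the 1e-6 relative level required of the format.
    return format(float(x), ".10g")


def write_session(session: SessionRecording, directory) -> list:
    """Write one CSV per placement plus ``session.meta``; returns paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for placement in PLACEMENTS:
        s = session.streams[placement]
        path = directory / f"{placement}.csv"
        rows = np.column_stack([s.time, s.accel, s.gyro, s.mag])
        with open(path, "w", newline="\n") as fh:
            fh.write(_UNITS_COMMENT + f" fs={_fmt(s.fs)}\n")
            fh.write(_CSV_HEADER + "\n")
            for row in rows:
                fh.write(",".join(_fmt(v) for v in row) + "\n")
        written.append(path)

    meta_path = directory / "session.meta"
    with open(meta_path, "w", newline="\n") as fh:
        fh.write(f"subject={session.subject}\n")
        fh.write(f"visit={session.visit}\n")
        fh.write(f"fs={_fmt(session.fs)}\n")
        for task, t0, t1 in session.annotations:
            fh.write(f"annotation={task}:{_fmt(t0)}:{_fmt(t1)}\n")
        for key in sorted(session.meta):
            fh.write(f"meta.{key}={session.meta[key]}\n")
    written.append(meta_path)
    return written


def read_session(directory, fs: float = None) -> SessionRecording:
    """Read a session directory written by :func:`write_session`.

    Timestamps are snapped to the nominal grid k/fs; the observed median
    absolute deviation from that grid is kept as ``ImuStream.jitter_s``.
    Runs of more than 3 missing samples are logged as warnings.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise SessionFormatError(f"session directory not found: {directory}")

    meta_path = directory / "session.meta"
    subject, visit = directory.name, "pre"
    annotations: list = []
    meta: dict = {}
    meta_fs = fs
    if meta_path.exists():
        for line in meta_path.read_text().splitlines():
            if not line.strip() or "=" not in line:
                continue
            key, val = line.split("=", 1)
            if key == "subject":
                subject = val
            elif key == "visit":
                visit = val
            elif key == "fs":
                meta_fs = float(val)
            elif key == "annotation":
                task, t0, t1 = val.split(":")
                annotations.append((task, float(t0), float(t1)))
            elif key.startswith("meta."):
                meta[key[5:]] = val
    nominal_fs = meta_fs if meta_fs is not None else DEFAULT_FS

    streams = {}
    for placement in PLACEMENTS:
        path = directory / f"{placement}.csv"
        if not path.exists():
            raise SessionFormatError(
                f"missing placement file for {placement!r}: {path}"
            )
        with open(path) as fh:
            first = fh.readline().strip()
            file_fs = nominal_fs
            if first.startswith("#"):
                if "accel=g" not in first or "gyro=deg/s" not in first or "mag=G" not in first:
                    raise SessionFormatError(f"{placement}: unit declaration mismatch: {first}")
                for token in first.split():
                    if token.startswith("fs="):
                        file_fs = float(token[3:])
                header = fh.readline().strip()
            else:
                header = first
            if header != _CSV_HEADER:
                raise SessionFormatError(
                    f"{placement}: unexpected header {header!r}; expected {_CSV_HEADER!r}"
                )
            data = np.loadtxt(fh, delimiter=",", ndmin=2)
        if data.shape[1] != 10:
            raise SessionFormatError(f"{placement}: expected 10 columns, got {data.shape[1]}")
        t_raw = data[:, 0]
        if np.any(np.diff(t_raw) <= 0):
            raise SessionFormatError(f"{placement}: non-monotone timestamps")
        # Snap to the nominal grid; raw jitter becomes a QC number.
        idx = np.round(t_raw * file_fs).astype(int)
        gaps = np.diff(idx)
        if np.any(gaps > 3):
            logger.warning(
                "%s/%s: %d gap(s) longer than 3 samples", directory.name,
                placement, int(np.sum(gaps > 3)),
            )
        t_grid = idx / file_fs
        jitter = float(np.median(np.abs(t_raw - t_grid)))
        streams[placement] = ImuStream(
            placement=placement,
            time=t_grid,
            accel=data[:, 1:4],
            gyro=data[:, 4:7],
            mag=data[:, 7:10],
            fs=file_fs,
            jitter_s=jitter,
        )

    return SessionRecording(
        subject=subject, visit=visit, streams=streams,
        annotations=annotations, meta=meta,
    )
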