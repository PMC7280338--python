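"""Core domain types and project-tree navigation.

A wearable eye tracker stores studies and recordings on its memory card in a
directory tree whose folder names are opaque random strings.  This module
builds a human-readable lookup table over such a tree and provides the shared
in-memory containers (gaze, IMU, TTL, video-time streams) used by every other
module.

Directory dialect::

    root/
      <project_id>/
        project.json            {"id", "name"}
        recordings/
          <recording_id>/
            recording.json      {"id", "name", "participant_id",
                                 "participant_name", "start_time",
                                 "duration_s"?, "calibration_status"?}
            segments/
              <k>/
                livedata.json.gz
                segment.json
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousRecordingError,
    ParseError,
    RecordingNotFoundError,
)
from .packet_io import SEGMENT_DATA_FILE

log = logging.getLogger(__name__)

CALIBRATION_STATUSES = ("calibrated", "failed", "none")

# binocularity labels; samples with no valid eye are "missing"
BINOCULAR = "binocular"
MONOCULAR_LEFT = "monocular_left"
MONOCULAR_RIGHT = "monocular_right"
MISSING = "missing"
BINOCULARITY_LABELS = (BINOCULAR, MONOCULAR_LEFT, MONOCULAR_RIGHT, MISSING)

LOOKUP_COLUMNS = [
    "project_id",
    "project_name",
    "participant_id",
    "participant_name",
    "recording_id",
    "recording_name",
    "start_time",
    "duration_s",
    "calibration_status",
    "path",
]

PROJECT_META_FILE = "project.json"
RECORDING_META_FILE = "recording.json"
LOOKUP_TSV = "lookup.tsv"
LOOKUP_XLSX = "lookup.xlsx"


@dataclass
class RecordingMeta:
    """Identity and acquisition metadata of one recording."""

    project_id: str = "unknown"
    project_name: str = "unknown"
    participant_id: str = "unknown"
    participant_name: str = "unknown"
    recording_id: str = "unknown"
    recording_name: str = "unknown"
    start_time: str = "unknown"
    nominal_gaze_rate_hz: int = 0
    segment_count: int = 1
    firmware_version: str = "unknown"
    calibration_status: str = "none"


@dataclass
class GazeSample:
    """One regularized tick of the gaze stream (a row view of GazeData)."""

    t: float
    left_gaze_dir: np.ndarray
    right_gaze_dir: np.ndarray
    left_azimuth: float
    left_elevation: float
    right_azimuth: float
    right_elevation: float
    left_pupil_diameter: float
    right_pupil_diameter: float
    left_pupil_center: np.ndarray
    right_pupil_center: np.ndarray
    video_gaze_point: np.ndarray
    gaze_point_3d: np.ndarray
    left_valid: bool
    right_valid: bool
    binocularity: str


@dataclass
class GazeData:
    """Columnar gaze time series.

    All per-sample quantities are parallel numpy arrays; missing values are
    NaN.  After regularization ``t`` lies on the exact grid
    ``t[0] + k / rate``.
    """

    t: np.ndarray  # (n,) seconds
    left_gaze_dir: np.ndarray  # (n, 3) unit vectors, NaN when invalid
    right_gaze_dir: np.ndarray
    left_azimuth: np.ndarray  # (n,) degrees, NaN when invalid
    left_elevation: np.ndarray
    right_azimuth: np.ndarray
    right_elevation: np.ndarray
    left_pupil_diameter: np.ndarray  # (n,) mm
    right_pupil_diameter: np.ndarray
    left_pupil_center: np.ndarray  # (n, 3) mm
    right_pupil_center: np.ndarray
    video_gaze_point: np.ndarray  # (n, 2) normalized scene-image coords
    gaze_point_3d: np.ndarray  # (n, 3) mm
    left_valid: np.ndarray  # (n,) bool
    right_valid: np.ndarray
    binocularity: np.ndarray  # (n,) unicode, one of BINOCULARITY_LABELS

    ARRAY_FIELDS = (
        "t",
        "left_gaze_dir",
        "right_gaze_dir",
        "left_azimuth",
        "left_elevation",
        "right_azimuth",
        "right_elevation",
        "left_pupil_diameter",
        "right_pupil_diameter",
        "left_pupil_center",
        "right_pupil_center",
        "video_gaze_point",
        "gaze_point_3d",
        "left_valid",
        "right_valid",
        "binocularity",
    )

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def empty(cls, n: int) -> "GazeData":
        return cls(
            t=np.full(n, np.nan),
            left_gaze_dir=np.full((n, 3), np.nan),
            right_gaze_dir=np.full((n, 3), np.nan),
            left_azimuth=np.full(n, np.nan),
            left_elevation=np.full(n, np.nan),
            right_azimuth=np.full(n, np.nan),
            right_elevation=np.full(n, np.nan),
            left_pupil_diameter=np.full(n, np.nan),
            right_pupil_diameter=np.full(n, np.nan),
            left_pupil_center=np.full((n, 3), np.nan),
            right_pupil_center=np.full((n, 3), np.nan),
            video_gaze_point=np.full((n, 2), np.nan),
            gaze_point_3d=np.full((n, 3), np.nan),
            left_valid=np.zeros(n, dtype=bool),
            right_valid=np.zeros(n, dtype=bool),
            binocularity=np.full(n, MISSING, dtype="U15"),
        )

    def sample(self, i: int) -> GazeSample:
        return GazeSample(
            t=float(self.t[i]),
            left_gaze_dir=self.left_gaze_dir[i],
            right_gaze_dir=self.right_gaze_dir[i],
            left_azimuth=float(self.left_azimuth[i]),
            left_elevation=float(self.left_elevation[i]),
            right_azimuth=float(self.right_azimuth[i]),
            right_elevation=float(self.right_elevation[i]),
            left_pupil_diameter=float(self.left_pupil_diameter[i]),
            right_pupil_diameter=float(self.right_pupil_diameter[i]),
            left_pupil_center=self.left_pupil_center[i],
            right_pupil_center=self.right_pupil_center[i],
            video_gaze_point=self.video_gaze_point[i],
            gaze_point_3d=self.gaze_point_3d[i],
            left_valid=bool(self.left_valid[i]),
            right_valid=bool(self.right_valid[i]),
            binocularity=str(self.binocularity[i]),
        )

    def __iter__(self) -> Iterator[GazeSample]:
        for i in range(len(self)):
            yield self.sample(i)


@dataclass
class ImuData:
    """One inertial stream (gyroscope deg/s or accelerometer m/s^2)."""

    t: np.ndarray  # (n,) seconds, native rate
    values: np.ndarray  # (n, 3)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.values).all(axis=1)

    @classmethod
    def empty(cls) -> "ImuData":
        return cls(t=np.empty(0), values=np.empty((0, 3)))


@dataclass(frozen=True)
class TtlEvent:
    """A timestamped TTL input level change (sync pulse, button press)."""

    t: float  # seconds
    value: int
    direction: str = "in"


@dataclass
class VideoTimeMap:
    """Piecewise-linear map between media time and recording data time."""

    media_t: np.ndarray  # (n,) seconds within the video file
    data_t: np.ndarray  # (n,) seconds on the recording clock
    stream_id: str = "scene"  # "scene" | "eyes"

    def __post_init__(self) -> None:
        self.media_t = np.asarray(self.media_t, dtype=float)
        self.data_t = np.asarray(self.data_t, dtype=float)
        if len(self.media_t) != len(self.data_t) or len(self.media_t) == 0:
            raise ParseError("video time map needs >= 1 (media, data) pair")
        if len(self.media_t) > 1 and (
            np.any(np.diff(self.media_t) <= 0) or np.any(np.diff(self.data_t) <= 0)
        ):
            raise ParseError("video time map pairs must be strictly increasing")

    def media_to_data(self, t):
        """Map media time to data time (clamped linear extrapolation)."""
        if len(self.media_t) == 1:
            return np.asarray(t, dtype=float) + (self.data_t[0] - self.media_t[0])
        return np.interp(t, self.media_t, self.data_t)

    def data_to_media(self, t):
        if len(self.media_t) == 1:
            return np.asarray(t, dtype=float) - (self.data_t[0] - self.media_t[0])
        return np.interp(t, self.data_t, self.media_t)


@dataclass
class Recording:
    """A fully assembled, synchronized recording.

    All streams share one clock with t = 0 at the first gaze sample; the
    gaze stream is regularized onto the nominal sampling grid, IMU streams
    keep their native timestamps.
    """

    meta: RecordingMeta
    gaze: GazeData
    gyro: ImuData
    accel: ImuData
    ttl: list[TtlEvent] = field(default_factory=list)
    video_maps: list[VideoTimeMap] = field(default_factory=list)
    derived: "object | None" = None  # KinematicsResult, set by gaze_kinematics

    @property
    def rate_hz(self) -> int:
        return self.meta.nominal_gaze_rate_hz

    @property
    def dt(self) -> float:
        return 1.0 / self.meta.nominal_gaze_rate_hz

    @property
    def duration_s(self) -> float:
        """Recording length: samples times the sampling interval."""
        return len(self.gaze) * self.dt


@dataclass
class RecordingLookup:
    """Tabular index of every recording under a project-tree root."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in LOOKUP_COLUMNS if c not in self.table.columns]
        if missing:
            raise ParseError(f"lookup table is missing columns {missing}")
        self.table = (
            self.table[LOOKUP_COLUMNS]
            .sort_values(["project_name", "participant_name", "recording_name"], kind="stable")
            .reset_index(drop=True)
        )

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path: os.PathLike | str) -> None:
        self.table.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")

    def to_xlsx(self, path: os.PathLike | str) -> None:
        self.table.to_excel(path, index=False)

    @classmethod
    def from_tsv(cls, path: os.PathLike | str) -> "RecordingLookup":
        table = pd.read_csv(
            path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
        )
        return cls(table=table)


def _read_json(path: Path) -> dict | None:
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            obj = json.load(fh)
        return obj if isinstance(obj, dict) else None
    except (OSError, json.JSONDecodeError):
        return None


def _segment_dirs(recording_dir: Path) -> list[Path]:
    seg_root = recording_dir / "segments"
    if not seg_root.is_dir():
        return []
    return sorted(d for d in seg_root.iterdir() if (d / SEGMENT_DATA_FILE).is_file())


def build_lookup(root_dir: os.PathLike | str, write_files: bool = True) -> RecordingLookup:
    """Scan a project tree and index every discoverable recording.

    A recording is discoverable when it has at least one segment containing a
    data file.  Recordings with unreadable metadata are still listed, with
    their fields set to ``"unknown"`` and a logged warning.  The lookup is
    written inside ``root_dir`` as ``lookup.tsv`` (canonical) and
    ``lookup.xlsx`` unless ``write_files`` is false.
    """
    root = Path(root_dir)
    if not root.is_dir():
        raise ParseError(f"root directory not found: {root}")

    rows: list[dict] = []
    for project_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        project_meta = _read_json(project_dir / PROJECT_META_FILE)
        if project_meta is None:
            if not (project_dir / "recordings").is_dir():
                continue  # unrelated directory
            log.warning("unreadable project metadata in %s", project_dir)
            project_meta = {}
        rec_root = project_dir / "recordings"
        if not rec_root.is_dir():
            continue
        for rec_dir in sorted(d for d in rec_root.iterdir() if d.is_dir()):
            if not _segment_dirs(rec_dir):
                continue
            rec_meta = _read_json(rec_dir / RECORDING_META_FILE)
            if rec_meta is None:
                log.warning("unreadable recording metadata in %s", rec_dir)
                rec_meta = {}
            status = rec_meta.get("calibration_status", "none")
            if status not in CALIBRATION_STATUSES:
                status = "none"
            duration = rec_meta.get("duration_s", "unknown")
            rows.append(
                {
                    "project_id": str(project_meta.get("id", project_dir.name)),
                    "project_name": str(project_meta.get("name", "unknown")),
                    "participant_id": str(rec_meta.get("participant_id", "unknown")),
                    "participant_name": str(rec_meta.get("participant_name", "unknown")),
                    "recording_id": str(rec_meta.get("id", rec_dir.name)),
                    "recording_name": str(rec_meta.get("name", "unknown")),
                    "start_time": str(rec_meta.get("start_time", "unknown")),
                    "duration_s": str(duration),
                    "calibration_status": status,
                    "path": rec_dir.relative_to(root).as_posix(),
                }
            )

    table = pd.DataFrame(rows, columns=LOOKUP_COLUMNS, dtype=str)
    lookup = RecordingLookup(table=table)
    if write_files:
        lookup.to_tsv(root / LOOKUP_TSV)
        try:
            lookup.to_xlsx(root / LOOKUP_XLSX)
        except Exception as exc:  # xlsx is a convenience mirror of the TSV
            log.warning("could not write %s: %s", root / LOOKUP_XLSX, exc)
    return lookup


def select_recording(
    lookup: RecordingLookup, project: str, recording: str, root_dir: os.PathLike | str | None = None
) -> Path:
    """Resolve a (project, recording) query to the recording's directory.

    Both arguments match either the opaque id or the human-readable name.
    A miss raises :class:`RecordingNotFoundError` listing near matches; more
    than one match raises :class:`AmbiguousRecordingError`.
    """
    t = lookup.table
    proj_mask = (t["project_id"] == project) | (t["project_name"] == project)
    rec_mask = (t["recording_id"] == recording) | (t["recording_name"] == recording)
    hits = t[proj_mask & rec_mask]
    if len(hits) == 0:
        near = t[proj_mask | rec_mask]
        candidates = [
            f"{r.project_name}/{r.recording_name} ({r.project_id}/{r.recording_id})"
            for r in near.itertuples()
        ][:10]
        raise RecordingNotFoundError(
            f"no recording matches project={project!r}, recording={recording!r};"
            f" near matches: {candidates or 'none'}"
        )
    if len(hits) > 1:
        raise AmbiguousRecordingError(
            f"{len(hits)} recordings match project={project!r}, recording={recording!r}: "
            + ", ".join(hits["path"])
        )
    rel = Path(hits.iloc[0]["path"])
    return Path(root_dir) / rel if root_dir is not None else rel
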