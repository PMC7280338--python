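"""Assemble raw packet streams into a synchronized, regularized Recording.

Gaze-family packets sharing a group index are merged into one gaze sample;
per-eye validity requires the eye's direction, pupil-center and
pupil-diameter packets to all be present with status 0.  Samples are then
snapped onto the exact nominal sampling grid and every unoccupied grid tick
between the first and last sample is filled with a "missing" sample, so the
sampling interval is preserved exactly.  Recordings split into multiple
segments (hardware splits recordings of roughly an hour or longer) are
concatenated on their shared clock, with the inter-segment span gap-filled
like any other gap.

Gaze positions are never interpolated: missing data stays missing.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ParseError, SegmentOverlapError
from .gaze_kinematics import fick_decompose
from .packet_io import (
    EYE_VIDEO_TIME_FILE,
    GAZE_FAMILY_KINDS,
    SEGMENT_DATA_FILE,
    RawPacket,
    ReadReport,
    read_segment,
    read_segment_meta,
)
from .recording_model import (
    BINOCULAR,
    MISSING,
    MONOCULAR_LEFT,
    MONOCULAR_RIGHT,
    GazeData,
    ImuData,
    Recording,
    RecordingMeta,
    TtlEvent,
    VideoTimeMap,
    _read_json,
)

log = logging.getLogger(__name__)

SUPPORTED_RATES = (50, 100)
CACHE_FILE = "livedata.processed"


@dataclass
class AssemblyReport:
    """Bookkeeping of one assembly run.

    After de-duplication, n_regularized = (n_raw_groups - n_duplicates)
    + n_gap_filled.
    """

    n_raw_groups: int = 0
    n_regularized: int = 0
    n_gap_filled: int = 0
    n_invalidated: int = 0  # raw groups with no valid eye
    n_duplicates: int = 0  # samples colliding on one grid tick (later dropped)
    inferred_rate_hz: int = 0
    segment_boundaries: list[float] = field(default_factory=list)
    dropped_lines: int = 0
    unknown_kind_lines: int = 0


def group_gaze_packets(packets: Sequence[RawPacket]) -> GazeData:
    """Merge gaze-family packets sharing a group index into gaze samples.

    Returns an irregular (not yet grid-snapped) :class:`GazeData`, sorted by
    time.  A conflicting duplicate payload for one (gidx, kind, eye) keeps
    the first occurrence and logs the conflict.  The sample timestamp is the
    earliest gaze-direction packet timestamp in the group (earliest packet
    timestamp when the group has no direction packet).
    """
    groups: dict[int, dict] = {}
    n_conflicts = 0
    for p in packets:
        if p.kind not in GAZE_FAMILY_KINDS:
            continue
        if p.gidx is None:
            log.debug("gaze-family packet without gidx skipped (ts=%d)", p.ts)
            continue
        g = groups.setdefault(p.gidx, {"ts": [], "gd_ts": []})
        slot = p.kind if p.eye == "none" else f"{p.eye}_{p.kind}"
        if slot in g:
            n_conflicts += 1
            continue
        g[slot] = p
        g["ts"].append(p.ts)
        if p.kind == "gaze_dir":
            g["gd_ts"].append(p.ts)
    if n_conflicts:
        log.warning("kept first of %d conflicting duplicate gaze packets", n_conflicts)

    order = sorted(groups, key=lambda gidx: min(groups[gidx]["ts"]))
    data = GazeData.empty(len(order))
    for i, gidx in enumerate(order):
        g = groups[gidx]
        ts = min(g["gd_ts"]) if g["gd_ts"] else min(g["ts"])
        data.t[i] = ts / 1e6
        for eye in ("left", "right"):
            gd = g.get(f"{eye}_gaze_dir")
            pc = g.get(f"{eye}_pupil_center")
            pd = g.get(f"{eye}_pupil_diameter")
            valid = all(p is not None and p.status == 0 for p in (gd, pc, pd))
            getattr(data, f"{eye}_valid")[i] = valid
            if valid:
                getattr(data, f"{eye}_gaze_dir")[i] = gd.payload
                getattr(data, f"{eye}_pupil_center")[i] = pc.payload
                getattr(data, f"{eye}_pupil_diameter")[i] = pd.payload[0]
        gp = g.get("gaze_point_2d")
        if gp is not None and gp.status == 0:
            data.video_gaze_point[i] = gp.payload
        gp3 = g.get("gaze_point_3d")
        if gp3 is not None and gp3.status == 0:
            data.gaze_point_3d[i] = gp3.payload
        lv, rv = data.left_valid[i], data.right_valid[i]
        data.binocularity[i] = (
            BINOCULAR if (lv and rv) else MONOCULAR_LEFT if lv else MONOCULAR_RIGHT if rv else MISSING
        )

    # Fick angles for valid eyes (vectorized over the whole series)
    for eye in ("left", "right"):
        theta, phi = fick_decompose(getattr(data, f"{eye}_gaze_dir"))
        getattr(data, f"{eye}_azimuth")[:] = theta
        getattr(data, f"{eye}_elevation")[:] = phi
    return data


def infer_rate(t: np.ndarray) -> int:
    """Nominal sampling rate: the supported rate nearest 1/median(dt)."""
    t = np.asarray(t, dtype=float)
    if len(t) < 10:
        raise ParseError(f"too short to infer sampling rate ({len(t)} samples, need >= 10)")
    med_dt = float(np.median(np.diff(t)))
    if med_dt <= 0:
        raise ParseError("non-increasing timestamps; cannot infer sampling rate")
    empirical = 1.0 / med_dt
    rate = min(SUPPORTED_RATES, key=lambda r: abs(empirical - r))
    if abs(empirical - rate) / rate > 0.1:
        log.warning(
            "empirical rate %.1f Hz deviates >10%% from nominal %d Hz", empirical, rate
        )
    return rate


def _snap_indices(t: np.ndarray, t0: float, rate: int) -> np.ndarray:
    """Nearest grid tick for each time; ties at half an interval go earlier."""
    return np.ceil((t - t0) * rate - 0.5).astype(np.int64)


def regularize_and_fill(
    gaze: GazeData, rate: int, report: AssemblyReport | None = None
) -> GazeData:
    """Snap samples to the exact grid t0 + k/rate and fill the holes.

    Each input sample moves to its nearest grid tick (ties snap to the
    earlier tick); unoccupied ticks between the first and last sample become
    "missing" samples; when two inputs collide on one tick the earlier one
    is kept.  The output grid is exact: every timestamp is computed directly
    as ``t0 + k / rate``.
    """
    if report is None:
        report = AssemblyReport()
    n_in = len(gaze)
    if n_in == 0:
        report.n_regularized = 0
        return GazeData.empty(0)
    order = np.argsort(gaze.t, kind="stable")
    t_sorted = gaze.t[order]
    t0 = float(t_sorted[0])
    k = _snap_indices(t_sorted, t0, rate)
    n_out = int(k[-1]) + 1

    out = GazeData.empty(n_out)
    out.t[:] = t0 + np.arange(n_out) / rate
    occupied = np.zeros(n_out, dtype=bool)
    # first occupant (earlier input) wins on tick collisions
    keep_mask = np.ones(n_in, dtype=bool)
    seen: set[int] = set()
    for j in range(n_in):
        tick = int(k[j])
        if tick in seen:
            keep_mask[j] = False
        else:
            seen.add(tick)
    n_dup = int(np.count_nonzero(~keep_mask))
    src = order[keep_mask]
    dst = k[keep_mask]
    occupied[dst] = True
    for name in GazeData.ARRAY_FIELDS:
        if name == "t":
            continue
        getattr(out, name)[dst] = getattr(gaze, name)[src]

    report.n_raw_groups += n_in
    report.n_duplicates += n_dup
    report.n_regularized = n_out
    report.n_gap_filled += int(np.count_nonzero(~occupied))
    report.n_invalidated += int(np.count_nonzero(gaze.binocularity == MISSING))
    return out


@dataclass
class SegmentStreams:
    """Raw per-segment streams on the shared recording clock (seconds)."""

    gaze: GazeData  # irregular
    gyro: ImuData
    accel: ImuData
    ttl: list[TtlEvent]
    vts_pairs: list[tuple[float, float]]  # (media_t, data_t) for the scene stream
    eye_vts_pairs: list[tuple[float, float]] = field(default_factory=list)


def concat_segments(
    segments: Sequence[SegmentStreams], rate: int | None = None, report: AssemblyReport | None = None
) -> tuple[GazeData, ImuData, ImuData, list[TtlEvent], list[VideoTimeMap], AssemblyReport]:
    """Concatenate segment streams in time order onto one regular grid.

    Segments must be non-overlapping in time (a shared clock is part of the
    dialect); overlap raises :class:`SegmentOverlapError` with its extent.
    The span between segments is gap-filled like any other gap and the
    boundary times are recorded in the report.
    """
    if report is None:
        report = AssemblyReport()
    segs = [s for s in segments if len(s.gaze) > 0]
    if not segs:
        raise ParseError("no gaze data in any segment")
    segs = sorted(segs, key=lambda s: float(s.gaze.t[0]))
    for a, b in zip(segs, segs[1:]):
        if b.gaze.t[0] <= a.gaze.t[-1]:
            raise SegmentOverlapError(
                f"segments overlap by {a.gaze.t[-1] - b.gaze.t[0]:.6f} s "
                f"(segment starting at {b.gaze.t[0]:.6f} s begins before "
                f"{a.gaze.t[-1]:.6f} s)"
            )

    merged = GazeData.empty(sum(len(s.gaze) for s in segs))
    pos = 0
    for s in segs:
        n = len(s.gaze)
        for name in GazeData.ARRAY_FIELDS:
            getattr(merged, name)[pos : pos + n] = getattr(s.gaze, name)
        pos += n
    if rate is None:
        rate = infer_rate(merged.t)
    report.inferred_rate_hz = rate
    report.segment_boundaries = [float(s.gaze.t[0]) for s in segs[1:]]
    gaze = regularize_and_fill(merged, rate, report)

    def _cat_imu(parts: list[ImuData]) -> ImuData:
        parts = [p for p in parts if len(p)]
        if not parts:
            return ImuData.empty()
        t = np.concatenate([p.t for p in parts])
        v = np.concatenate([p.values for p in parts])
        order = np.argsort(t, kind="stable")
        return ImuData(t=t[order], values=v[order])

    gyro = _cat_imu([s.gyro for s in segs])
    accel = _cat_imu([s.accel for s in segs])
    ttl = sorted((e for s in segs for e in s.ttl), key=lambda e: e.t)

    video_maps = []
    for stream_id, attr in (("scene", "vts_pairs"), ("eyes", "eye_vts_pairs")):
        pairs = sorted(p for s in segs for p in getattr(s, attr))
        if pairs:
            media, data = zip(*pairs)
            video_maps.append(attach_video_map(media, data, stream_id))
    return gaze, gyro, accel, ttl, video_maps, report


def attach_video_map(media_t, data_t, stream_id: str = "scene") -> VideoTimeMap:
    """Build a monotone piecewise-linear media-time/data-time map."""
    return VideoTimeMap(media_t=np.asarray(media_t), data_t=np.asarray(data_t), stream_id=stream_id)


def _load_segment(segment_dir: Path, report: AssemblyReport) -> tuple[SegmentStreams, dict]:
    """Read one segment directory into raw streams (times still in µs here)."""
    read_rep = ReadReport()
    packets = list(read_segment(segment_dir / SEGMENT_DATA_FILE, read_rep))
    report.dropped_lines += read_rep.dropped
    report.unknown_kind_lines += read_rep.unknown_kind
    meta = read_segment_meta(segment_dir)

    gaze_pkts = [p for p in packets if p.kind in GAZE_FAMILY_KINDS]
    gyro = [(p.ts, p.payload) for p in packets if p.kind == "gyro" and p.status == 0]
    accel = [(p.ts, p.payload) for p in packets if p.kind == "accel" and p.status == 0]
    ttl = [(p.ts, int(p.payload[0])) for p in packets if p.kind == "ttl"]
    vts = [(p.payload[0], p.ts) for p in packets if p.kind == "vts" and p.status == 0]

    eye_vts: list[tuple[float, float]] = []
    evts_path = segment_dir / EYE_VIDEO_TIME_FILE
    if evts_path.is_file():
        evts_rep = ReadReport()
        eye_vts = [
            (p.payload[0], p.ts)
            for p in read_segment(evts_path, evts_rep)
            if p.kind == "vts" and p.status == 0
        ]
        report.dropped_lines += evts_rep.dropped

    def _imu(rows: list[tuple[int, tuple[float, ...]]]) -> ImuData:
        if not rows:
            return ImuData.empty()
        t = np.array([r[0] for r in rows], dtype=float)
        v = np.array([r[1] for r in rows], dtype=float)
        return ImuData(t=t, values=v)

    streams = SegmentStreams(
        gaze=group_gaze_packets(gaze_pkts),
        gyro=_imu(gyro),
        accel=_imu(accel),
        ttl=[TtlEvent(t=float(ts), value=val) for ts, val in ttl],
        vts_pairs=[(float(m), float(d)) for m, d in vts],
        eye_vts_pairs=[(float(m), float(d)) for m, d in eye_vts],
    )
    return streams, meta


def _rescale_to_seconds(seg: SegmentStreams, ts0_us: float) -> SegmentStreams:
    seg.gaze.t = (seg.gaze.t * 1e6 - ts0_us) / 1e6
    seg.gyro.t = (seg.gyro.t - ts0_us) / 1e6
    seg.accel.t = (seg.accel.t - ts0_us) / 1e6
    seg.ttl = [TtlEvent(t=(e.t - ts0_us) / 1e6, value=e.value) for e in seg.ttl]
    seg.vts_pairs = [(m / 1e6, (d - ts0_us) / 1e6) for m, d in seg.vts_pairs]
    seg.eye_vts_pairs = [(m / 1e6, (d - ts0_us) / 1e6) for m, d in seg.eye_vts_pairs]
    return seg


def parse_recording(
    rec_dir: os.PathLike | str, force: bool = False, cache: bool = True
) -> tuple[Recording, AssemblyReport]:
    """Parse a recording directory into a synchronized Recording.

    Composes segment reading, gaze grouping, rate inference, grid
    regularization with gap filling, multi-segment concatenation and
    video-time mapping.  The assembled result is cached in a single HDF5
    container (``livedata.processed``) inside the recording directory; a
    subsequent call loads the cache unless ``force`` is set.
    """
    from . import processed_cache  # deferred: h5py import cost

    rec_dir = Path(rec_dir)
    if not rec_dir.is_dir():
        raise ParseError(f"recording directory not found: {rec_dir}")
    cache_path = rec_dir / CACHE_FILE
    if cache and not force and cache_path.is_file():
        return processed_cache.load(cache_path)

    seg_root = rec_dir / "segments"
    seg_dirs = (
        sorted(d for d in seg_root.iterdir() if (d / SEGMENT_DATA_FILE).is_file())
        if seg_root.is_dir()
        else []
    )
    if not seg_dirs:
        raise ParseError(f"no data segments in {rec_dir}")

    report = AssemblyReport()
    loaded = [_load_segment(d, report) for d in seg_dirs]
    nonempty = [(s, m) for s, m in loaded if len(s.gaze) > 0]
    if not nonempty:
        raise ParseError(f"no gaze data in {rec_dir}")
    # shared clock zero: the first gaze sample over all segments (microseconds)
    ts0_us = min(float(s.gaze.t[0]) * 1e6 for s, _ in nonempty)
    segments = [_rescale_to_seconds(s, ts0_us) for s, _ in nonempty]

    seg_meta = nonempty[0][1]
    gaze, gyro, accel, ttl, video_maps, report = concat_segments(
        segments, rate=seg_meta.get("nominal_rate_hz"), report=report
    )

    rec_meta = _read_json(rec_dir / "recording.json") or {}
    proj_meta = _read_json(rec_dir.parent.parent / "project.json") or {}
    meta = RecordingMeta(
        project_id=str(proj_meta.get("id", "unknown")),
        project_name=str(proj_meta.get("name", "unknown")),
        participant_id=str(rec_meta.get("participant_id", "unknown")),
        participant_name=str(rec_meta.get("participant_name", "unknown")),
        recording_id=str(rec_meta.get("id", rec_dir.name)),
        recording_name=str(rec_meta.get("name", "unknown")),
        start_time=str(rec_meta.get("start_time", "unknown")),
        nominal_gaze_rate_hz=report.inferred_rate_hz,
        segment_count=len(segments),
        firmware_version=str(seg_meta.get("firmware", "unknown")),
        calibration_status=str(rec_meta.get("calibration_status", "none")),
    )
    recording = Recording(
        meta=meta, gaze=gaze, gyro=gyro, accel=accel, ttl=ttl, video_maps=video_maps
    )
    if cache:
        processed_cache.save(cache_path, recording, report)
    return recording, report
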