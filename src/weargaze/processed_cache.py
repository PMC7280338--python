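"""Single-file HDF5 container for an assembled recording.

Layout: groups ``/gaze``, ``/gyro``, ``/accel``, ``/ttl``, ``/video_maps``
and ``/meta`` (attributes), plus ``/report`` with the assembly bookkeeping.
Gaze column names match the TSV export columns of the CLI.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import h5py
import numpy as np

from .errors import ParseError
from .recording_model import (
    GazeData,
    ImuData,
    Recording,
    RecordingMeta,
    TtlEvent,
    VideoTimeMap,
)

FORMAT_VERSION = 1


def save(path: os.PathLike | str, recording: Recording, report) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = FORMAT_VERSION
        g = f.create_group("gaze")
        for name in GazeData.ARRAY_FIELDS:
            arr = getattr(recording.gaze, name)
            if name == "binocularity":
                g.create_dataset(name, data=arr.astype("S15"))
            else:
                g.create_dataset(name, data=arr)
        for label, imu in (("gyro", recording.gyro), ("accel", recording.accel)):
            grp = f.create_group(label)
            grp.create_dataset("t", data=imu.t)
            grp.create_dataset("values", data=imu.values)
        ttl = f.create_group("ttl")
        ttl.create_dataset("t", data=np.array([e.t for e in recording.ttl]))
        ttl.create_dataset("value", data=np.array([e.value for e in recording.ttl], dtype=np.int64))
        vm = f.create_group("video_maps")
        for m in recording.video_maps:
            grp = vm.create_group(m.stream_id)
            grp.create_dataset("media_t", data=m.media_t)
            grp.create_dataset("data_t", data=m.data_t)
        meta = f.create_group("meta")
        for fld in dataclasses.fields(recording.meta):
            meta.attrs[fld.name] = getattr(recording.meta, fld.name)
        rep = f.create_group("report")
        for fld in dataclasses.fields(report):
            value = getattr(report, fld.name)
            rep.attrs[fld.name] = value if not isinstance(value, list) else np.asarray(value)


def load(path: os.PathLike | str):
    """Load (Recording, AssemblyReport) from a cache file."""
    from .stream_assembly import AssemblyReport  # avoid circular import at module load

    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format_version") != FORMAT_VERSION:
                raise ParseError(
                    f"{path}: unsupported cache format version "
                    f"{f.attrs.get('format_version')!r}"
                )
            g = f["gaze"]
            kwargs = {}
            for name in GazeData.ARRAY_FIELDS:
                arr = g[name][()]
                if name == "binocularity":
                    arr = arr.astype("U15")
                kwargs[name] = arr
            gaze = GazeData(**kwargs)
            gyro = ImuData(t=f["gyro/t"][()], values=f["gyro/values"][()].reshape(-1, 3))
            accel = ImuData(t=f["accel/t"][()], values=f["accel/values"][()].reshape(-1, 3))
            ttl = [
                TtlEvent(t=float(t), value=int(v))
                for t, v in zip(f["ttl/t"][()], f["ttl/value"][()])
            ]
            video_maps = [
                VideoTimeMap(
                    media_t=f[f"video_maps/{sid}/media_t"][()],
                    data_t=f[f"video_maps/{sid}/data_t"][()],
                    stream_id=sid,
                )
                for sid in f["video_maps"]
            ]
            meta = RecordingMeta(
                **{
                    fld.name: _coerce(fld, f["meta"].attrs[fld.name])
                    for fld in dataclasses.fields(RecordingMeta)
                }
            )
            report = AssemblyReport()
            for fld in dataclasses.fields(report):
                if fld.name in f["report"].attrs:
                    value = f["report"].attrs[fld.name]
                    if fld.name == "segment_boundaries":
                        value = [float(v) for v in np.atleast_1d(value)]
                    else:
                        value = int(value)
                    setattr(report, fld.name, value)
    except (OSError, KeyError) as exc:
        raise ParseError(f"corrupt or unreadable cache file {path}: {exc}") from exc
    return Recording(meta=meta, gaze=gaze, gyro=gyro, accel=accel, ttl=ttl, video_maps=video_maps), report


def _coerce(fld: dataclasses.Field, value):
    return int(value) if fld.type == "int" else str(value)
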