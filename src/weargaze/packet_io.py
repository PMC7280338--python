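"""Reader/writer for the gzip-compressed line-delimited JSON packet dialect.

Each segment of a recording is a file ``livedata.json.gz`` holding one JSON
object per line.  Keys: ``ts`` (integer microseconds on the recording clock),
``s`` (status integer, 0 = valid), ``gidx`` (gaze-sample group index, present
for gaze-family packets only), ``eye`` ("left"/"right", present for per-eye
packets only) and exactly one payload key:

========  =================  ======  ===========================
key       kind               length  payload meaning
========  =================  ======  ===========================
``gd``    gaze_dir           3       gaze direction unit vector
``pc``    pupil_center       3       pupil center, mm
``pd``    pupil_diameter     1       pupil diameter, mm
``gp``    gaze_point_2d      2       gaze on scene image, [0,1]^2
``gp3``   gaze_point_3d      3       3-D gaze point, mm
``gy``    gyro               3       angular rate, deg/s
``ac``    accel              3       acceleration, m/s^2
``vts``   vts                1       media time, microseconds
``sig``   ttl                1       TTL level/pulse code
========  =================  ======  ===========================

Scalar payloads (``pd``, ``vts``, ``sig``) are encoded as bare numbers.
A per-segment ``segment.json`` carries ``{segment_index, nominal_rate_hz?,
calibration_status?, firmware?}``.
"""

from __future__ import annotations

import gzip
import io
import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import PacketError, ParseError, UnknownPacketKind

log = logging.getLogger(__name__)

SEGMENT_DATA_FILE = "livedata.json.gz"
SEGMENT_META_FILE = "segment.json"
EYE_VIDEO_TIME_FILE = "evts.json.gz"

#: payload key -> (kind, payload length)
PAYLOAD_KEYS: dict[str, tuple[str, int]] = {
    "gd": ("gaze_dir", 3),
    "pc": ("pupil_center", 3),
    "pd": ("pupil_diameter", 1),
    "gp": ("gaze_point_2d", 2),
    "gp3": ("gaze_point_3d", 3),
    "gy": ("gyro", 3),
    "ac": ("accel", 3),
    "vts": ("vts", 1),
    "sig": ("ttl", 1),
}
KIND_TO_KEY = {kind: key for key, (kind, _n) in PAYLOAD_KEYS.items()}

#: kinds that are reported per eye (and therefore carry an ``eye`` key)
PER_EYE_KINDS = frozenset({"gaze_dir", "pupil_center", "pupil_diameter"})
#: kinds that belong to a gaze sample group (carry ``gidx``)
GAZE_FAMILY_KINDS = frozenset(
    {"gaze_dir", "pupil_center", "pupil_diameter", "gaze_point_2d", "gaze_point_3d"}
)


@dataclass(frozen=True)
class RawPacket:
    """One decoded packet of the dialect."""

    ts: int  # microseconds on the recording clock
    status: int  # 0 = valid
    kind: str
    payload: tuple[float, ...]
    eye: str = "none"  # "left" | "right" | "none"
    gidx: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in KIND_TO_KEY:
            raise PacketError(f"unknown packet kind {self.kind!r}")
        if self.ts < 0:
            raise PacketError(f"negative timestamp {self.ts}")
        want = PAYLOAD_KEYS[KIND_TO_KEY[self.kind]][1]
        if len(self.payload) != want:
            raise PacketError(
                f"{self.kind} payload has length {len(self.payload)}, expected {want}"
            )
        if (self.eye != "none") != (self.kind in PER_EYE_KINDS):
            raise PacketError(
                f"eye={self.eye!r} is not valid for packet kind {self.kind!r}"
            )


@dataclass
class ReadReport:
    """Summary counts emitted by :func:`read_segment`."""

    total_lines: int = 0
    decoded: int = 0
    dropped: int = 0
    unknown_kind: int = 0
    per_kind: dict[str, int] = field(default_factory=dict)


def decode_packet(line: str) -> RawPacket:
    """Decode one JSON line into a :class:`RawPacket`.

    Unknown keys in the object are ignored.  Raises :class:`PacketError` on
    malformed JSON, bad payloads or missing required keys, and
    :class:`UnknownPacketKind` when no known payload key is present.
    """
    try:
        obj = json.loads(line)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise PacketError(f"malformed JSON: {exc}") from exc
    if not isinstance(obj, dict):
        raise PacketError("packet line is not a JSON object")

    keys = [k for k in obj if k in PAYLOAD_KEYS]
    if not keys:
        raise UnknownPacketKind(f"no known payload key in {sorted(obj)}")
    if len(keys) > 1:
        raise PacketError(f"multiple payload keys {keys} in one packet")
    key = keys[0]
    kind, want = PAYLOAD_KEYS[key]

    raw = obj[key]
    if isinstance(raw, (int, float)) and not isinstance(raw, bool):
        payload: tuple[float, ...] = (float(raw),)
    elif isinstance(raw, list) and all(
        isinstance(v, (int, float)) and not isinstance(v, bool) for v in raw
    ):
        payload = tuple(float(v) for v in raw)
    else:
        raise PacketError(f"payload {key}={raw!r} is not numeric")

    try:
        ts = obj["ts"]
    except KeyError:
        raise PacketError("packet has no 'ts' key") from None
    if not isinstance(ts, int) or isinstance(ts, bool):
        raise PacketError(f"ts={ts!r} is not an integer")

    status = obj.get("s", 0)
    if not isinstance(status, int) or isinstance(status, bool):
        raise PacketError(f"s={status!r} is not an integer")

    eye = obj.get("eye", "none")
    if eye not in ("left", "right", "none"):
        raise PacketError(f"eye={eye!r} is not one of left/right/none")

    gidx = obj.get("gidx")
    if gidx is not None and (not isinstance(gidx, int) or isinstance(gidx, bool)):
        raise PacketError(f"gidx={gidx!r} is not an integer")

    return RawPacket(ts=ts, status=status, kind=kind, payload=payload, eye=eye, gidx=gidx)


def encode_packet(packet: RawPacket) -> str:
    """Encode a packet as one JSON line (inverse of :func:`decode_packet`)."""
    obj: dict = {"ts": packet.ts, "s": packet.status}
    if packet.gidx is not None:
        obj["gidx"] = packet.gidx
    if packet.eye != "none":
        obj["eye"] = packet.eye
    key = KIND_TO_KEY[packet.kind]
    _, n = PAYLOAD_KEYS[key]
    values = [int(v) if float(v).is_integer() else v for v in packet.payload]
    obj[key] = values[0] if n == 1 else values
    return json.dumps(obj, separators=(",", ":"), sort_keys=False)


def _open_maybe_gzip(path: Path) -> io.TextIOBase:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def read_segment(file: os.PathLike | str, report: ReadReport | None = None) -> Iterator[RawPacket]:
    """Yield packets from a segment data file in file order.

    Malformed lines are skipped and counted; packets of unknown kind are
    skipped and counted separately.  Pass a :class:`ReadReport` to receive
    the counts.  A missing or corrupt file raises :class:`ParseError`.
    """
    path = Path(file)
    if not path.is_file():
        raise ParseError(f"segment file not found: {path}")
    if report is None:
        report = ReadReport()
    try:
        with _open_maybe_gzip(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                report.total_lines += 1
                try:
                    packet = decode_packet(line)
                except UnknownPacketKind:
                    report.unknown_kind += 1
                    continue
                except PacketError as exc:
                    report.dropped += 1
                    log.debug("dropped packet line: %s", exc)
                    continue
                report.decoded += 1
                report.per_kind[packet.kind] = report.per_kind.get(packet.kind, 0) + 1
                yield packet
    except (OSError, EOFError) as exc:
        raise ParseError(f"cannot read segment file {path}: {exc}") from exc
    if report.dropped:
        log.warning("%s: dropped %d malformed packet line(s)", path, report.dropped)
    if report.unknown_kind:
        log.info("%s: skipped %d packet(s) of unknown kind", path, report.unknown_kind)


def write_segment(packets: Iterable[RawPacket], file: os.PathLike | str) -> int:
    """Write packets to a segment data file; returns the number written.

    Files ending in ``.gz`` are gzip-compressed with a zeroed mtime so that
    identical packet sequences produce byte-identical files.
    """
    path = Path(file)
    n = 0
    try:
        if path.suffix == ".gz":
            with open(path, "wb") as raw:
                with gzip.GzipFile(filename="", mode="wb", fileobj=raw, mtime=0) as gz:
                    with io.TextIOWrapper(gz, encoding="utf-8", newline="\n") as fh:
                        for packet in packets:
                            fh.write(encode_packet(packet))
                            fh.write("\n")
                            n += 1
        else:
            with open(path, "wt", encoding="utf-8", newline="\n") as fh:
                for packet in packets:
                    fh.write(encode_packet(packet))
                    fh.write("\n")
                    n += 1
    except OSError as exc:
        raise ParseError(f"cannot write segment file {path}: {exc}") from exc
    return n


def read_segment_meta(segment_dir: os.PathLike | str) -> dict:
    """Read ``segment.json`` from a segment directory; {} when absent."""
    path = Path(segment_dir) / SEGMENT_META_FILE
    if not path.is_file():
        return {}
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            meta = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if not isinstance(meta, dict):
        raise ParseError(f"{path} does not contain a JSON object")
    return meta


def write_segment_meta(segment_dir: os.PathLike | str, meta: dict) -> None:
    path = Path(segment_dir) / SEGMENT_META_FILE
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
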