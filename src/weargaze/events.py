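"""Event-annotation streams: contiguous labeled episodes with flags.

An event stream is a named, time-ordered, non-overlapping sequence of
labeled intervals (annotations) over a recording's timeline, each optionally
carrying flags drawn from the per-label flag vocabulary (e.g. a "saccade"
annotation flagged "vergence").  Streams originate from manual editing, from
TTL activity, from text files (resettable to the file's contents), or from
registered classifier plugins.

Editing operations are pure: each returns a new stream and validates the
stream invariants (ordering, non-overlap, labels within the configured
categories).  Manual streams may leave uncoded spans; classifier output must
cover the full timeline.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .errors import (
    CategoryError,
    ConfigError,
    EventFileFormatError,
    FlagError,
    LockedStreamError,
    NoOpError,
    OverlapError,
    ParseError,
    RangeError,
    StreamValidationError,
)
from .recording_model import Recording, TtlEvent

CODING_FILE = "coding.json"

SLOW = "slow"
FAST = "fast"
GAP = "missing"


@dataclass(frozen=True)
class Annotation:
    """A half-open labeled interval [start, end) in recording seconds."""

    start: float
    end: float
    label: str
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (self.end > self.start):
            raise RangeError(f"annotation end {self.end} must exceed start {self.start}")
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Category:
    label: str
    flag_labels: tuple[str, ...] = ()


@dataclass
class EventStream:
    name: str
    categories: tuple[Category, ...]
    annotations: tuple[Annotation, ...] = ()
    source: str = "manual"  # manual | ttl | file | classifier
    locked: bool = False
    file_snapshot: tuple[Annotation, ...] | None = None  # for reset of file streams
    source_file: str | None = None  # origin of a file-derived stream

    def __post_init__(self) -> None:
        self.categories = tuple(self.categories)
        self.annotations = tuple(self.annotations)
        validate_stream(self)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(c.label for c in self.categories)

    def category(self, label: str) -> Category:
        for c in self.categories:
            if c.label == label:
                return c
        raise CategoryError(
            f"label {label!r} is not among stream {self.name!r} categories {self.labels}"
        )

    @property
    def total_annotated(self) -> float:
        return sum(a.duration for a in self.annotations)


def validate_stream(stream: EventStream, duration: float | None = None) -> None:
    """Check ordering, non-overlap, category membership and flag validity."""
    prev_end = -math.inf
    for i, a in enumerate(stream.annotations):
        if a.start < 0:
            raise StreamValidationError(f"annotation {i} starts before 0 ({a.start})")
        if a.start < prev_end:
            raise StreamValidationError(
                f"annotations overlap at index {i} ([{a.start}, {a.end}) begins "
                f"before previous end {prev_end})"
            )
        cat = stream.category(a.label)
        bad = a.flags - set(cat.flag_labels)
        if bad:
            raise FlagError(f"flags {sorted(bad)} are not valid for label {a.label!r}")
        if duration is not None and a.end > duration + 1e-9:
            raise StreamValidationError(
                f"annotation {i} ends at {a.end} beyond recording duration {duration}"
            )
        prev_end = a.end


def _edited(stream: EventStream, annotations: Sequence[Annotation]) -> EventStream:
    new = replace(stream, annotations=tuple(sorted(annotations, key=lambda a: a.start)))
    return new


def _require_unlocked(stream: EventStream) -> None:
    if stream.locked:
        raise LockedStreamError(f"stream {stream.name!r} is locked ({stream.source}-derived)")


def add_annotation(
    stream: EventStream, t_click: float, label: str, flags: Sequence[str] = ()
) -> EventStream:
    """Add an annotation from the end of the previous annotation to t_click.

    The new interval spans from the end of the latest annotation ending at
    or before ``t_click`` (or from 0) up to ``t_click``.
    """
    _require_unlocked(stream)
    stream.category(label)
    for a in stream.annotations:
        if a.start <= t_click < a.end:
            raise OverlapError(
                f"time {t_click} lies inside existing annotation [{a.start}, {a.end})"
            )
    prev_ends = [a.end for a in stream.annotations if a.end <= t_click]
    start = max(prev_ends, default=0.0)
    if t_click <= start:
        raise RangeError(f"click at {t_click} leaves no room after previous end {start}")
    new = Annotation(start=start, end=t_click, label=label, flags=frozenset(flags))
    return _edited(stream, (*stream.annotations, new))


def split_annotation(stream: EventStream, t: float) -> EventStream:
    """Split the annotation containing t into two at t (label/flags kept)."""
    _require_unlocked(stream)
    for i, a in enumerate(stream.annotations):
        if a.start < t < a.end:
            left = Annotation(a.start, t, a.label, a.flags)
            right = Annotation(t, a.end, a.label, a.flags)
            return _edited(
                stream, (*stream.annotations[:i], left, right, *stream.annotations[i + 1 :])
            )
    raise NoOpError(f"time {t} is not strictly inside any annotation")


def relabel_annotation(
    stream: EventStream, index: int, new_label: str, new_flags: Sequence[str] = ()
) -> EventStream:
    _require_unlocked(stream)
    a = _get(stream, index)
    cat = stream.category(new_label)
    bad = frozenset(new_flags) - set(cat.flag_labels)
    if bad:
        raise FlagError(f"flags {sorted(bad)} are not valid for label {new_label!r}")
    new = Annotation(a.start, a.end, new_label, frozenset(new_flags))
    return _edited(stream, (*stream.annotations[:index], new, *stream.annotations[index + 1 :]))


def remove_annotation(stream: EventStream, index: int) -> EventStream:
    _require_unlocked(stream)
    _get(stream, index)
    return _edited(stream, (*stream.annotations[:index], *stream.annotations[index + 1 :]))


def merge_adjacent_equal(stream: EventStream) -> EventStream:
    """Coalesce touching annotations with identical label and flags."""
    merged: list[Annotation] = []
    for a in stream.annotations:
        if (
            merged
            and merged[-1].end == a.start
            and merged[-1].label == a.label
            and merged[-1].flags == a.flags
        ):
            merged[-1] = Annotation(merged[-1].start, a.end, a.label, a.flags)
        else:
            merged.append(a)
    return _edited(stream, merged)


def move_boundary(
    stream: EventStream, boundary_index: int, new_t: float, duration: float | None = None
) -> EventStream:
    """Move the boundary_index-th distinct annotation edge to new_t.

    A shared edge of two adjacent annotations shifts for both; an outer edge
    grows or shrinks its annotation against uncoded time.  ``new_t`` must
    stay strictly between the neighboring edges (and within [0, duration]).
    """
    _require_unlocked(stream)
    edges = sorted({e for a in stream.annotations for e in (a.start, a.end)})
    if not 0 <= boundary_index < len(edges):
        raise RangeError(f"boundary index {boundary_index} out of range (0..{len(edges) - 1})")
    old = edges[boundary_index]
    lo = edges[boundary_index - 1] if boundary_index > 0 else 0.0
    hi = edges[boundary_index + 1] if boundary_index + 1 < len(edges) else (
        duration if duration is not None else math.inf
    )
    if boundary_index == 0:
        lo = -math.inf  # first edge may move toward 0 freely
    if not (lo < new_t < hi) or new_t < 0:
        raise RangeError(
            f"new boundary {new_t} must lie strictly between {max(lo, 0.0)} and {hi}"
        )
    moved = [
        Annotation(
            new_t if a.start == old else a.start,
            new_t if a.end == old else a.end,
            a.label,
            a.flags,
        )
        for a in stream.annotations
    ]
    return _edited(stream, moved)


def _get(stream: EventStream, index: int) -> Annotation:
    if not 0 <= index < len(stream.annotations):
        raise RangeError(f"annotation index {index} out of range")
    return stream.annotations[index]


# ---------------------------------------------------------------------------
# stream sources: TTL, text files, classifiers


def ttl_stream(
    ttl: Sequence[TtlEvent],
    scheme: str = "levels",
    duration: float | None = None,
    gaze_interval: float = 0.02,
    name: str = "ttl",
) -> EventStream:
    """Build a locked event stream from TTL activity.

    ``levels``: each annotation spans from one level change to the next (the
    last one to ``duration``), labeled by the held level.  ``edges``: each
    level change becomes a minimal annotation one gaze interval long, so
    stream invariants (end > start) hold for instantaneous pulses.
    """
    if scheme not in ("levels", "edges"):
        raise ConfigError(f"unknown TTL scheme {scheme!r}")
    events = sorted(ttl, key=lambda e: e.t)
    labels = sorted({str(e.value) for e in events})
    categories = tuple(Category(label=lb) for lb in labels)
    annotations: list[Annotation] = []
    for i, e in enumerate(events):
        nxt = events[i + 1].t if i + 1 < len(events) else (duration if duration is not None else None)
        if scheme == "levels":
            end = nxt if nxt is not None else e.t + gaze_interval
        else:
            end = e.t + gaze_interval
            if nxt is not None:
                end = min(end, nxt)
        if end > e.t:
            annotations.append(Annotation(e.t, end, str(e.value)))
    return EventStream(
        name=name, categories=categories, annotations=tuple(annotations), source="ttl", locked=True
    )


EVENT_FILE_COLUMNS = ["start_s", "end_s", "label", "flags"]


def load_events_from_text(
    file: os.PathLike | str, categories: Sequence[Category], name: str | None = None
) -> EventStream:
    """Load an event stream from a TSV file (header start_s, end_s, label[, flags]).

    Flags are semicolon-separated.  The loaded annotations become both the
    stream content and a snapshot that :func:`reset_stream` restores after
    manual edits.
    """
    path = Path(file)
    if not path.is_file():
        raise EventFileFormatError(f"event file not found: {path}")
    with open(path, "rt", encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise EventFileFormatError(f"{path}: empty file (expected a header row)")
    header = lines[0].split("\t")
    if header[:3] != EVENT_FILE_COLUMNS[:3]:
        raise EventFileFormatError(
            f"{path}: header must start with {EVENT_FILE_COLUMNS[:3]}, got {header}"
        )
    has_flags = len(header) > 3 and header[3] == "flags"
    annotations: list[Annotation] = []
    for row_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        try:
            start, end, label = float(fields[0]), float(fields[1]), fields[2]
        except (IndexError, ValueError) as exc:
            raise EventFileFormatError(f"{path}: bad row {row_no}: {exc}") from exc
        flags = (
            frozenset(f for f in fields[3].split(";") if f)
            if has_flags and len(fields) > 3
            else frozenset()
        )
        try:
            annotations.append(Annotation(start, end, label, flags))
        except RangeError as exc:
            raise EventFileFormatError(f"{path}: row {row_no}: {exc}") from exc
    annotations.sort(key=lambda a: a.start)
    for i, (a, b) in enumerate(zip(annotations, annotations[1:])):
        if b.start < a.end:
            raise EventFileFormatError(
                f"{path}: rows overlap ([{a.start}, {a.end}) and [{b.start}, {b.end}))"
            )
    try:
        stream = EventStream(
            name=name or path.stem,
            categories=tuple(categories),
            annotations=tuple(annotations),
            source="file",
            locked=False,
            file_snapshot=tuple(annotations),
            source_file=str(path),
        )
    except CategoryError as exc:
        raise CategoryError(f"{path}: {exc}") from exc
    return stream


def save_events_to_text(stream: EventStream, file: os.PathLike | str) -> None:
    with open(file, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(EVENT_FILE_COLUMNS) + "\n")
        for a in stream.annotations:
            fh.write(f"{a.start:.6f}\t{a.end:.6f}\t{a.label}\t{';'.join(sorted(a.flags))}\n")


def reset_stream(stream: EventStream) -> EventStream:
    """Restore a file-derived stream to its loaded (snapshot) contents."""
    if stream.file_snapshot is None:
        raise NoOpError(f"stream {stream.name!r} has no file snapshot to reset to")
    return replace(stream, annotations=stream.file_snapshot)


# ---------------------------------------------------------------------------
# classifier plugins

CLASSIFIER_REGISTRY: dict[str, Callable] = {}


def register_classifier(name: str) -> Callable:
    """Decorator registering a classifier entry point by name.

    A classifier is called with the Recording followed by its parameter
    values as keyword arguments and must return an EventStream covering the
    full timeline.
    """

    def deco(fn: Callable) -> Callable:
        CLASSIFIER_REGISTRY[name] = fn
        return fn

    return deco


@dataclass(frozen=True)
class ClassifierParameter:
    name: str
    value: float
    min: float
    max: float
    user_settable: bool = True

    def __post_init__(self) -> None:
        if not (self.min <= self.value <= self.max):
            raise ConfigError(
                f"parameter {self.name!r}: value {self.value} outside [{self.min}, {self.max}]"
            )


@dataclass(frozen=True)
class ClassifierSpec:
    id: str
    entry_point: str
    parameters: tuple[ClassifierParameter, ...] = ()

    def with_values(self, **overrides: float) -> "ClassifierSpec":
        known = {p.name for p in self.parameters}
        unknown = set(overrides) - known
        if unknown:
            raise ConfigError(f"unknown parameter(s) {sorted(unknown)} for classifier {self.id!r}")
        params = tuple(
            replace(p, value=overrides.get(p.name, p.value)) for p in self.parameters
        )
        return replace(self, parameters=params)


def run_classifier(recording: Recording, spec: ClassifierSpec) -> EventStream:
    """Invoke a registered classifier and validate its output stream."""
    try:
        fn = CLASSIFIER_REGISTRY[spec.entry_point]
    except KeyError:
        raise ConfigError(
            f"no classifier registered under {spec.entry_point!r}; "
            f"known: {sorted(CLASSIFIER_REGISTRY)}"
        ) from None
    kwargs = {p.name: p.value for p in spec.parameters}
    stream = fn(recording, **kwargs)
    if not isinstance(stream, EventStream):
        raise StreamValidationError(
            f"classifier {spec.id!r} returned {type(stream).__name__}, not an EventStream"
        )
    try:
        validate_stream(stream, duration=recording.duration_s)
    except (StreamValidationError, FlagError, CategoryError) as exc:
        raise StreamValidationError(f"classifier {spec.id!r} produced an invalid stream: {exc}") from exc
    stream = replace(stream, source="classifier", name=spec.id)
    return stream


def _binocular_speed(recording: Recording) -> np.ndarray:
    """Mean of the finite per-eye speeds; NaN where neither eye has one."""
    vel = recording.derived.velocity
    pair = np.stack([vel.left_speed, vel.right_speed])
    with np.errstate(invalid="ignore"):
        finite = np.isfinite(pair)
        both = finite.sum(axis=0)
        summed = np.where(finite, pair, 0.0).sum(axis=0)
        out = np.full(pair.shape[1], np.nan)
        np.divide(summed, both, out=out, where=both > 0)
    return out


@register_classifier("slow_fast")
def classify_slow_fast(
    recording: Recording,
    velocity_threshold_dps: float = 100.0,
    min_fast_ms: float = 10.0,
    min_slow_ms: float = 40.0,
) -> EventStream:
    """Velocity-threshold slow/fast-phase classification with run merging.

    Samples whose binocular-mean eye speed (the finite eye when only one is
    available) exceeds the threshold are fast, the rest slow; spans without
    valid gaze data are "missing".  A sample with valid gaze but no defined
    speed (the filter window touches a gap or the series edge) is not above
    threshold and therefore slow.  Slow or fast runs shorter than their
    minimum duration are merged into a neighbor, shortest run first, each
    into its longer non-missing neighbor (ties to the earlier one); runs
    bordered only by missing spans or recording edges are kept.  The output
    covers the full timeline with no gaps.
    """
    from .gaze_kinematics import compute_kinematics

    if recording.derived is None:
        compute_kinematics(recording)
    from .recording_model import MISSING as GAZE_MISSING

    speed = _binocular_speed(recording)
    n = len(speed)
    dt = recording.dt
    gaze_missing = recording.gaze.binocularity == GAZE_MISSING
    categories = (Category(SLOW), Category(FAST), Category(GAP))
    if n == 0 or bool(gaze_missing.all()):
        ann = (Annotation(0.0, max(recording.duration_s, dt), GAP),)
        return EventStream(
            name="slow_fast", categories=categories, annotations=ann, source="classifier"
        )

    with np.errstate(invalid="ignore"):
        fast = np.isfinite(speed) & (speed > velocity_threshold_dps)
    codes = np.where(gaze_missing, 2, np.where(fast, 1, 0))
    runs: list[list] = []  # [code, start_idx, length]
    for i, c in enumerate(codes):
        if runs and runs[-1][0] == c:
            runs[-1][2] += 1
        else:
            runs.append([int(c), i, 1])

    min_len = {0: min_slow_ms / 1000.0, 1: min_fast_ms / 1000.0}

    def _mergeable(idx: int) -> bool:
        code, _s, length = runs[idx]
        if code == 2 or length * dt >= min_len[code]:
            return False
        neighbors = [j for j in (idx - 1, idx + 1) if 0 <= j < len(runs) and runs[j][0] != 2]
        return bool(neighbors)

    while True:
        candidates = [i for i in range(len(runs)) if _mergeable(i)]
        if not candidates:
            break
        idx = min(candidates, key=lambda i: (runs[i][2], i))
        left = idx - 1 if idx - 1 >= 0 and runs[idx - 1][0] != 2 else None
        right = idx + 1 if idx + 1 < len(runs) and runs[idx + 1][0] != 2 else None
        if left is not None and right is not None:
            target = left if runs[left][2] >= runs[right][2] else right
        else:
            target = left if left is not None else right
        runs[idx][0] = runs[target][0]
        # coalesce adjacent equal-code runs
        merged: list[list] = []
        for r in runs:
            if merged and merged[-1][0] == r[0]:
                merged[-1][2] += r[2]
            else:
                merged.append(r)
        runs = merged

    label_of = {0: SLOW, 1: FAST, 2: GAP}
    t0 = float(recording.gaze.t[0]) if len(recording.gaze) else 0.0
    annotations = tuple(
        Annotation(t0 + s * dt, t0 + (s + length) * dt, label_of[code])
        for code, s, length in runs
    )
    return EventStream(
        name="slow_fast", categories=categories, annotations=annotations, source="classifier"
    )


DEFAULT_SLOW_FAST_SPEC = ClassifierSpec(
    id="slow_fast",
    entry_point="slow_fast",
    parameters=(
        ClassifierParameter("velocity_threshold_dps", 100.0, 10.0, 1000.0),
        ClassifierParameter("min_fast_ms", 10.0, 0.0, 500.0),
        ClassifierParameter("min_slow_ms", 40.0, 0.0, 2000.0),
    ),
)


# ---------------------------------------------------------------------------
# persistence


def stream_to_dict(stream: EventStream) -> dict:
    return {
        "name": stream.name,
        "source": stream.source,
        "locked": stream.locked,
        "source_file": stream.source_file,
        "categories": [
            {"label": c.label, "flags": list(c.flag_labels)} for c in stream.categories
        ],
        "annotations": [
            {
                "start_s": a.start,
                "end_s": a.end,
                "label": a.label,
                "flags": sorted(a.flags),
            }
            for a in stream.annotations
        ],
    }


def stream_from_dict(obj: dict) -> EventStream:
    try:
        categories = tuple(
            Category(label=c["label"], flag_labels=tuple(c.get("flags", ())))
            for c in obj["categories"]
        )
        annotations = tuple(
            Annotation(
                start=float(a["start_s"]),
                end=float(a["end_s"]),
                label=a["label"],
                flags=frozenset(a.get("flags", ())),
            )
            for a in obj["annotations"]
        )
        return EventStream(
            name=obj["name"],
            categories=categories,
            annotations=annotations,
            source=obj.get("source", "manual"),
            locked=bool(obj.get("locked", False)),
            source_file=obj.get("source_file"),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed stream object in coding file: {exc}") from exc


def save_coding(streams: Sequence[EventStream], directory: os.PathLike | str) -> Path:
    """Write all event streams to coding.json alongside the recording."""
    path = Path(directory) / CODING_FILE
    payload = {"streams": [stream_to_dict(s) for s in streams]}
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_coding(directory: os.PathLike | str) -> list[EventStream]:
    """Load event streams from coding.json; an absent file yields []."""
    path = Path(directory) / CODING_FILE
    if not path.is_file():
        return []
    try:
        with open(path, "rt", encoding="utf-8") as fh:
            payload = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise ParseError(f"corrupt coding file {path}: {exc}") from exc
    if not isinstance(payload, dict) or not isinstance(payload.get("streams"), list):
        raise ParseError(f"corrupt coding file {path}: expected {{'streams': [...]}}")
    return [stream_from_dict(s) for s in payload["streams"]]
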