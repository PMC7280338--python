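"""Synthetic wearable eye-tracker recordings in the packet dialect.

The generator emulates what the headset writes to its memory card: a project
tree with opaque folder names, per-recording metadata, and per-segment
gzip-compressed line-delimited JSON packet streams holding binocular gaze,
pupil, gyroscope, accelerometer, TTL and video-timestamp packets.  The
scanpath is scripted from fixation, saccade, pursuit and gap episodes;
saccades follow a minimum-jerk displacement profile, whose closed-form peak
velocity (1.875 x amplitude / duration) makes it a convenient oracle — it is
a modeling convenience, not a claim about real saccade dynamics.  Fixations
add iid Gaussian noise on azimuth and elevation, independently per eye; gaps
and randomly injected loss delete packets; monocular spans drop one eye's
packets to exercise the monocular validity path.

Generation is fully deterministic for a given script (including its seed):
the output tree is byte-identical across runs.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .events import GAP, FAST, SLOW, Annotation, Category, EventStream
from .gaze_kinematics import fick_compose
from .packet_io import (
    SEGMENT_DATA_FILE,
    RawPacket,
    write_segment,
    write_segment_meta,
)

MIN_JERK_PEAK_FACTOR = 1.875  # peak velocity = 1.875 * amplitude / duration

_EPISODE_KINDS = ("fixation", "saccade", "pursuit", "gap")


@dataclass(frozen=True)
class Episode:
    """One scripted scanpath episode.

    fixation: hold (theta, phi) (current position when None).
    saccade: minimum-jerk move to (theta, phi), or by ``amplitude`` degrees
    along azimuth when no target is given.
    pursuit: constant-velocity drift at ``velocity`` = (dtheta, dphi) deg/s.
    gap: tracking loss — packets for these samples are not written.
    """

    kind: str
    duration_ms: float
    theta: float | None = None
    phi: float | None = None
    velocity: tuple[float, float] | None = None
    amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _EPISODE_KINDS:
            raise ConfigError(f"unknown episode kind {self.kind!r}")
        if self.duration_ms <= 0:
            raise ConfigError(f"episode duration must be positive, got {self.duration_ms}")


def fixation(duration_ms: float, theta: float | None = None, phi: float | None = None) -> Episode:
    return Episode("fixation", duration_ms, theta=theta, phi=phi)


def saccade(
    duration_ms: float,
    theta: float | None = None,
    phi: float | None = None,
    amplitude: float | None = None,
) -> Episode:
    if theta is None and amplitude is None:
        raise ConfigError("saccade needs a target (theta/phi) or an amplitude")
    return Episode("saccade", duration_ms, theta=theta, phi=phi, amplitude=amplitude)


def pursuit(duration_ms: float, velocity: tuple[float, float]) -> Episode:
    return Episode("pursuit", duration_ms, velocity=velocity)


def gap(duration_ms: float) -> Episode:
    return Episode("gap", duration_ms)


@dataclass
class ScanpathScript:
    """Full description of one synthetic recording."""

    episodes: tuple[Episode, ...]
    rate_hz: int = 50
    noise_sd: float = 0.05  # degrees per axis, typical wearable-tracker precision
    ttl_times: tuple[float, ...] = ()  # seconds; button presses (100-ms high pulse)
    segment_split_s: float | None = None  # device splits the recording here
    segment_gap_s: float = 1.0  # recording hole at the split
    loss_percent: float = 0.0  # extra random per-sample loss
    monocular_spans: tuple[tuple[float, float, str], ...] = ()  # (start, end, eye dropped)
    seed: int = 0
    project_name: str = "SyntheticStudy"
    recording_name: str = "Recording001"
    participant_name: str = "P01"
    calibration_status: str = "calibrated"
    start_time: str = "2024-05-01T10:00:00"

    def __post_init__(self) -> None:
        self.episodes = tuple(self.episodes)
        if self.rate_hz not in (50, 100):
            raise ConfigError(f"rate_hz must be 50 or 100, got {self.rate_hz}")
        if self.noise_sd < 0 or not (0 <= self.loss_percent < 100):
            raise ConfigError("noise_sd must be >= 0 and loss_percent in [0, 100)")

    @property
    def duration_s(self) -> float:
        return sum(e.duration_ms for e in self.episodes) / 1000.0

    def to_json(self) -> str:
        obj = {
            "episodes": [
                {k: v for k, v in vars(e).items() if v is not None} for e in self.episodes
            ],
            **{
                k: v
                for k, v in vars(self).items()
                if k != "episodes"
            },
        }
        return json.dumps(obj, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ScanpathScript":
        obj = json.loads(text)
        episodes = tuple(
            Episode(**{**e, "velocity": tuple(e["velocity"]) if "velocity" in e else None})
            for e in obj.pop("episodes")
        )
        obj["ttl_times"] = tuple(obj.get("ttl_times", ()))
        obj["monocular_spans"] = tuple(tuple(s) for s in obj.get("monocular_spans", ()))
        return cls(episodes=episodes, **obj)


@dataclass
class SynthResult:
    """Everything a test oracle needs about a generated recording."""

    recording_dir: Path
    project_id: str
    recording_id: str
    ground_truth: EventStream  # slow/fast/missing episodes, noiseless boundaries
    t: np.ndarray  # sample times, seconds from recording start
    true_theta: np.ndarray  # noiseless azimuth, degrees
    true_phi: np.ndarray  # noiseless elevation, degrees
    missing_mask: np.ndarray  # samples whose packets were not written
    report: dict = field(default_factory=dict)


def _min_jerk(tau: np.ndarray) -> np.ndarray:
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def min_jerk_peak_velocity(amplitude_deg: float, duration_s: float) -> float:
    """Closed-form peak speed of the minimum-jerk profile, deg/s."""
    return MIN_JERK_PEAK_FACTOR * abs(amplitude_deg) / duration_s


def build_trajectory(script: ScanpathScript) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, EventStream]:
    """Noiseless scanpath: (t, theta, phi, gap_mask, ground-truth events)."""
    rate = script.rate_hz
    dt = 1.0 / rate
    counts = [max(1, round(e.duration_ms / 1000.0 * rate)) for e in script.episodes]
    n = sum(counts)
    t = np.arange(n) * dt
    theta = np.zeros(n)
    phi = np.zeros(n)
    gap_mask = np.zeros(n, dtype=bool)

    first = script.episodes[0]
    cur_th = first.theta if first.theta is not None else 0.0
    cur_ph = first.phi if first.phi is not None else 0.0
    annotations: list[Annotation] = []
    pos = 0
    for e, n_ep in zip(script.episodes, counts):
        sl = slice(pos, pos + n_ep)
        local = np.arange(n_ep) * dt
        T = n_ep * dt
        if e.kind == "fixation":
            cur_th = e.theta if e.theta is not None else cur_th
            cur_ph = e.phi if e.phi is not None else cur_ph
            theta[sl], phi[sl] = cur_th, cur_ph
            label = SLOW
        elif e.kind == "saccade":
            if e.theta is not None:
                tgt_th = e.theta
                tgt_ph = e.phi if e.phi is not None else cur_ph
            else:
                tgt_th, tgt_ph = cur_th + e.amplitude, cur_ph
            s = _min_jerk(local / T)
            theta[sl] = cur_th + (tgt_th - cur_th) * s
            phi[sl] = cur_ph + (tgt_ph - cur_ph) * s
            cur_th, cur_ph = tgt_th, tgt_ph
            label = FAST
        elif e.kind == "pursuit":
            vth, vph = e.velocity
            theta[sl] = cur_th + vth * local
            phi[sl] = cur_ph + vph * local
            cur_th += vth * T
            cur_ph += vph * T
            label = SLOW
        else:  # gap
            theta[sl], phi[sl] = cur_th, cur_ph
            gap_mask[sl] = True
            label = GAP
        start, end = pos * dt, (pos + n_ep) * dt
        if annotations and annotations[-1].label == label:
            prev = annotations.pop()
            annotations.append(Annotation(prev.start, end, label))
        else:
            annotations.append(Annotation(start, end, label))
        pos += n_ep

    truth = EventStream(
        name="ground_truth",
        categories=(Category(SLOW), Category(FAST), Category(GAP)),
        annotations=tuple(annotations),
        source="file",
        locked=True,
    )
    return t, theta, phi, gap_mask, truth


def _rand_id(rng: np.random.Generator, length: int = 7) -> str:
    alphabet = "abcdefghijklmnopqrstuvwxyz234567"
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


TS0_US = 10_000_000  # recording clock does not start at zero


def _gaze_packets(
    script: ScanpathScript,
    t: np.ndarray,
    theta: np.ndarray,
    phi: np.ndarray,
    written: np.ndarray,
    rng: np.random.Generator,
) -> list[RawPacket]:
    n = len(t)
    ts = TS0_US + np.round(t * 1e6).astype(np.int64)
    packets: list[RawPacket] = []
    noise = rng.normal(0.0, script.noise_sd, size=(2, 2, n)) if script.noise_sd > 0 else np.zeros((2, 2, n))
    pd_noise = rng.normal(0.0, 0.02, size=(2, n))

    eye_dropped = np.zeros((2, n), dtype=bool)
    for start, end, eye in script.monocular_spans:
        idx = 0 if eye == "left" else 1
        eye_dropped[idx, (t >= start) & (t < end)] = True

    for i in range(n):
        if not written[i]:
            continue
        dirs = {}
        for e_idx, eye in enumerate(("left", "right")):
            if eye_dropped[e_idx, i]:
                continue
            th = theta[i] + noise[e_idx, 0, i]
            ph = phi[i] + noise[e_idx, 1, i]
            v = fick_compose(th, ph)
            dirs[eye] = v
            x_mm = 32.0 if eye == "left" else -32.0
            packets.append(
                RawPacket(ts=int(ts[i]), status=0, kind="gaze_dir", eye=eye, gidx=i,
                          payload=tuple(round(c, 9) for c in v))
            )
            packets.append(
                RawPacket(ts=int(ts[i]), status=0, kind="pupil_center", eye=eye, gidx=i,
                          payload=(x_mm, 0.0, -35.0))
            )
            packets.append(
                RawPacket(ts=int(ts[i]), status=0, kind="pupil_diameter", eye=eye, gidx=i,
                          payload=(round(3.0 + pd_noise[e_idx, i], 4),))
            )
        if dirs:
            mean_dir = np.mean(list(dirs.values()), axis=0)
            mean_dir /= np.linalg.norm(mean_dir)
            gp = (
                round(min(max(0.5 + theta[i] / 100.0, 0.0), 1.0), 6),
                round(min(max(0.5 - phi[i] / 100.0, 0.0), 1.0), 6),
            )
            packets.append(
                RawPacket(ts=int(ts[i]), status=0, kind="gaze_point_2d", gidx=i, payload=gp)
            )
            packets.append(
                RawPacket(ts=int(ts[i]), status=0, kind="gaze_point_3d", gidx=i,
                          payload=tuple(round(c * 1500.0, 3) for c in mean_dir))
            )
    return packets


def _aux_packets(script: ScanpathScript, duration_s: float, rng: np.random.Generator) -> list[RawPacket]:
    packets: list[RawPacket] = []
    imu_rate = 100
    n_imu = int(duration_s * imu_rate)
    t_imu = np.arange(n_imu) / imu_rate
    ts_imu = TS0_US + np.round(t_imu * 1e6).astype(np.int64)
    gy = rng.normal(0.0, 1.0, size=(n_imu, 3))
    ac = np.array([0.0, -9.81, 0.0]) + rng.normal(0.0, 0.05, size=(n_imu, 3))
    for i in range(n_imu):
        packets.append(RawPacket(ts=int(ts_imu[i]), status=0, kind="gyro",
                                 payload=tuple(round(v, 4) for v in gy[i])))
        packets.append(RawPacket(ts=int(ts_imu[i]), status=0, kind="accel",
                                 payload=tuple(round(v, 4) for v in ac[i])))
    # TTL: 100-ms high pulse per press
    for press in script.ttl_times:
        hi = TS0_US + int(round(press * 1e6))
        packets.append(RawPacket(ts=hi, status=0, kind="ttl", payload=(1.0,)))
        packets.append(RawPacket(ts=hi + 100_000, status=0, kind="ttl", payload=(0.0,)))
    # video-time packets every 5 s: media clock started 0.5 s before data
    k = 0
    while k * 5.0 <= duration_s:
        data_us = TS0_US + int(k * 5_000_000)
        packets.append(RawPacket(ts=data_us, status=0, kind="vts",
                                 payload=(float(500_000 + k * 5_000_000),)))
        k += 1
    return packets


def generate_recording(script: ScanpathScript, out_dir: os.PathLike | str) -> SynthResult:
    """Write a complete synthetic project tree and return its ground truth."""
    rng = np.random.default_rng(script.seed)
    t, theta, phi, gap_mask, truth = build_trajectory(script)
    n = len(t)

    written = ~gap_mask
    n_loss = int(round(script.loss_percent / 100.0 * n))
    if n_loss:
        candidates = np.flatnonzero(written)
        candidates = candidates[(candidates > 0) & (candidates < n - 1)]
        if n_loss > len(candidates):
            raise ConfigError("loss_percent too high for the scripted episodes")
        drop = rng.choice(candidates, size=n_loss, replace=False)
        written[drop] = False

    packets = _gaze_packets(script, t, theta, phi, written, rng)
    packets += _aux_packets(script, script.duration_s, rng)
    packets.sort(key=lambda p: (p.ts, p.kind, p.eye))

    project_id = _rand_id(rng)
    participant_id = _rand_id(rng)
    recording_id = _rand_id(rng)
    root = Path(out_dir)
    rec_dir = root / project_id / "recordings" / recording_id
    rec_dir.mkdir(parents=True, exist_ok=True)
    (root / project_id / PROJECT_JSON).write_text(
        json.dumps({"id": project_id, "name": script.project_name}, indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )
    (rec_dir / "recording.json").write_text(
        json.dumps(
            {
                "id": recording_id,
                "name": script.recording_name,
                "participant_id": participant_id,
                "participant_name": script.participant_name,
                "start_time": script.start_time,
                "duration_s": round(script.duration_s, 3),
                "calibration_status": script.calibration_status,
            },
            indent=2,
            sort_keys=True,
        )
        + "\n",
        encoding="utf-8",
    )

    if script.segment_split_s is not None:
        split_us = TS0_US + int(round(script.segment_split_s * 1e6))
        gap_end_us = split_us + int(round(script.segment_gap_s * 1e6))
        seg_packets = [
            [p for p in packets if p.ts < split_us],
            [p for p in packets if p.ts >= gap_end_us],
        ]
    else:
        seg_packets = [packets]

    for k, pkts in enumerate(seg_packets, start=1):
        seg_dir = rec_dir / "segments" / str(k)
        seg_dir.mkdir(parents=True, exist_ok=True)
        write_segment(pkts, seg_dir / SEGMENT_DATA_FILE)
        write_segment_meta(
            seg_dir,
            {
                "segment_index": k,
                "nominal_rate_hz": script.rate_hz,
                "calibration_status": script.calibration_status,
                "firmware": "1.25.3-syn",
            },
        )

    # samples erased by a segment split count as missing too
    if script.segment_split_s is not None:
        in_hole = (t >= script.segment_split_s) & (
            t < script.segment_split_s + script.segment_gap_s
        )
        written &= ~in_hole

    return SynthResult(
        recording_dir=rec_dir,
        project_id=project_id,
        recording_id=recording_id,
        ground_truth=truth,
        t=t,
        true_theta=theta,
        true_phi=phi,
        missing_mask=~written,
        report={
            "n_samples": n,
            "n_missing": int(np.count_nonzero(~written)),
            "injected_loss_percent": 100.0 * np.count_nonzero(~written) / n,
            "segment_count": len(seg_packets),
        },
    )


PROJECT_JSON = "project.json"


def five_fixation_script(
    noise_sd: float = 0.0, rate_hz: int = 50, seed: int = 0, **overrides
) -> ScanpathScript:
    """A five-fixation / four-saccade scanpath with realistic dynamics.

    Saccades are 8-16 degrees with durations on the main-sequence scale
    (about 50-60 ms), giving minimum-jerk peak velocities of 250-500 deg/s.
    """
    episodes = (
        fixation(600, 0.0, 0.0),
        saccade(60, theta=12.0, phi=0.0),
        fixation(500),
        saccade(60, theta=12.0, phi=9.0),
        fixation(700),
        saccade(50, theta=2.0, phi=9.0),
        fixation(500),
        saccade(60, theta=-4.0, phi=-4.0),
        fixation(600),
    )
    return ScanpathScript(
        episodes=episodes, noise_sd=noise_sd, rate_hz=rate_hz, seed=seed, **overrides
    )


def search_task_script(seed: int = 0, **overrides) -> ScanpathScript:
    """A visual-search style recording: scan a board, press a button on hits.

    Emulates a participant searching a notice board for targets, pressing a
    response button (TTL pulse) each time one is found.
    """
    rng = np.random.default_rng(seed)
    episodes: list[Episode] = [fixation(500, 0.0, 0.0)]
    t_cursor = 0.5
    presses: list[float] = []
    for i in range(12):
        th = float(rng.uniform(-20, 20))
        ph = float(rng.uniform(-12, 12))
        sac_ms = 55.0
        fix_ms = float(rng.uniform(400, 900))
        episodes.append(saccade(sac_ms, theta=th, phi=ph))
        episodes.append(fixation(fix_ms))
        t_cursor += (sac_ms + fix_ms) / 1000.0
        if i % 4 == 2:  # every so often: a find, so a button press mid-fixation
            presses.append(round(t_cursor - fix_ms / 2000.0, 3))
    return ScanpathScript(
        episodes=tuple(episodes),
        ttl_times=tuple(presses),
        noise_sd=overrides.pop("noise_sd", 0.05),
        seed=seed,
        **overrides,
    )
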