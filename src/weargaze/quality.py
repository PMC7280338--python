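"""Recording data-quality metrics: RMS-S2S precision and data loss.

Precision is the root-mean-square of the differences between adjacent gaze
samples (RMS-S2S), computed separately for the azimuth and elevation signals
of each eye.  A moving window (default 300 ms, stride one sample) yields one
RMS value per window position; the median over windows estimates precision
during the slow-movement periods that dominate a recording, robust to the
occasional fast-movement window.  Windows containing any missing sample are
excluded entirely so every retained window aggregates the same number of
sample-to-sample differences.

Data loss is the percentage of gaze samples in the regularized recording
that carry no valid gaze data; gap-filled samples count as lost.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, ParseError
from .recording_model import MISSING, GazeData, Recording

DEFAULT_WINDOW_MS = 300.0


@dataclass
class QualityReport:
    """Per-eye, per-axis RMS-S2S (degrees) plus data loss (percent)."""

    window_ms: float
    rms_s2s: dict[str, dict[str, float]]  # {eye: {axis: degrees}}
    data_loss_percent: float
    n_windows_used: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "window_ms": self.window_ms,
            "rms_s2s": self.rms_s2s,
            "data_loss_percent": self.data_loss_percent,
            "n_windows_used": self.n_windows_used,
        }

    def to_json(self, path: os.PathLike | str) -> None:
        def _clean(v):
            if isinstance(v, dict):
                return {k: _clean(x) for k, x in v.items()}
            if isinstance(v, float) and not np.isfinite(v):
                return None
            return v

        with open(path, "wt", encoding="utf-8", newline="\n") as fh:
            json.dump(_clean(self.to_dict()), fh, indent=2, sort_keys=True)
            fh.write("\n")


def rms_s2s(
    axis_series: np.ndarray, rate_hz: float, window_ms: float = DEFAULT_WINDOW_MS
) -> tuple[float, int]:
    """Median moving-window RMS of successive-sample differences.

    Returns ``(median_rms_degrees, n_windows_used)``.  When no window is
    free of missing samples the median is NaN (with a warning), not an
    error.
    """
    x = np.asarray(axis_series, dtype=float)
    if window_ms <= 0:
        raise ConfigError(f"window_ms must be positive, got {window_ms}")
    w = int(round(window_ms / 1000.0 * rate_hz))
    if w < 2:
        raise ConfigError(
            f"window of {window_ms} ms spans {w} sample(s) at {rate_hz} Hz; need >= 2"
        )
    if len(x) < w:
        warnings.warn("series shorter than one RMS-S2S window; no estimate")
        return float("nan"), 0
    finite = np.isfinite(x)
    window_ok = sliding_window_view(finite, w).all(axis=1)
    n_used = int(np.count_nonzero(window_ok))
    if n_used == 0:
        warnings.warn("no RMS-S2S window free of missing samples; no estimate")
        return float("nan"), 0
    d = np.diff(x)
    d2 = np.where(np.isfinite(d), d * d, 0.0)  # masked rows are discarded below
    win_means = sliding_window_view(d2, w - 1).mean(axis=1)
    rms = np.sqrt(win_means[window_ok])
    return float(np.median(rms)), n_used


def data_loss(gaze: GazeData) -> float:
    """Invalid gaze samples as a percentage of all regularized samples."""
    n = len(gaze)
    if n == 0:
        raise ParseError("cannot compute data loss of an empty gaze series")
    return 100.0 * float(np.count_nonzero(gaze.binocularity == MISSING)) / n


def quality_report(recording: Recording, window_ms: float = DEFAULT_WINDOW_MS) -> QualityReport:
    """Assemble the four RMS-S2S cells and the data-loss figure."""
    gaze = recording.gaze
    rate = recording.rate_hz
    cells: dict[str, dict[str, float]] = {}
    counts: dict[str, dict[str, int]] = {}
    for eye in ("left", "right"):
        cells[eye] = {}
        counts[eye] = {}
        for axis, attr in (("azimuth", f"{eye}_azimuth"), ("elevation", f"{eye}_elevation")):
            value, n_used = rms_s2s(getattr(gaze, attr), rate, window_ms)
            cells[eye][axis] = value
            counts[eye][axis] = n_used
    return QualityReport(
        window_ms=window_ms,
        rms_s2s=cells,
        data_loss_percent=data_loss(gaze),
        n_windows_used=counts,
    )
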