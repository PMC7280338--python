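"""Eye orientation and velocity.

Gaze direction unit vectors are decomposed into Fick angles — azimuth
:math:`\\theta` (rotation about the vertical axis, applied first) then
elevation :math:`\\varphi` — in a headset-fixed frame with x to the wearer's
right, y up, z straight ahead:

.. math::

    \\theta = \\operatorname{atan2}(x, z), \\qquad \\varphi = \\arcsin(y)

Smoothed angular rates :math:`\\dot\\theta, \\dot\\varphi` come from a
Savitzky–Golay differentiation filter (local least-squares polynomial fit,
derivative evaluated at the window center), and the total eye speed is

.. math::

    \\dot\\omega = \\sqrt{\\dot\\theta^2 \\cos^2\\varphi + \\dot\\varphi^2}

which accounts for the shrinking of azimuth circles away from the equator
of the ocular sphere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import savgol_coeffs

from .errors import ConfigError
from .recording_model import Recording

UNIT_NORM_TOL = 1e-6


@dataclass(frozen=True)
class SgSettings:
    """Savitzky–Golay differentiation filter settings.

    window_samples must be odd and >= 3; poly_order >= 1 and strictly less
    than window_samples.
    """

    window_samples: int = 5
    poly_order: int = 2

    def __post_init__(self) -> None:
        w, p = self.window_samples, self.poly_order
        if not (isinstance(w, int) and w >= 3 and w % 2 == 1):
            raise ConfigError(f"window_samples must be an odd integer >= 3, got {w}")
        if not (isinstance(p, int) and 1 <= p < w):
            raise ConfigError(f"poly_order must satisfy 1 <= order < window, got {p}")


def default_sg_settings(rate_hz: int) -> SgSettings:
    """Default filter: a ~100-ms window (odd sample count), quadratic fit."""
    window = 2 * round(0.05 * rate_hz) + 1
    return SgSettings(window_samples=max(window, 3), poly_order=2)


@dataclass
class OrientationTrace:
    """Per-eye Fick angles (degrees) on the gaze grid; NaN where missing."""

    t: np.ndarray
    left_azimuth: np.ndarray
    left_elevation: np.ndarray
    right_azimuth: np.ndarray
    right_elevation: np.ndarray


@dataclass
class VelocityTrace:
    """Per-eye angular rates (deg/s) on the gaze grid.

    NaN wherever the filter window touches a missing sample or the series
    edge.
    """

    t: np.ndarray
    left_azimuth_rate: np.ndarray
    left_elevation_rate: np.ndarray
    right_azimuth_rate: np.ndarray
    right_elevation_rate: np.ndarray
    left_speed: np.ndarray  # omega-dot, total eye speed
    right_speed: np.ndarray
    settings: SgSettings | None = None


@dataclass
class KinematicsResult:
    orientation: OrientationTrace
    velocity: VelocityTrace


def fick_decompose(gaze_dir: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Decompose gaze direction vector(s) into (azimuth, elevation) degrees.

    Accepts shape (3,) or (..., 3).  Vectors must be unit length within
    1e-6 (they are renormalized); near-zero or badly scaled vectors raise
    :class:`ConfigError`.  NaN vectors yield NaN angles.
    """
    v = np.asarray(gaze_dir, dtype=float)
    if v.shape[-1] != 3:
        raise ConfigError(f"gaze_dir must have last dimension 3, got shape {v.shape}")
    norm = np.linalg.norm(v, axis=-1)
    finite = np.isfinite(norm)
    bad = finite & (np.abs(norm - 1.0) > UNIT_NORM_TOL)
    if np.any(bad):
        raise ConfigError(
            f"{int(np.count_nonzero(bad))} gaze vector(s) are not unit length within "
            f"{UNIT_NORM_TOL:g} (worst |norm-1| = {np.max(np.abs(norm[bad] - 1.0)):.3g})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        u = v / norm[..., None]
        theta = np.degrees(np.arctan2(u[..., 0], u[..., 2]))
        phi = np.degrees(np.arcsin(np.clip(u[..., 1], -1.0, 1.0)))
    return theta, phi


def fick_compose(azimuth_deg, elevation_deg) -> np.ndarray:
    """Compose Fick angles (degrees) back into unit gaze vector(s)."""
    theta = np.radians(np.asarray(azimuth_deg, dtype=float))
    phi = np.radians(np.asarray(elevation_deg, dtype=float))
    if np.any(np.isfinite(phi) & (np.abs(phi) >= np.pi / 2)):
        raise ConfigError("elevation must satisfy |phi| < 90 degrees")
    return np.stack(
        [np.cos(phi) * np.sin(theta), np.sin(phi), np.cos(phi) * np.cos(theta)],
        axis=-1,
    )


def sg_differentiate(series: np.ndarray, dt: float, settings: SgSettings) -> np.ndarray:
    """Savitzky–Golay first derivative of a uniformly sampled series.

    Fits a polynomial of ``settings.poly_order`` over each centered window of
    ``settings.window_samples`` and evaluates its derivative at the center,
    scaled to per-second units.  The output is NaN wherever the window
    contains a missing (NaN) sample or is truncated by the series edge.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ConfigError("series must be one-dimensional")
    w = settings.window_samples
    if dt <= 0:
        raise ConfigError(f"dt must be positive, got {dt}")
    out = np.full_like(x, np.nan)
    if len(x) < w:
        return out
    coeffs = savgol_coeffs(w, settings.poly_order, deriv=1, delta=dt, use="dot")
    half = w // 2
    windows = sliding_window_view(x, w)
    # NaN anywhere in a window propagates to that window's output
    out[half : len(x) - half] = windows @ coeffs
    return out


def eye_velocity(azimuth_rate, elevation_rate, elevation_deg) -> np.ndarray:
    """Total eye speed sqrt(theta_dot^2 cos^2(phi) + phi_dot^2), deg/s."""
    th_dot = np.asarray(azimuth_rate, dtype=float)
    ph_dot = np.asarray(elevation_rate, dtype=float)
    phi = np.radians(np.asarray(elevation_deg, dtype=float))
    return np.sqrt((th_dot * np.cos(phi)) ** 2 + ph_dot**2)


def compute_kinematics(
    recording: Recording, settings: SgSettings | None = None
) -> KinematicsResult:
    """Orientation and velocity traces for both eyes of a recording.

    Attaches the result to ``recording.derived`` and returns it.
    """
    if settings is None:
        settings = default_sg_settings(recording.rate_hz)
    gaze = recording.gaze
    dt = recording.dt
    orientation = OrientationTrace(
        t=gaze.t,
        left_azimuth=gaze.left_azimuth,
        left_elevation=gaze.left_elevation,
        right_azimuth=gaze.right_azimuth,
        right_elevation=gaze.right_elevation,
    )
    rates = {}
    for eye in ("left", "right"):
        az = getattr(gaze, f"{eye}_azimuth")
        el = getattr(gaze, f"{eye}_elevation")
        az_rate = sg_differentiate(az, dt, settings)
        el_rate = sg_differentiate(el, dt, settings)
        rates[eye] = (az_rate, el_rate, eye_velocity(az_rate, el_rate, el))
    velocity = VelocityTrace(
        t=gaze.t,
        left_azimuth_rate=rates["left"][0],
        left_elevation_rate=rates["left"][1],
        right_azimuth_rate=rates["right"][0],
        right_elevation_rate=rates["right"][1],
        left_speed=rates["left"][2],
        right_speed=rates["right"][2],
        settings=settings,
    )
    result = KinematicsResult(orientation=orientation, velocity=velocity)
    recording.derived = result
    return result
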