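# Methods

This note documents the models, conventions and numerical choices behind
weargaze, what its synthetic-data generator does and does not emulate, and
the package's known limitations.

## Coordinate conventions and the Fick decomposition

Gaze direction is a unit vector per eye in a headset-fixed frame: x to the
wearer's right, y up, z straight ahead. We decompose it into Fick angles —
a rotation about the vertical axis (azimuth θ) applied first, followed by a
rotation about the interaural axis (elevation φ):

- θ = atan2(x, z), degrees, positive rightward, range (−180°, 180°];
- φ = asin(y), degrees, positive upward, range [−90°, 90°].

Using asin for φ makes the decomposition unique; the poles (|φ| = 90°) are
excluded from composition since azimuth is undefined there. Input vectors
must be unit length within 1e-6 (they are renormalized inside that
tolerance, rejected beyond it); NaN vectors — missing samples — yield NaN
angles rather than errors.

## Eye velocity

Smoothed angular rates θ̇ and φ̇ are obtained with a Savitzky–Golay
differentiation filter: over each centered window of `window_samples`
samples a polynomial of `poly_order` is fit by least squares and its
derivative is evaluated at the window center, scaled by the sampling
interval to deg/s. Total eye speed combines the two rates as

    ω̇ = sqrt(θ̇² cos²φ + φ̇²)

The cos φ factor converts azimuth rate into arc speed on the ocular sphere:
a 100 °/s azimuth sweep at 60° elevation moves the line of sight at only
50 °/s.

Defaults: `window_samples` = 2·round(0.05·rate)+1 (≈ 100 ms, always odd;
5 samples at 50 Hz, 11 at 100 Hz) and `poly_order` = 2, a common choice
for saccade-scale smoothing. Both are settings in the JSON config.

Two deliberate properties of the filter:

- **Edge and gap handling.** The derivative is reported only where the full
  window is available and free of missing samples; truncated or
  contaminated windows yield NaN rather than a shrunken-window estimate, so
  the filter bandwidth is constant across the recording. One isolated
  missing sample therefore blanks exactly `window_samples` velocity
  samples.
- **Known attenuation.** A polynomial fit attenuates sinusoidal components.
  For the order-2 filter the leading-order attenuation of a sinusoid's
  derivative is (ωΔt)²·Σk⁴/(6·Σk²) over window offsets k: for an 11-sample
  window at 100 Hz and a 1-Hz signal this is 1.17 % of peak, a property the
  test suite verifies against the analytic expression. Raising the order to
  3 cancels this term (measured error below 0.05 % of peak). Users needing
  minimal peak attenuation at the cost of noise suppression should lower
  the window or raise the order.

## Gaze-sample assembly and regularization

The packet dialect reports each gaze sample as a family of packets sharing
a group index (per-eye direction, pupil center, pupil diameter; binocular
2-D and 3-D gaze points). An eye is valid in a sample only when all three
of its per-eye packets are present with status 0; binocularity is
`binocular` when both eyes are valid, `monocular_left`/`monocular_right`
when one is, `missing` when none is. The sample's timestamp is its earliest
gaze-direction packet's timestamp.

The nominal rate (50 or 100 Hz) is inferred as the supported rate nearest
1/median(Δt) — the median is robust to jitter and isolated gaps — with a
warning when the empirical rate deviates more than 10 %.

Regularization snaps each sample to its nearest tick of the exact grid
t₀ + k/rate; ties exactly halfway snap to the earlier tick, two samples
landing on one tick keep the earlier one, and every unoccupied tick between
the first and last sample becomes a `missing` sample. Grid timestamps are
computed directly as t₀ + k/rate (never cumulatively), so consecutive
intervals deviate from 1/rate only by float representation error (< 1e-9 s;
in practice ~1e-15 s). Gaze positions are never interpolated: a gap stays a
gap. The procedure is idempotent.

Multi-segment recordings (hardware splits recordings of roughly an hour or
longer) share one clock; segments are ordered by time, concatenated, and
the inter-segment span is gap-filled like any other gap. Overlapping
segments are an error rather than silently re-offset, since re-offsetting
would hide hardware clock faults. IMU streams keep their native timestamps;
only gaze is regularized. All stream times are seconds with t = 0 at the
first gaze sample of the recording.

Parsed recordings are cached in one HDF5 container (`livedata.processed`)
per recording directory; reload is exact.

## Data-quality panel

- **RMS-S2S** (precision): the RMS of successive-sample differences of one
  axis signal (azimuth or elevation, per eye, in degrees), computed in a
  moving window of 300 ms (default) with stride one sample, summarized by
  the median over window positions. The median estimates precision during
  the slow-movement periods that dominate recordings while remaining robust
  to the minority of windows containing saccades or artifacts (a single
  1000 °/s spike moves the median by well under 1 %). Windows containing
  any missing sample are excluded entirely, so every retained window
  aggregates the same number of differences. For iid Gaussian noise of
  standard deviation σ per sample the statistic concentrates near σ√2.
- **Data loss**: missing samples as a percentage of all regularized
  samples; gap-filled samples count as lost.

When no window is free of missing data the RMS cell is NaN with a warning,
not an error.

## Event streams

An event stream is a named, time-ordered sequence of non-overlapping
half-open intervals [start, end), each labeled from the stream's configured
categories and optionally carrying flags from the label's flag vocabulary
(e.g. a saccade flagged `vergence`). Editing operations are pure functions
that return a new stream and re-validate the invariants:

- *add*: a new annotation spans from the end of the latest annotation
  ending at or before the clicked time (or from 0) up to the clicked time;
  clicking inside an existing annotation is an overlap error.
- *split*: strictly inside an annotation only; label and flags are copied.
- *move boundary*: a shared edge moves for both neighbors; an outer edge
  grows/shrinks against uncoded time; crossing a neighboring edge is a
  range error.

Manual streams may leave uncoded spans; classifier output must cover the
whole timeline. TTL-derived streams are locked against accidental edits
(instantaneous level changes are widened to one gaze interval under the
`edges` scheme so end > start always holds); text-file streams are editable
but carry a snapshot so they can be reset to the file's contents.
Everything persists to an open JSON file (`coding.json`) next to the
recording, which external tools (e.g. manual-mapping coders) may extend
with their own streams.

## The slow/fast classifier

`classify_slow_fast` is a documented velocity-threshold classifier with run
merging, shipped as the built-in behind the plugin registry (faithful ports
of published head-worn-tracker classifiers can be registered alongside it
under the same contract):

1. Per sample, the binocular speed is the mean of the finite per-eye ω̇
   values (the single finite eye when only one is available).
2. Samples without valid gaze data are `missing`; samples with speed above
   `velocity_threshold_dps` (default 100 °/s) are `fast`; all others —
   including valid-gaze samples whose filter window is contaminated, which
   have no speed estimate and hence are not above threshold — are `slow`.
3. Runs shorter than their minimum duration (`min_fast_ms` = 10,
   `min_slow_ms` = 40) are merged shortest-first, each into its longer
   non-missing neighbor (ties to the earlier neighbor); runs bordered only
   by missing spans or the recording edges are kept; `missing` spans are
   never merged. Sample k owns the interval [t₀+k·Δt, t₀+(k+1)·Δt), so the
   output tiles the full timeline.

The defaults sit in `defaults.json` with allowed ranges; parameters marked
user-settable can be overridden per run (`--set name=value`). The
classifier is deterministic: identical recording and parameters give an
identical stream.

## The synthetic-data generator

The generator scripts a scanpath from episodes — fixations at (θ, φ)
targets, saccades, constant-velocity pursuit, and gaps — and writes a
complete project tree in the packet dialect, including per-segment metadata,
IMU packets (100 Hz; white gyro noise, gravity-plus-noise accelerometer),
TTL button presses (100-ms high pulses), and video-timestamp packets.

Choices and what they mean for the tests:

- **Saccade profile**: minimum-jerk displacement, chosen because its peak
  velocity has the closed form 1.875·amplitude/duration, making an exact
  oracle for the kinematics chain. It is a modeling convenience, not a
  claim about real saccade dynamics. The built-in scripts use 8–16°
  saccades of 50–60 ms — main-sequence-scale durations with peak
  velocities of 250–500 °/s.
- **Noise**: iid Gaussian on θ and φ, independent per eye and axis, default
  0.05° — the order of precision typical of wearable trackers. Real
  tracker noise is colored and heteroscedastic (worse at gaze extremes);
  passing RMS-S2S tests on white noise validates the estimator's
  statistics, not the device model.
- **Loss**: gap episodes delete whole spans of packets; `loss_percent`
  additionally deletes an exact count of randomly chosen interior samples,
  so recovered data loss can be asserted tightly. Monocular spans drop one
  eye's packets to exercise the monocular validity path.
- **Determinism**: one seed drives every random draw, JSON is serialized
  canonically, and gzip members are written with a zeroed mtime, so a
  script plus seed reproduces a byte-identical tree.

The generator does not synthesize video files (video-timestamp packets are
emitted without MP4s), realistic pupil dynamics (diameter is constant plus
noise), head motion coupled to gaze, or vendor-specific auxiliary packets.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
recordings of seconds to two minutes at 50–100 Hz (up to ~6000 gaze
samples), 500–1000-packet round-trip checks, and 10⁴ random edit
operations. These sizes already exercise every code path (multi-segment
assembly, gap filling, windowed statistics, merging) while keeping a full
run under a minute; all statistics asserted at these sizes concentrate well
within the stated tolerances.

## Known limitations

- The packet dialect is this package's own documented format in the style
  of packet-based wearable trackers; real vendor files need a (thin)
  dialect adapter at the `packet_io` layer.
- No accuracy (systematic offset) estimation — quality reporting covers
  precision and loss only.
- No gyro fusion or gaze-in-world reconstruction; velocities are eye-in-
  head, per eye, with binocular averaging left to callers.
- No clock-drift estimation between IMU and gaze streams (a shared clock is
  assumed, as the dialect guarantees).
- Scene/eye video decoding and any GUI (timeline rendering, playback) are
  out of scope; the video-time maps only translate timestamps.
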