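# Methods

This note documents the models and procedures implemented in `breathcam`,
the defaults and why they were chosen, what the synthetic scenes do and do
not emulate, and the numerical choices that matter.

## Sensor model and calibration

The thermal stream emulates a low-cost microbolometer camera: 8-bit grey
frames in which each frame's grey scale is re-spanned to that frame's own
temperature range, printed on an embedded calibration bar. Calibration is
therefore *adaptive*: the bar is re-read every frame. The bar reader is a
two-layer perceptron — sigmoid hidden layer (32 units), softmax output —
over 12 character classes (digits, decimal point, minus sign; the minus
sign and decimals are needed because the camera range spans −40…330 °C and
the bar prints one decimal place). Glyph cells are normalised before
classification: Otsu binarisation, then the ink bounding box is centred on
a fixed 12×8 canvas (down-scaled, aspect preserved, only if it overflows).
Centring rather than stretching keeps the small classes ('.', '−')
geometrically distinct. Training is full-batch gradient descent on the
mean cross-entropy (600 epochs, learning rate 2.0, seeded Gaussian
initialisation scaled by 1/√fan-in); the jittered training distribution
(±2 px shift, 0.85–1.15 scale, σ=25 grey-level noise) comes from the same
renderer, which is why held-out accuracy sits at ~100%: the deployment
distribution equals the training distribution. For a real camera overlay
the same machinery applies after retraining on that overlay's font and a
user-supplied cell layout.

Grey maps to temperature as `T(g) = tmin + g·(tmax−tmin)/255`; grey 0 is
tmin, grey 255 is tmax. The per-pixel error of the whole
render→read→map chain is bounded by one quantisation step
`(tmax−tmin)/255` (≈0.04 °C for a typical 10 °C span), which the tests
assert.

Bar reading errors are explicit failures carrying the frame index: blank
padding cells (no ink) are skipped, a low-confidence glyph (softmax below
0.5) or an unparseable field (e.g. `tmin ≥ tmax`) raises a calibration
error rather than producing a silent misread.

## Mouth-region detection and tracking

Breathing is localised as the region of largest temperature *change*:
per-pixel peak-to-peak (max − min) over a trailing history window,
optionally box-smoothed. Peak-to-peak was chosen over the standard
deviation because it is parameter-free and directly reads "largest
changes"; over a window covering at least one breath cycle it equals twice
the local breathing amplitude. The map is thresholded at its
`change_quantile` quantile; 8-connected components with area in
`[min_area, max_area]` qualify. The initial detection takes the largest
qualifying component's bounding box; each subsequent frame re-detects and
keeps the component whose centroid is nearest the previous region (ties:
larger area, then lower corner). When nothing qualifies the previous
region is kept and flagged, so the extracted series is gap-free and the
fallback rate is reported.

Defaults: `history_sec = 4` (midpoint of the plausible 1–8 s range, one
full cycle at typical resting rates), `init_frames = history·fs`,
`change_quantile = 0.95`, `min_area = 9 px`, `max_area` a quarter frame,
`smoothing_radius = 1 px`. Two situation-dependent adjustments are worth
knowing:

* **Moving head.** For drifting targets a short history (2 s) and no
  smoothing track best: the change map of a moving patch smears along the
  motion path in proportion to speed × window length, and smoothing
  dilates the detected box further. With the default 4 s history a patch
  moving at ~1 px/frame yields a bounding box much longer than the true
  region.
* **Very clean data.** The threshold should sit above the background
  change floor. With noise-free (or heavily averaged) input the only
  background "change" is grey-quantisation flicker; a 0.95 quantile then
  admits the top 5% of background pixels even though the breathing patch
  may occupy only ~2–3% of the frame, and flicker pixels touching the
  patch inflate its box. A tighter quantile (0.99) isolates the patch. In
  general `change_quantile` should be roughly `1 −` (expected breathing
  patch fraction) `−` (noise budget).

Region statistics: `mean_temperature` (the breathing series),
`range_fraction` (percentage of pixels inside a temperature band, e.g.
26–28 °C, used to verify camera precision on stable scenes — the tests
require a coefficient of variation below 7% across 24 frames sampled every
5 s), and `flat_field_stats` (per-pixel noise summary of a
uniform-temperature surface).

## Depth stream

The depth sensor produces matrices of distances in metres (valid range
0.4–4 m). The chest region is a *fixed*, user-selected rectangle — chest
position is stable in the intended seated/lying recordings, so no
adaptive tracking is applied — and the breathing series is the mean of
valid region pixels per frame. Non-finite pixels and values outside the
sensor range (real time-of-flight dropouts) are excluded and counted.

## Spectral rate estimation

The series is mean-removed, filtered with a causal linear-phase FIR
band-pass (windowed-sinc, Hamming window) over 0.05–1.5 Hz, and the rate
is the in-band argmax of the DFT magnitude, quantised to the bin grid
`f_k = (k/N)·fs` — no peak interpolation, so the resolution is exactly
`fs/N` (0.0033 Hz = 0.2 bpm for 300 s at 10 Hz). Design choices:

* 512 taps at `fs = 10 Hz`. The low band edge (0.05 Hz) sits 0.5% of the
  Nyquist range from DC; a Hamming transition width of ≈3.3·fs/M requires
  M in the hundreds. Every design is verified by evaluating its response
  (≥ −6 dB across [2·f_low, 0.8·f_high], ≤ −20 dB at DC and Nyquist);
  infeasible tap counts raise a design error instead of returning a
  filter that silently passes drift.
* Filtering is skipped (mean removal only) for records shorter than two
  filter lengths: the transient would span the record, and the in-band
  argmax is unaffected by the filter's phase anyway.
* No group-delay compensation is applied before the DFT; a linear-phase
  filter delays all in-band components equally and the magnitude argmax
  is delay-invariant.

## Windowed features, recovery regression, response delays

Non-overlapping 60 s windows (chronological, centre-timestamped) each
contribute the raw-series mean and the in-band rate of the window's
filtered, re-centred samples. The whole series is filtered *once* before
windowing: a fresh 512-tap transient inside every 600-sample window would
dominate the window. At 60 s the window rate resolution is 1 bpm.

Recovery after exercise is summarised by ordinary least squares of a
windowed feature against time in minutes (slope in °C/min or bpm/min).
The error statistic `S` is the mean squared residual divided by the
squared mean of the fitted values, as a percentage — zero for a noiseless
line. This normalisation is a package definition chosen so that `S` is
scale-free and comparable between temperature and frequency fits.

Response delay after an activity change is the time until the feature
first crosses `baseline + c·(steady − baseline)` with crossing fraction
`c = 0.5`: baseline is the mean of the last two windows before the
boundary, steady the mean of the last two windows of the segment, and
the crossing time is linearly interpolated between window centres. A
feature that never crosses (or does not move) is censored at the segment
length. The half-way crossing of an exponential approach with time
constant τ occurs at ln 2·τ ≈ 0.693τ, which the tests use as the
closed-form check; the crossing-fraction rule itself is this package's
operationalisation of "delay".

## Synthetic scenes: what they emulate, and what they do not

`synthgen` renders, per frame: a smooth warm face (Gaussian bump, 8 °C
over a 22 °C background) on the scene below the bar; a rectangular mouth
patch at `base_temp + drift + amplitude·sin(2πft)`; i.i.d. Gaussian pixel
noise; 8-bit quantisation against the frame's own span rounded outward to
0.1 °C; and the calibration bar printing that span. The depth stream is a
background plane plus a chest patch at
`chest_mean ± chest_amplitude·sin(2πft)` with Gaussian noise, clipped to
the sensor range. Defaults (the simulated study conditions): `fs = 10 Hz`,
300 s records, breathing 0.25 Hz (15 bpm), mouth 10×14 px at 30 °C with
1.5 °C breathing amplitude, 0.1 °C/min drift, 0.3 °C thermal pixel noise;
chest at 1.5 m with 5 mm amplitude and 2 mm depth noise. Head movement is
a sinusoidal drift path with peak speed ≤ 1 px/frame (a linear 1 px/frame
walk would leave the frame within seconds). Noise is i.i.d. Gaussian,
consistent with the unimodal flat-field pixel distribution of
microbolometer cameras.

Not emulated: radiometric physics, lens vignetting and fixed-pattern
noise, facial geometry/expression changes, occlusions, vendor overlay
fonts, Kinect RGB/IR streams, and non-stationary breathing waveforms
(the simulated breath is sinusoidal). Passing tests therefore demonstrate
the correctness of the *algorithms* under controlled conditions with
known truth — not field performance on arbitrary subjects; on real video
the OCR needs retraining on the camera's font and the tracker's quantile
needs matching to the scene as described above.

## Problem sizes used in the validation suite

Tests and the acceptance script use a 64×112 frame (14-row bar + 50×112
scene) so that full 300 s/3000-frame records run in seconds; tracking
uses one-pass rolling extrema over the stack, and repeated bar spans are
memoised during calibration. Rate-recovery checks run 20 seeded paired
runs with the true rate drawn uniformly from 9–30 bpm; recovery-slope
checks run 200 seeded replicates. All randomness flows from explicit
seeds; reruns are byte-identical.

## Known limitations

* The tracker returns axis-aligned bounding boxes; an oblique or
  non-rectangular breathing region is covered loosely.
* Rate estimation assumes one dominant breathing line in 0.05–1.5 Hz;
  apnea episodes, talking, or strong harmonics can misplace the argmax
  within the band.
* The delay and `S` definitions are package operationalisations (stated
  above), not field standards; compare across runs of this package only.
* OCR generalises only to fonts it was trained on.
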