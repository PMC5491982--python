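"""Breathing-signal processing: FIR band-pass, DFT rate estimation,
windowed trends, recovery regression and activity-response delays.

The breathing series x(n), n = 0..N-1 (mean mouth temperature in degC or
mean chest distance in m, uniformly sampled at fs) is de-noised with a
causal FIR filter

    y(n) = sum_{k=0}^{M-1} b(k) x(n-k)

whose pass band covers the physiological breathing range 0.05-1.5 Hz, and
the rate is taken as the largest in-band magnitude of the DFT

    Y(k) = sum_{n=0}^{N-1} y(n) exp(-j k n 2 pi / N),  f_k = (k/N) fs.

With 300 s records at fs = 10 Hz (N = 3000) the bin spacing fs/N is
0.0033 Hz, i.e. 0.2 breaths per minute, which sets the rate resolution.
Longer-time behaviour — warm-up/recovery trends around exercise — is
summarised per non-overlapping window (60 s by default): window mean and
in-band spectral rate, then ordinary least squares for recovery slopes and
a threshold-crossing rule for response delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "ActivitySchedule",
    "BreathSignal",
    "DesignError",
    "FilterSpec",
    "RegressionResult",
    "Segment",
    "SegmentDelay",
    "Spectrum",
    "WindowedFeatures",
    "breathing_frequency",
    "design_bandpass",
    "dft",
    "estimate_breathing_rate",
    "fir_filter",
    "recovery_regression",
    "response_delay",
    "windowed_features",
]

#: Physiological breathing band (Hz) used throughout as the default.
DEFAULT_BAND = (0.05, 1.5)
DEFAULT_TAPS = 512


class DesignError(ValueError):
    """Filter design failed its frequency-response verification."""


@dataclass(frozen=True)
class BreathSignal:
    """Uniformly sampled scalar breathing series."""

    x: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 1 or x.size < 2:
            raise ValueError("signal must be 1-D with at least two samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("signal contains non-finite samples")
        if not self.fs > 0:
            raise ValueError("fs must be positive")

    @property
    def n(self) -> int:
        return int(self.x.size)

    @property
    def duration(self) -> float:
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n) / self.fs

    @property
    def resolution_hz(self) -> float:
        """DFT bin spacing fs/N — the smallest resolvable rate difference."""
        return self.fs / self.n

    @property
    def resolution_bpm(self) -> float:
        return 60.0 * self.resolution_hz


@dataclass(frozen=True)
class FilterSpec:
    """FIR filter coefficients b(k), k = 0..M-1, with its design band."""

    b: np.ndarray
    f_low: float
    f_high: float
    fs: float

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        object.__setattr__(self, "b", b)
        if b.ndim != 1 or b.size < 1 or not np.all(np.isfinite(b)):
            raise ValueError("coefficients must be a finite 1-D array")
        if not 0 < self.f_low < self.f_high < self.fs / 2:
            raise ValueError("need 0 < f_low < f_high < fs/2")

    @property
    def m(self) -> int:
        return int(self.b.size)

    def response_db(self, freqs) -> np.ndarray:
        """Magnitude response in dB at the given frequencies (Hz)."""
        _, h = sps.freqz(self.b, worN=np.atleast_1d(np.asarray(freqs, float)), fs=self.fs)
        return 20.0 * np.log10(np.abs(h) + 1e-300)


@dataclass(frozen=True)
class Spectrum:
    """DFT of a breathing signal with its bin-to-frequency mapping."""

    y: np.ndarray  # complex DFT values Y(k), k = 0..N-1
    fs: float

    @property
    def n(self) -> int:
        return int(self.y.size)

    @property
    def freqs(self) -> np.ndarray:
        return np.arange(self.n) * self.fs / self.n

    @property
    def magnitudes(self) -> np.ndarray:
        return np.abs(self.y)


def design_bandpass(
    f_low: float = DEFAULT_BAND[0],
    f_high: float = DEFAULT_BAND[1],
    taps: int = DEFAULT_TAPS,
    fs: float = 10.0,
) -> FilterSpec:
    """Linear-phase windowed-sinc (Hamming) band-pass FIR design.

    The design is verified by evaluating its response: at least -6 dB across
    [2*f_low, 0.8*f_high] and at most -20 dB at DC and Nyquist; a tap count
    too small for the band (the low edge sits close to DC, so hundreds of
    taps are needed at fs = 10 Hz) raises :class:`DesignError`.
    """
    if not 0 < f_low < f_high < fs / 2:
        raise ValueError("need 0 < f_low < f_high < fs/2")
    if taps < 1:
        raise ValueError("taps must be >= 1")
    try:
        b = sps.firwin(taps, [f_low, f_high], window="hamming", pass_zero=False, fs=fs)
    except ValueError as exc:
        raise DesignError(f"infeasible design: {exc}") from exc
    spec = FilterSpec(b=b, f_low=f_low, f_high=f_high, fs=fs)
    grid = np.linspace(2 * f_low, 0.8 * f_high, 64)
    if spec.response_db(grid).min() < -6.0:
        raise DesignError(f"pass band sags below -6 dB with {taps} taps")
    stop = spec.response_db([0.0, fs / 2.0])
    if stop.max() > -20.0:
        raise DesignError(f"stop-band rejection worse than -20 dB with {taps} taps")
    return spec


def fir_filter(signal: BreathSignal, spec: FilterSpec) -> BreathSignal:
    """Causal FIR filtering with zero initial conditions.

    y(n) = sum_k b(k) x(n-k) with x(n-k) = 0 for n-k < 0; output length
    equals input length.
    """
    y = sps.lfilter(spec.b, [1.0], signal.x)
    return BreathSignal(x=y, fs=signal.fs)


def dft(signal: BreathSignal) -> Spectrum:
    """Discrete Fourier transform Y(k) = sum_n y(n) exp(-j k n 2 pi / N)."""
    return Spectrum(y=np.fft.fft(signal.x), fs=signal.fs)


def breathing_frequency(
    spectrum: Spectrum,
    f_low: float = DEFAULT_BAND[0],
    f_high: float = DEFAULT_BAND[1],
) -> tuple[float, float, int]:
    """Dominant in-band spectral component: (f_hz, f_bpm, bin index).

    Picks argmax |Y(k)| over bins with f_low <= f_k <= min(f_high, fs/2);
    ties resolve to the lowest bin.  No interpolation: the estimate is
    quantised to the record's bin spacing fs/N.
    """
    freqs = spectrum.freqs
    band = (freqs >= f_low) & (freqs <= min(f_high, spectrum.fs / 2.0))
    if not band.any():
        raise ValueError(
            f"band [{f_low}, {f_high}] Hz contains no DFT bin "
            f"(N={spectrum.n}, fs={spectrum.fs})"
        )
    idx = np.flatnonzero(band)
    k = int(idx[np.argmax(spectrum.magnitudes[idx])])
    f_hz = float(freqs[k])
    return f_hz, 60.0 * f_hz, k


def estimate_breathing_rate(
    series: BreathSignal,
    f_low: float = DEFAULT_BAND[0],
    f_high: float = DEFAULT_BAND[1],
    taps: int = DEFAULT_TAPS,
) -> tuple[float, float, int]:
    """Whole-record rate estimate: filter, DFT, in-band argmax.

    The series is mean-removed and band-pass filtered before the DFT;
    records too short to carry the filter (N < 2*taps) are only
    mean-removed, since the argmax is unaffected by a filter whose
    transient would span the whole record.
    """
    centred = BreathSignal(series.x - series.x.mean(), series.fs)
    if series.n >= 2 * taps and f_high < series.fs / 2:
        spec = design_bandpass(f_low, f_high, taps, series.fs)
        centred = fir_filter(centred, spec)
    return breathing_frequency(dft(centred), f_low, f_high)


@dataclass(frozen=True)
class WindowedFeatures:
    """Non-overlapping-window summaries of a breathing series."""

    window_len_s: float
    times_s: np.ndarray  # window-centre times
    means: np.ndarray  # raw-series window means
    freqs_bpm: np.ndarray  # in-band spectral rate per window

    @property
    def n_windows(self) -> int:
        return int(self.times_s.size)

    def values(self, feature: str) -> np.ndarray:
        if feature == "mean":
            return self.means
        if feature == "frequency":
            return self.freqs_bpm
        raise ValueError(f"unknown feature {feature!r} (use 'mean' or 'frequency')")


def windowed_features(
    series: BreathSignal,
    window_len_s: float = 60.0,
    f_low: float = DEFAULT_BAND[0],
    f_high: float = DEFAULT_BAND[1],
    filter_spec: FilterSpec | None = None,
) -> WindowedFeatures:
    """Window means and breathing rates over non-overlapping windows.

    The whole mean-removed series is band-pass filtered once (avoiding a
    fresh filter transient in every window); each full window then
    contributes its raw mean and the argmax in-band DFT rate of its
    filtered, re-centred samples.  When the record is too short to carry
    the default 512-tap filter, mean removal alone is used.
    """
    w = int(round(window_len_s * series.fs))
    if w < 4:
        raise ValueError("window must span at least 4 samples")
    n_win = series.n // w
    if n_win < 1:
        raise ValueError(f"series shorter than one {window_len_s} s window")
    centred = BreathSignal(series.x - series.x.mean(), series.fs)
    if (
        filter_spec is None
        and series.n >= 2 * DEFAULT_TAPS
        and f_high < series.fs / 2
    ):
        filter_spec = design_bandpass(f_low, f_high, DEFAULT_TAPS, series.fs)
    filtered = fir_filter(centred, filter_spec).x if filter_spec else centred.x

    times = (np.arange(n_win) + 0.5) * w / series.fs
    means = np.empty(n_win)
    freqs = np.empty(n_win)
    for i in range(n_win):
        seg_raw = series.x[i * w : (i + 1) * w]
        means[i] = seg_raw.mean()
        seg = filtered[i * w : (i + 1) * w]
        spec = dft(BreathSignal(seg - seg.mean(), series.fs))
        _, freqs[i], _ = breathing_frequency(spec, f_low, f_high)
    return WindowedFeatures(
        window_len_s=window_len_s, times_s=times, means=means, freqs_bpm=freqs
    )


@dataclass(frozen=True)
class RegressionResult:
    """OLS recovery fit: slope in units/minute and normalised error S."""

    slope_per_min: float
    s_percent: float
    intercept: float
    n_windows: int


def recovery_regression(
    features: WindowedFeatures,
    interval: tuple[float, float],
    feature: str = "mean",
) -> RegressionResult:
    """Least-squares linear trend of a windowed feature over an interval.

    Time is expressed in minutes so the slope is in feature-units per
    minute.  S is the mean squared residual relative to the squared mean of
    the fitted values, as a percentage — zero for a noiseless line.
    """
    t0, t1 = interval
    mask = (features.times_s >= t0) & (features.times_s <= t1)
    if np.count_nonzero(mask) < 3:
        raise ValueError("need at least three windows inside the interval")
    t_min = features.times_s[mask] / 60.0
    v = features.values(feature)[mask]
    if np.ptp(t_min) <= 0:
        raise ValueError("degenerate interval: zero time variance")
    slope, intercept = np.polyfit(t_min, v, 1)
    fitted = slope * t_min + intercept
    denom = float(np.mean(fitted)) ** 2
    s = 100.0 * float(np.mean((v - fitted) ** 2)) / denom if denom > 0 else np.inf
    return RegressionResult(
        slope_per_min=float(slope),
        s_percent=float(s),
        intercept=float(intercept),
        n_windows=int(mask.sum()),
    )


@dataclass(frozen=True)
class Segment:
    """One activity segment: [start_s, end_s) labelled load or rest."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in ("load", "rest"):
            raise ValueError("segment label must be 'load' or 'rest'")
        if not self.start_s < self.end_s:
            raise ValueError("segment must have positive length")


@dataclass(frozen=True)
class ActivitySchedule:
    """Contiguous, non-overlapping sequence of load/rest segments."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule must contain at least one segment")
        for a, b in zip(self.segments, self.segments[1:]):
            if abs(a.end_s - b.start_s) > 1e-9:
                raise ValueError("segments must be contiguous and ordered")

    @classmethod
    def exercise_protocol(
        cls, n_cycles: int = 2, load_s: float = 600.0, rest_s: float = 600.0
    ) -> "ActivitySchedule":
        """Alternating exercise/rest blocks (default: two 10-min pairs)."""
        segs = []
        t = 0.0
        for _ in range(n_cycles):
            segs.append(Segment(t, t + load_s, "load"))
            t += load_s
            segs.append(Segment(t, t + rest_s, "rest"))
            t += rest_s
        return cls(tuple(segs))

    @property
    def total_s(self) -> float:
        return self.segments[-1].end_s


@dataclass(frozen=True)
class SegmentDelay:
    """Response delay of a feature after one activity change."""

    label: str
    boundary_s: float
    delay_s: float
    censored: bool


def response_delay(
    features: WindowedFeatures,
    schedule: ActivitySchedule,
    crossing: float = 0.5,
    feature: str = "mean",
) -> list[SegmentDelay]:
    """Delay between each activity change and the feature's response.

    For every segment after the first, the baseline is the mean of the last
    two windows before the boundary and the steady level is the mean of the
    last two windows inside the segment.  The delay is the time (linear
    interpolation between window centres) until the feature first crosses
    baseline + crossing*(steady - baseline).  A feature that never crosses
    is censored at the segment length.
    """
    if not 0.0 < crossing < 1.0:
        raise ValueError("crossing fraction must lie in (0, 1)")
    t = features.times_s
    v = features.values(feature)
    out: list[SegmentDelay] = []
    for seg in schedule.segments[1:]:
        before = np.flatnonzero(t < seg.start_s)
        inside = np.flatnonzero((t >= seg.start_s) & (t <= seg.end_s))
        if before.size < 2 or inside.size < 2:
            raise ValueError(
                f"segment at {seg.start_s} s needs >= 2 windows before and inside"
            )
        baseline = float(v[before[-2:]].mean())
        steady = float(v[inside[-2:]].mean())
        direction = np.sign(steady - baseline)
        length = seg.end_s - seg.start_s
        if direction == 0:
            out.append(SegmentDelay(seg.label, seg.start_s, length, True))
            continue
        target = baseline + crossing * (steady - baseline)
        t_prev, v_prev = seg.start_s, baseline
        crossed = None
        for j in inside:
            if direction * (v[j] - target) >= 0:
                frac = (target - v_prev) / (v[j] - v_prev)
                crossed = t_prev + frac * (t[j] - t_prev)
                break
            t_prev, v_prev = float(t[j]), float(v[j])
        if crossed is None:
            out.append(SegmentDelay(seg.label, seg.start_s, length, True))
        else:
            out.append(SegmentDelay(seg.label, seg.start_s, crossed - seg.start_s, False))
    return out
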