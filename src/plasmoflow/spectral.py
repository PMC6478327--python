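"""Spectral and contour statistics of plasmodial oscillation traces.

FFT amplitude spectra and dominant-period read-off, the frequency-selection
(low-pass) index comparing front and uroid spectra, cross-correlation decay
of vein velocity profiles, the circularity shape factor, and membrane
extension/retraction timing.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

__all__ = [
    "OscillationTrace", "SpectralResult", "SpectralPeak", "ContourMetrics",
    "CorrelationProfile",
    "fft_spectrum", "dominant_periods", "frequency_selection_index",
    "cross_correlation_profile", "circularity", "extension_retraction_ratio",
]


@dataclass(frozen=True)
class OscillationTrace:
    """Uniformly sampled oscillation time series.

    ``dt`` is the sampling interval in seconds; ``units`` labels the
    sample values (e.g. 'um/min'); ``position`` optionally names where
    along the cell the trace was taken ('uroid', 'front', 'segment3', …).
    """

    samples: np.ndarray = field(repr=False)
    dt: float
    units: str = ""
    position: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.samples.ndim != 1 or len(self.samples) < 4:
            raise ValueError("trace must be 1-D with at least 4 samples")
        if self.dt <= 0:
            raise ValueError("sampling interval must be > 0")

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dt

    @property
    def time(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt


@dataclass(frozen=True)
class SpectralPeak:
    frequency_hz: float
    period_min: float
    amplitude: float


@dataclass(frozen=True)
class SpectralResult:
    """One-sided amplitude spectrum of a trace.

    ``resolution_hz`` = 1/(N·dt) is the frequency-bin width; ``peaks``
    holds the detected local maxima sorted by descending amplitude
    (ties broken toward lower frequency).
    """

    frequencies_hz: np.ndarray = field(repr=False)
    amplitudes: np.ndarray = field(repr=False)
    resolution_hz: float
    peaks: tuple[SpectralPeak, ...] = ()

    def amplitude_at_period(self, period_min: float) -> float:
        """Spectrum amplitude at the bin nearest to a period (minutes)."""
        f = 1.0 / (period_min * 60.0)
        if f < self.frequencies_hz[1] / 2 or f > self.frequencies_hz[-1]:
            raise ValueError(
                f"period {period_min} min outside the resolved band "
                f"[{1 / (60 * self.frequencies_hz[-1]):.3g}, "
                f"{1 / (60 * self.resolution_hz):.3g}] min"
            )
        idx = int(np.argmin(np.abs(self.frequencies_hz - f)))
        return float(self.amplitudes[idx])


@dataclass(frozen=True)
class ContourMetrics:
    """Shape and timing metrics of a cell contour; unset fields are None."""

    circularity: float | None = None
    area: float | None = None
    perimeter: float | None = None
    t_ext_min: float | None = None
    t_ret_min: float | None = None
    ext_ret_ratio: float | None = None


@dataclass(frozen=True)
class CorrelationProfile:
    """Correlation of segment 1 against each subsequent segment.

    ``zero_lag[i]`` is the Pearson correlation with segment i+2 at zero
    lag; ``optimal[i]`` the maximum normalized cross-correlation over all
    lags, achieved at ``lag_s[i]`` seconds (positive = that segment is
    delayed relative to segment 1).
    """

    zero_lag: np.ndarray
    optimal: np.ndarray
    lag_s: np.ndarray


def fft_spectrum(
    trace: OscillationTrace,
    window: str | None = None,
    prominence_factor: float = 3.0,
) -> SpectralResult:
    """One-sided amplitude spectrum of a trace.

    The mean is removed; by default no taper is applied, matching a plain
    peak read-off.  ``window='hann'`` tapers the trace for noisy inputs
    (with the amplitude normalization corrected for the window's mean).
    Detected peaks are local maxima above ``prominence_factor`` × the
    median spectral amplitude.
    """
    x = trace.samples - np.mean(trace.samples)
    n = len(x)
    if window is None:
        w = np.ones(n)
    elif window == "hann":
        w = np.hanning(n)
    else:
        raise ValueError(f"unknown window {window!r}")
    spec = np.fft.rfft(x * w)
    # amplitude normalization: a pure cosine of amplitude A yields A
    amps = np.abs(spec) * 2.0 / np.sum(w)
    amps[0] /= 2.0
    if n % 2 == 0:
        amps[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=trace.dt)
    resolution = 1.0 / (n * trace.dt)
    peaks = _find_peaks(freqs, amps, prominence_factor)
    return SpectralResult(
        frequencies_hz=freqs, amplitudes=amps, resolution_hz=resolution, peaks=peaks
    )


def _find_peaks(
    freqs: np.ndarray, amps: np.ndarray, prominence_factor: float
) -> tuple[SpectralPeak, ...]:
    if len(amps) < 3:
        return ()
    median_amp = float(np.median(amps[1:]))
    threshold = prominence_factor * median_amp
    if threshold == 0.0:
        # flat spectrum (constant trace): nothing to report
        idx = np.array([], dtype=int)
    else:
        idx, _ = sp_signal.find_peaks(amps[1:], height=threshold)
        idx += 1  # DC bin excluded from the search
    peaks = [
        SpectralPeak(
            frequency_hz=float(freqs[i]),
            period_min=1.0 / (freqs[i] * 60.0),
            amplitude=float(amps[i]),
        )
        for i in idx
    ]
    peaks.sort(key=lambda p: (-p.amplitude, p.frequency_hz))
    return tuple(peaks)


def dominant_periods(spectrum: SpectralResult, k: int = 2) -> list[float]:
    """Periods (minutes) of the top-k spectral peaks, amplitude-ordered.

    If fewer than k peaks clear the prominence threshold, the shorter
    list is returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    periods = [p.period_min for p in spectrum.peaks[:k]]
    if len(periods) < k:
        warnings.warn(f"only {len(periods)} peaks found (requested {k})")
    return periods


def frequency_selection_index(
    front: SpectralResult,
    back: SpectralResult,
    low_period_min: float,
    high_period_min: float,
) -> dict[str, float]:
    """Low-pass selection between two spectra.

    Compares front/back amplitude ratios at a low-frequency tone (period
    ``low_period_min``) and a high-frequency tone (``high_period_min``).
    The selection index is (high-tone ratio)/(low-tone ratio); an index
    below 1 means the high tone is attenuated more on the way to the
    front — the signature of low-pass frequency selection.  The index is
    invariant under uniform amplitude rescaling of either spectrum.
    """
    if high_period_min >= low_period_min:
        raise ValueError("high-frequency tone must have the shorter period")
    ratios = {}
    for name, period in (("low", low_period_min), ("high", high_period_min)):
        a_front = front.amplitude_at_period(period)
        a_back = back.amplitude_at_period(period)
        if a_back == 0:
            raise ValueError(f"back spectrum has zero amplitude at the {name} tone")
        ratios[name] = a_front / a_back
    return {
        "ratio_low": ratios["low"],
        "ratio_high": ratios["high"],
        "selection_index": ratios["high"] / ratios["low"],
    }


def cross_correlation_profile(segments: list[OscillationTrace]) -> CorrelationProfile:
    """Correlation decay of vein velocity profiles along the cell.

    Segment 1 (closest to the uroid) is correlated against every
    subsequent segment; both the zero-lag Pearson correlation and the
    maximum over all lags (with the lag achieving it) are reported.
    Declining correlation from back to front quantifies the progressive
    decorrelation of the propagating flow wave.
    """
    if len(segments) < 2:
        raise ValueError("need at least two segments")
    n = len(segments[0].samples)
    dt = segments[0].dt
    for s in segments[1:]:
        if len(s.samples) != n or s.dt != dt:
            raise ValueError("segments must be identically sampled")
    ref = segments[0].samples - np.mean(segments[0].samples)
    ref_norm = np.linalg.norm(ref)
    zero_lag, optimal, lag_s = [], [], []
    for s in segments[1:]:
        x = s.samples - np.mean(s.samples)
        denom = ref_norm * np.linalg.norm(x)
        if denom == 0:
            raise ValueError("constant segment has undefined correlation")
        cc = sp_signal.correlate(x, ref, mode="full") / denom
        lags = sp_signal.correlation_lags(n, n, mode="full")
        best = int(np.argmax(cc))
        zero_lag.append(float(cc[lags == 0][0]))
        optimal.append(float(cc[best]))
        lag_s.append(float(lags[best] * dt))
    return CorrelationProfile(
        zero_lag=np.array(zero_lag), optimal=np.array(optimal), lag_s=np.array(lag_s)
    )


def circularity(area: float, perimeter: float) -> float:
    """Circularity f_circ = 4πA/P²: 1 for a circle, < 1 for elongated shapes."""
    if area <= 0 or perimeter <= 0:
        raise ValueError("area and perimeter must be > 0")
    return 4.0 * math.pi * area / perimeter**2


def extension_retraction_ratio(velocity: OscillationTrace) -> ContourMetrics:
    """Membrane extension vs retraction timing from a front-velocity trace.

    t_ext is the total time with outward (positive) velocity, t_ret the
    total time moving back toward the contour centre; exact zeros are
    split evenly between the two.  Persistently migrating cells extend
    longer than they retract, giving ratios above 1.
    """
    v = velocity.samples
    n_pos = int(np.sum(v > 0))
    n_neg = int(np.sum(v < 0))
    n_zero = len(v) - n_pos - n_neg
    if n_pos == 0 or n_neg == 0:
        raise ValueError("trace never changes sign: extension/retraction undefined")
    dt_min = velocity.dt / 60.0
    t_ext = (n_pos + 0.5 * n_zero) * dt_min
    t_ret = (n_neg + 0.5 * n_zero) * dt_min
    return ContourMetrics(
        t_ext_min=t_ext, t_ret_min=t_ret, ext_ret_ratio=t_ext / t_ret
    )
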