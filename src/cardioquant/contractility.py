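"""Contraction-event calling on single-cell length traces.

A length-vs-time trace is normalized to the first rest plateau, detrended by
subtracting the best-fit sixth-order polynomial, and contraction events are
called as peaks of the negated residual (x100, i.e. percent fractional
shortening) at or above a 5% threshold.  The per-cell summary is the mean
event amplitude and the frequency, defined as the inverse of the mean period
between events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from scipy.signal import find_peaks


@dataclass
class LengthTrace:
    """Cell length (pixels) on a uniform time grid (seconds)."""

    time: np.ndarray
    length: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.length = np.asarray(self.length, float)
        if self.time.shape != self.length.shape:
            raise ValueError("time and length must have the same shape")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def duration(self) -> float:
        return len(self.time) * self.frame_interval

    @classmethod
    def from_csv(cls, path) -> "LengthTrace":
        df = pd.read_csv(path)
        t = df["time_s"].to_numpy(float)
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
        return cls(time=t, length=df["length_px"].to_numpy(float), frame_interval=dt)

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "length_px": self.length}).to_csv(
            path, index=False
        )


@dataclass
class NormalizedTrace:
    """Rest-normalized, optionally detrended residual of a length trace.

    ``value`` is dimensionless: 0 at rest, negative during contraction, so
    ``-value * 100`` is percent fractional shortening.
    """

    time: np.ndarray
    value: np.ndarray
    rest_length: float
    frame_interval: float
    detrend_coefficients: np.ndarray | None = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.value = np.asarray(self.value, float)
        if self.rest_length <= 0:
            raise ValueError("rest_length must be positive")


@dataclass(frozen=True)
class EventParams:
    """Event-calling parameters.

    fs_threshold : percent fractional shortening a pulse must reach (default 5).
    min_event_separation : minimum peak-to-peak spacing in seconds (default 0.2,
        well below physiological inter-beat intervals).
    rest_window : length in seconds of the low-variation plateau that defines
        the rest length (default 1.0).
    """

    fs_threshold: float = 5.0
    min_event_separation: float = 0.2
    rest_window: float = 1.0

    def __post_init__(self) -> None:
        if self.fs_threshold <= 0:
            raise ValueError("fs_threshold must be positive")


@dataclass(frozen=True)
class ContractionEvent:
    peak_time: float
    amplitude: float  # percent fractional shortening
    onset_time: float
    offset_time: float


@dataclass
class ContractilityResult:
    n_events: int
    mean_amplitude: float  # percent
    frequency: float  # Hz; 0 with below_detection=True when < 2 events
    events: list[ContractionEvent]
    below_detection: bool = False

    def to_dict(self) -> dict:
        return {
            "n_events": self.n_events,
            "mean_amplitude_pct": self.mean_amplitude,
            "frequency_hz": self.frequency,
            "below_detection": self.below_detection,
            "events": [
                {
                    "peak_time_s": e.peak_time,
                    "amplitude_pct": e.amplitude,
                    "onset_s": e.onset_time,
                    "offset_s": e.offset_time,
                }
                for e in self.events
            ],
        }


def normalize_to_rest(trace: LengthTrace, params: EventParams | None = None) -> NormalizedTrace:
    """Normalize a length trace to the first rest plateau.

    The rest length is the median over the first ``rest_window``-long interval
    whose coefficient of variation is below 1% (cells are longest and quiet at
    rest).  If no such plateau exists (e.g. the recording opens
    mid-contraction) the 95th percentile of all lengths is used and the trace
    is flagged ``no-rest-plateau``.
    """
    params = params or EventParams()
    n = len(trace.length)
    w = max(2, int(round(params.rest_window / trace.frame_interval)))
    if n < 2 * w:
        raise ValueError("trace must be at least twice the rest window long")
    rest = None
    flags: tuple[str, ...] = ()
    for start in range(0, n - w + 1):
        seg = trace.length[start : start + w]
        m = seg.mean()
        if m > 0 and seg.std() / m < 0.01:
            rest = float(np.median(seg))
            break
    if rest is None:
        rest = float(np.percentile(trace.length, 95))
        flags = ("no-rest-plateau",)
    return NormalizedTrace(
        time=trace.time,
        value=trace.length / rest - 1.0,
        rest_length=rest,
        frame_interval=trace.frame_interval,
        flags=flags,
    )


def detrend(ntrace: NormalizedTrace, degree: int = 6, n_iter: int = 3) -> NormalizedTrace:
    """Subtract the best-fit (degree-6) polynomial baseline drift.

    The fit is made robust to the contractions themselves: after an initial
    least-squares fit, samples deflected far below the baseline (residual
    < -3 robust SD) are excluded and the polynomial is refit, for ``n_iter``
    rounds.  Without this the pulses drag the baseline down and event
    amplitudes are systematically underestimated.  Traces too short to
    support the fit get the degree reduced to ``floor(n/2) - 1`` with a
    warning.  The fitted coefficients (power basis, ascending) are stored on
    the result.
    """
    n = len(ntrace.value)
    deg = degree
    if n < 2 * (degree + 1):
        deg = max(0, n // 2 - 1)
        warnings.warn(f"trace of {n} samples too short for degree {degree}; using {deg}")
    keep = np.ones(n, bool)
    fit = Polynomial.fit(ntrace.time, ntrace.value, deg)
    for _ in range(n_iter):
        fit = Polynomial.fit(ntrace.time[keep], ntrace.value[keep], deg)
        residual = ntrace.value - fit(ntrace.time)
        sigma = 1.4826 * np.median(np.abs(residual[keep] - np.median(residual[keep])))
        new_keep = residual >= -max(3.0 * sigma, 1e-9)
        if new_keep.sum() <= deg + 1 or np.array_equal(new_keep, keep):
            break
        keep = new_keep
    residual = ntrace.value - fit(ntrace.time)
    return NormalizedTrace(
        time=ntrace.time,
        value=residual,
        rest_length=ntrace.rest_length,
        frame_interval=ntrace.frame_interval,
        detrend_coefficients=fit.convert().coef,
        flags=ntrace.flags,
    )


def _threshold_crossing(neg: np.ndarray, time: np.ndarray, peak: int, half: float, side: int) -> float:
    """Sub-sample time where ``neg`` crosses ``half`` walking from ``peak``."""
    i = peak
    while 0 <= i + side < len(neg) and neg[i + side] > half:
        i += side
    j = i + side
    if j < 0 or j >= len(neg):
        return float(time[i])
    # linear interpolation between samples i and j
    if neg[i] == neg[j]:
        return float(time[j])
    frac = (neg[i] - half) / (neg[i] - neg[j])
    return float(time[i] + frac * (time[j] - time[i]))


def detect_events(ntrace: NormalizedTrace, params: EventParams | None = None) -> list[ContractionEvent]:
    """Call contraction events on a detrended normalized trace.

    Peaks of ``-value * 100`` (percent fractional shortening) with height at or
    above ``fs_threshold`` and spacing of at least ``min_event_separation`` are
    events; onset/offset are the nearest crossings of half the threshold.
    """
    params = params or EventParams()
    neg = -ntrace.value * 100.0
    distance = max(1, int(round(params.min_event_separation / ntrace.frame_interval)))
    peaks, _ = find_peaks(neg, height=params.fs_threshold, distance=distance)
    half = params.fs_threshold / 2.0
    events = []
    for p in peaks:
        events.append(
            ContractionEvent(
                peak_time=float(ntrace.time[p]),
                amplitude=float(neg[p]),
                onset_time=_threshold_crossing(neg, ntrace.time, p, half, -1),
                offset_time=_threshold_crossing(neg, ntrace.time, p, half, +1),
            )
        )
    return events


def summarize(events: list[ContractionEvent], duration: float) -> ContractilityResult:
    """Per-cell summary: mean event amplitude and contraction frequency.

    Frequency is the inverse of the mean period between successive event
    peaks; with fewer than two events it is reported as 0 and flagged as below
    the detectable threshold.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = len(events)
    mean_amp = float(np.mean([e.amplitude for e in events])) if n else 0.0
    if n >= 2:
        peaks = np.array([e.peak_time for e in events])
        freq = float(1.0 / np.mean(np.diff(peaks)))
        below = False
    else:
        freq = 0.0
        below = True
    return ContractilityResult(
        n_events=n,
        mean_amplitude=mean_amp,
        frequency=freq,
        events=events,
        below_detection=below,
    )


def analyze_trace(trace: LengthTrace, params: EventParams | None = None) -> ContractilityResult:
    """normalize -> detrend -> detect -> summarize, in one call."""
    params = params or EventParams()
    nt = detrend(normalize_to_rest(trace, params))
    return summarize(detect_events(nt, params), trace.duration)


def analyze_stack(stack, seg_params=None, event_params=None):
    """Full movie pipeline: segmentation length readout plus event analysis.

    Returns (ContractilityResult, LengthTrace).
    """
    from .segmentation import track_length

    trace = track_length(stack, seg_params)
    return analyze_trace(trace, event_params), trace


def events_to_csv(events: list[ContractionEvent], path) -> None:
    pd.DataFrame(
        {
            "peak_time_s": [e.peak_time for e in events],
            "amplitude_pct": [e.amplitude for e in events],
            "onset_s": [e.onset_time for e in events],
            "offset_s": [e.offset_time for e in events],
        }
    ).to_csv(path, index=False)
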