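"""Synthetic inputs with recorded ground truth for every analysis stage.

Four generators emulate the four kinds of raw input the pipelines consume:

* ``make_cell_movie`` — a 16-bit time-lapse movie (one frame per 40 ms by
  default) of a single contracting cell, modelled as a filled ellipse whose
  long axis follows raised-cosine shortening pulses.
* ``make_chamber_traces`` — atrial/ventricular chamber-area-vs-time profiles
  as produced by semi-automated chamber delineation, modelled as sinusoids
  with optional skipped beats.
* ``make_coloc_pair`` — a two-channel image pair with a prescribed population
  Pearson correlation (Gaussian mixture construction).
* ``make_ibaq_table`` — a MaxQuant-style protein x run iBAQ table with
  log-normal run noise and per-condition detection dropout.

Each generator returns a :class:`GroundTruth` whose derived truths (true
fractional shortening, beat counts, fold changes, channel correlation) are
recomputable in closed form from the spec parameters, and all randomness flows
through one seeded generator per call, so identical specs and seeds give
byte-identical outputs.

The generators deliberately stop short of photorealism: no point-spread
function, no per-photon shot noise, and no 2-D beating-heart video — only the
quantities the downstream measurements actually consume.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .contractility import NormalizedTrace
from .enrichment import IbaqTable
from .rhythm import AreaProfile
from .segmentation import ImageStack


@dataclass
class GroundTruth:
    """Generator parameters plus closed-form derived truths."""

    params: dict
    truth: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"params": self.params, "truth": self.truth}, fh, indent=2, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON serializable: {type(x)}")


# ---------------------------------------------------------------------------
# cell movies


@dataclass(frozen=True)
class CellMovieSpec:
    """Parameters of a synthetic single-cell contraction movie.

    The cell is a filled ellipse centred in the frame.  At each event onset
    the long axis follows a raised-cosine pulse from ``rest_long_axis`` down
    to ``contraction_ratio * rest_long_axis`` and back; the short axis is held
    constant so the longest axis stays unambiguous.  True fractional
    shortening is therefore exactly ``(1 - contraction_ratio) * 100`` percent.
    """

    image_size: tuple[int, int] = (512, 512)
    frame_interval: float = 0.040  # seconds; the movie acquisition interval
    duration: float = 20.0
    rest_long_axis: float = 200.0  # full length, pixels
    rest_short_axis: float = 80.0
    contraction_ratio: float = 0.876
    pulse_duration: float = 0.6  # seconds per raised-cosine pulse
    event_onsets: tuple[float, ...] = (1.0, 4.7, 8.4, 12.1, 15.8)
    orientation_deg: float = 0.0
    foreground_level: float = 30000.0
    background_level: float = 2000.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.contraction_ratio <= 1:
            raise ValueError("contraction_ratio must be in (0, 1]")
        onsets = np.asarray(self.event_onsets, float)
        if onsets.size and np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        if onsets.size and np.any(np.diff(onsets) < self.pulse_duration):
            raise ValueError("pulse windows must not overlap")
        if not self.foreground_level > self.background_level:
            raise ValueError("foreground_level must exceed background_level")
        for v in (self.foreground_level, self.background_level):
            if not 0 <= v <= 65535:
                raise ValueError("intensity levels must be in [0, 65535]")
        h, w = self.image_size
        half = self.rest_long_axis / 2.0
        if half >= min(h, w) / 2.0 - 2 or self.rest_short_axis / 2.0 >= min(h, w) / 2.0 - 2:
            raise ValueError("ellipse exceeds frame bounds at rest; enlarge image_size")


def _pulse_fraction(t: np.ndarray, onsets: np.ndarray, dur: float) -> np.ndarray:
    """Sum of raised-cosine pulses, 0 at rest, 1 at each pulse peak."""
    f = np.zeros_like(t)
    for t0 in onsets:
        w = (t >= t0) & (t <= t0 + dur)
        f[w] += 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[w] - t0) / dur))
    return f


def make_cell_movie(spec: CellMovieSpec) -> tuple[ImageStack, GroundTruth]:
    """Render the movie and record its ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration / spec.frame_interval))
    t = np.arange(n) * spec.frame_interval
    onsets = np.asarray(spec.event_onsets, float)
    # only pulses that fit whole in the recording are rendered (and counted)
    onsets = onsets[onsets + spec.pulse_duration <= spec.duration]
    frac = _pulse_fraction(t, onsets, spec.pulse_duration)
    long_axes = spec.rest_long_axis * (1.0 - (1.0 - spec.contraction_ratio) * frac)

    h, w = spec.image_size
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    theta = np.deg2rad(spec.orientation_deg)
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    b = spec.rest_short_axis / 2.0

    frames = np.empty((n, h, w), dtype=np.uint16)
    for i in range(n):
        a = long_axes[i] / 2.0
        inside = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        img = np.where(inside, spec.foreground_level, spec.background_level).astype(float)
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
        frames[i] = np.clip(np.rint(img), 0, 65535).astype(np.uint16)

    peak_times = onsets + spec.pulse_duration / 2.0
    truth = {
        "fs_pct": (1.0 - spec.contraction_ratio) * 100.0,
        "n_events": int(onsets.size),
        "event_onsets_s": onsets.tolist(),
        "event_peak_times_s": peak_times.tolist(),
        "frequency_hz": float(1.0 / np.mean(np.diff(peak_times))) if onsets.size >= 2 else 0.0,
    }
    stack = ImageStack(frames=frames, frame_interval=spec.frame_interval)
    return stack, GroundTruth(params=asdict(spec), truth=truth)


# ---------------------------------------------------------------------------
# chamber-area traces


@dataclass(frozen=True)
class ChamberTraceSpec:
    """Parameters of synthetic atrial/ventricular area profiles.

    Each chamber's area is ``baseline * (1 + amplitude * sin(2 pi t / period))``
    with listed beats deleted (area held at baseline across the skipped cycle)
    and Gaussian noise added.  Defaults model a healthy embryonic heart
    beating 1:1 at 140 bpm (period 3/7 s) with a 20% area excursion.
    """

    duration: float = 15.0
    sample_interval: float = 0.04
    atrial_period: float = 3.0 / 7.0
    ventricular_period: float = 3.0 / 7.0
    atrial_amplitude: float = 0.2
    ventricular_amplitude: float = 0.2
    baseline_area: float = 1.0
    skipped_beat_times: tuple[float, ...] = ()
    skipped_beat_chamber: str = "ventricle"
    noise_sd: float = 0.0  # fraction of mean area
    seed: int = 0

    def validate(self) -> None:
        for p in (self.atrial_period, self.ventricular_period):
            if p <= 2 * self.sample_interval:
                raise ValueError("periods must exceed twice the sample interval")
        for a in (self.atrial_amplitude, self.ventricular_amplitude):
            if not 0 <= a < 1:
                raise ValueError("amplitudes must be in [0, 1)")
        for s in self.skipped_beat_times:
            if not 0 <= s < self.duration:
                raise ValueError(f"skipped beat time {s} outside [0, duration)")


def _peak_times(period: float, duration: float) -> np.ndarray:
    """Maxima of sin(2 pi t / period) in [0, duration): T/4 + k T."""
    first = period / 4.0
    k = np.arange(0, int(np.ceil((duration - first) / period)) + 1)
    peaks = first + k * period
    return peaks[peaks < duration]


def make_chamber_traces(
    spec: ChamberTraceSpec,
) -> tuple[AreaProfile, AreaProfile, GroundTruth]:
    """Generate atrium and ventricle area profiles plus ground-truth counts."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    # inclusive endpoint: a "15 s" recording covers [0, 15] so that a beat
    # cycle fitting the recording an integer number of times is sampled whole
    n = int(round(spec.duration / spec.sample_interval)) + 1
    t = np.arange(n) * spec.sample_interval

    profiles = {}
    true_counts = {}
    for chamber, period, amp in (
        ("atrium", spec.atrial_period, spec.atrial_amplitude),
        ("ventricle", spec.ventricular_period, spec.ventricular_amplitude),
    ):
        signal = amp * np.sin(2.0 * np.pi * t / period)
        peaks = _peak_times(period, spec.duration)
        n_skipped = 0
        if chamber == spec.skipped_beat_chamber:
            # hold at baseline from zero-crossing to zero-crossing (+-3T/4)
            # around the deleted maximum, so the flanking minima go too and no
            # spurious plateau-maximum is left behind
            for s in spec.skipped_beat_times:
                p = peaks[np.argmin(np.abs(peaks - s))]
                signal[(t >= p - 0.75 * period) & (t <= p + 0.75 * period)] = 0.0
                n_skipped += 1
        area = spec.baseline_area * (1.0 + signal)
        if spec.noise_sd > 0:
            area = area + spec.baseline_area * rng.normal(0.0, spec.noise_sd, size=n)
        profiles[chamber] = AreaProfile(
            chamber=chamber, time=t, area=area, sample_interval=spec.sample_interval
        )
        true_counts[chamber] = int(len(peaks)) - (n_skipped if amp > 0 else 0)
        if amp == 0:
            true_counts[chamber] = 0

    truth = {
        "beat_count_atrium": true_counts["atrium"],
        "beat_count_ventricle": true_counts["ventricle"],
        "bpm_atrium": true_counts["atrium"] * 60.0 / spec.duration,
        "bpm_ventricle": true_counts["ventricle"] * 60.0 / spec.duration,
        "av_ratio": (
            true_counts["atrium"] / true_counts["ventricle"]
            if true_counts["ventricle"]
            else None
        ),
    }
    return profiles["atrium"], profiles["ventricle"], GroundTruth(asdict(spec), truth)


# ---------------------------------------------------------------------------
# colocalization pairs


def make_coloc_pair(
    rho: float,
    size: tuple[int, ...] = (512, 512),
    seed: int = 0,
    mean: float = 32000.0,
    sd: float = 3500.0,
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Two 16-bit channels with population Pearson correlation ``rho``.

    Channel B is ``rho * A + sqrt(1 - rho^2) * independent noise`` on
    standardized Gaussian fields, then both are affinely rescaled into the
    16-bit range (correlation is affine-invariant).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    a0 = rng.standard_normal(size)
    noise = rng.standard_normal(size)
    b0 = rho * a0 + np.sqrt(1.0 - rho * rho) * noise
    ch_a = np.clip(np.rint(mean + sd * a0), 0, 65535).astype(np.uint16)
    ch_b = np.clip(np.rint(mean + sd * b0), 0, 65535).astype(np.uint16)
    truth = {"rho": float(rho), "n_voxels": int(np.prod(size))}
    params = {"rho": float(rho), "size": list(size), "seed": seed, "mean": mean, "sd": sd}
    return ch_a, ch_b, GroundTruth(params, truth)


# ---------------------------------------------------------------------------
# iBAQ tables


@dataclass(frozen=True)
class IbaqTableSpec:
    """Parameters of a synthetic iBAQ intensity table.

    ``condition_runs`` gives the number of MS runs per condition (default two
    conditions with 4 runs each, i.e. 8 runs total).  ``mean_intensity`` is a
    (protein, condition) array of true condition means; per-run intensities
    are drawn log-normally around them with coefficient of variation
    ``noise_cv`` and zeroed out (not detected) with probability
    ``1 - detection_probability``.
    """

    mean_intensity: tuple[tuple[float, ...], ...] = ((1000.0, 100.0), (500.0, 500.0))
    condition_runs: tuple[tuple[str, int], ...] = (("transfected", 4), ("control", 4))
    detection_probability: float | tuple[tuple[float, ...], ...] = 1.0
    noise_cv: float = 0.0
    nd_impute_value: float = 10.0
    protein_prefix: str = "P"
    seed: int = 0

    @property
    def n_proteins(self) -> int:
        return len(self.mean_intensity)

    @property
    def conditions(self) -> list[str]:
        return [c for c, _ in self.condition_runs]

    def validate(self) -> None:
        if any(n < 1 for _, n in self.condition_runs):
            raise ValueError("run counts must be >= 1")
        means = np.asarray(self.mean_intensity, float)
        if means.ndim != 2 or means.shape[1] != len(self.condition_runs):
            raise ValueError("mean_intensity must be (n_proteins, n_conditions)")
        if np.any(means <= 0):
            raise ValueError("mean intensities must be positive")
        p = self._detection_matrix()
        if np.any((p < 0) | (p > 1)):
            raise ValueError("detection probabilities must be in [0, 1]")

    def _detection_matrix(self) -> np.ndarray:
        if np.isscalar(self.detection_probability):
            return np.full(
                (self.n_proteins, len(self.condition_runs)),
                float(self.detection_probability),
            )
        return np.asarray(self.detection_probability, float)


def make_ibaq_table(spec: IbaqTableSpec) -> tuple[IbaqTable, GroundTruth]:
    """Draw a table and record closed-form true fold changes.

    True condition means follow the analysis imputation rule: a condition with
    detection probability 0 contributes ``nd_impute_value``; the true fold
    change is the ratio of the first condition's mean to the second's.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    means = np.asarray(spec.mean_intensity, float)
    pdet = spec._detection_matrix()
    sigma = np.sqrt(np.log1p(spec.noise_cv**2))

    columns: dict[str, np.ndarray] = {}
    conditions: dict[str, str] = {}
    for j, (cond, n_runs) in enumerate(spec.condition_runs):
        for r in range(1, n_runs + 1):
            run = f"{cond}_{r}"
            if sigma > 0:
                z = rng.standard_normal(spec.n_proteins)
                vals = means[:, j] * np.exp(sigma * z - sigma * sigma / 2.0)
            else:
                vals = means[:, j].copy()
            detected = rng.random(spec.n_proteins) < pdet[:, j]
            vals = np.where(detected, vals, np.nan)
            columns[run] = vals
            conditions[run] = cond

    proteins = [f"{spec.protein_prefix}{i + 1}" for i in range(spec.n_proteins)]
    df = pd.DataFrame(columns, index=pd.Index(proteins, name="Protein IDs"))
    table = IbaqTable(intensities=df, conditions=conditions)

    true_means = np.where(pdet > 0, means, spec.nd_impute_value)
    truth = {
        "fold_change": {
            proteins[i]: float(true_means[i, 0] / true_means[i, 1])
            for i in range(spec.n_proteins)
        },
        "numerator": spec.conditions[0],
        "denominator": spec.conditions[1],
    }
    return table, GroundTruth(asdict(spec), truth)


# ---------------------------------------------------------------------------
# analytic pulse traces (already-normalized residuals)


def make_pulse_trace(
    amplitudes_pct,
    peak_times,
    duration: float,
    sample_interval: float = 0.04,
    pulse_duration: float = 0.64,
) -> NormalizedTrace:
    """A noiseless normalized residual with raised-cosine shortening pulses.

    Pulse ``k`` reaches ``-amplitudes_pct[k] / 100`` at ``peak_times[k]``.
    Useful for exercising the event detector in isolation with analytically
    known amplitudes.
    """
    amplitudes_pct = np.atleast_1d(np.asarray(amplitudes_pct, float))
    peak_times = np.atleast_1d(np.asarray(peak_times, float))
    if amplitudes_pct.shape != peak_times.shape:
        raise ValueError("amplitudes and peak times must align")
    n = int(round(duration / sample_interval))
    t = np.arange(n) * sample_interval
    value = np.zeros(n)
    for amp, c in zip(amplitudes_pct, peak_times):
        onset = c - pulse_duration / 2.0
        w = (t >= onset) & (t <= onset + pulse_duration)
        value[w] -= (amp / 100.0) * 0.5 * (
            1.0 - np.cos(2.0 * np.pi * (t[w] - onset) / pulse_duration)
        )
    return NormalizedTrace(
        time=t, value=value, rest_length=1.0, frame_interval=sample_interval
    )


# ---------------------------------------------------------------------------
# writers


def write_ibaq_tsv(table: IbaqTable, path) -> None:
    """Write a MaxQuant-style TSV; n.d. is an empty cell, never 0."""
    out = table.intensities.copy()
    out.columns = [f"iBAQ {c}" for c in out.columns]
    out.reset_index().to_csv(path, sep="\t", index=False, na_rep="")
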