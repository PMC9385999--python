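"""Auditory brainstem response (ABR) analysis.

The analysis follows the dual-RMS-window strategy: a 1.5 ms *early* window
anchored at the onset of wave I (the compound auditory-nerve response) and a
contiguous 6.0 ms *late* window covering the brainstem-generated waves.
Input/output (I/O) functions plot the RMS amplitude of each window against
stimulus level; thresholds are grid-valued ("the intensity above which the RMS
amplitude exceeds 0.1 µV"); per-peak latencies are read from the positive peaks
of waves I-VI. A conductive hearing loss appears as a frequency-flat threshold
shift, a parallel rightward I/O shift, and latency delays that disappear when
the two groups are compared at the same sensation level (dB above threshold).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt

from otokit._common import (
    InvalidWindowError,
    NoSignalError,
    ThresholdResult,
    suffix_threshold,
)

__all__ = [
    "ABRRecording",
    "ABRLevelSeries",
    "WaveWindows",
    "IOFunction",
    "PeakLatencies",
    "EqualSLComparison",
    "ThresholdShiftResult",
    "bandpass",
    "detect_wave1_onset",
    "build_windows",
    "rms_amplitude",
    "build_io",
    "estimate_threshold",
    "peak_latencies",
    "threshold_shift",
    "equal_sl_latency_compare",
]

EARLY_WINDOW_MS = 1.5
LATE_WINDOW_MS = 6.0
#: default criterion for grid-valued thresholds, µV RMS
DEFAULT_CRITERION_UV = 0.1


@dataclass(frozen=True)
class ABRRecording:
    """One averaged evoked response at a single stimulus level.

    ``samples`` are in µV on a uniform time grid starting at stimulus onset.
    """

    samples: np.ndarray
    sampling_rate_hz: float
    stimulus_frequency_hz: float
    level_db_spl: float
    subject_id: str = "unknown"
    genotype: str = "unknown"

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.samples.size) * (1000.0 / self.sampling_rate_hz)

    @property
    def duration_ms(self) -> float:
        return self.samples.size * 1000.0 / self.sampling_rate_hz

    @property
    def sample_period_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz


@dataclass(frozen=True)
class ABRLevelSeries:
    """Averaged responses of one subject at one frequency, one per level."""

    recordings: tuple[ABRRecording, ...]

    def __post_init__(self) -> None:
        recs = tuple(sorted(self.recordings, key=lambda r: r.level_db_spl))
        if not recs:
            raise ValueError("series must contain at least one recording")
        levels = [r.level_db_spl for r in recs]
        if len(set(levels)) != len(levels):
            raise ValueError("levels must be unique within a series")
        rates = {r.sampling_rate_hz for r in recs}
        if len(rates) != 1:
            raise ValueError("inconsistent sampling rates within a series")
        object.__setattr__(self, "recordings", recs)

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(r.level_db_spl for r in self.recordings)

    @property
    def sampling_rate_hz(self) -> float:
        return self.recordings[0].sampling_rate_hz

    def at_level(self, level: float) -> ABRRecording:
        for rec in self.recordings:
            if math.isclose(rec.level_db_spl, level):
                return rec
        raise KeyError(f"level {level} dB SPL not in series (grid: {self.levels})")


@dataclass(frozen=True)
class WaveWindows:
    """Contiguous early/late RMS analysis windows anchored at wave-I onset (ms)."""

    wave1_onset_ms: float

    @property
    def early(self) -> tuple[float, float]:
        return (self.wave1_onset_ms, self.wave1_onset_ms + EARLY_WINDOW_MS)

    @property
    def late(self) -> tuple[float, float]:
        start = self.wave1_onset_ms + EARLY_WINDOW_MS
        return (start, start + LATE_WINDOW_MS)


@dataclass(frozen=True)
class IOFunction:
    """Level -> RMS amplitude pairs for one window kind ('early' or 'late')."""

    points: tuple[tuple[float, float], ...]
    window_kind: str

    def __post_init__(self) -> None:
        pts = tuple(sorted((float(l), float(a)) for l, a in self.points))
        if any(a < 0 for _, a in pts):
            raise ValueError("RMS amplitudes must be non-negative")
        levels = [l for l, _ in pts]
        if len(set(levels)) != len(levels):
            raise ValueError("levels must be unique")
        object.__setattr__(self, "points", pts)

    @property
    def levels(self) -> tuple[float, ...]:
        return tuple(l for l, _ in self.points)

    @property
    def amplitudes(self) -> tuple[float, ...]:
        return tuple(a for _, a in self.points)


@dataclass(frozen=True)
class PeakLatencies:
    """Positive-peak latencies (ms) of waves I-VI; missing peaks are absent keys."""

    latencies_ms: Mapping[int, float]
    level_db_spl: float
    warning: bool = False

    def __post_init__(self) -> None:
        lats = dict(sorted(self.latencies_ms.items()))
        vals = list(lats.values())
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("peak latencies must increase from wave I to VI")
        object.__setattr__(self, "latencies_ms", lats)


@dataclass(frozen=True)
class ThresholdShiftResult:
    """Per-frequency threshold shifts (dB) and a flatness index (max - min)."""

    shifts_db: Mapping[float, float]
    excluded: tuple[float, ...] = ()

    @property
    def flatness_db(self) -> float:
        vals = list(self.shifts_db.values())
        return max(vals) - min(vals)


@dataclass(frozen=True)
class EqualSLComparison:
    """Per-peak latencies of two groups compared at matched sensation levels."""

    table: pd.DataFrame
    reference_level_db: float
    comparison_level_db: float
    sl_db: float


def bandpass(
    rec: ABRRecording, low_hz: float = 300.0, high_hz: float = 3000.0, order: int = 4
) -> ABRRecording:
    """Zero-phase Butterworth bandpass for raw acquisitions.

    Synthetic averages are generated in-band and do not need this step.
    """
    sos = butter(order, [low_hz, high_hz], btype="band", fs=rec.sampling_rate_hz, output="sos")
    return replace(rec, samples=sosfiltfilt(sos, rec.samples))


def _baseline_sd(rec: ABRRecording, baseline_ms: float = 1.0) -> float:
    n = max(2, int(round(baseline_ms * rec.sampling_rate_hz / 1000.0)))
    return float(np.std(rec.samples[:n]))


def _wave1_peak_index(rec: ABRRecording, template_latency_ms: float) -> int | None:
    """Index of the most prominent positive peak within template +/- 1 ms, or None."""
    x = rec.samples
    t = rec.times_ms
    lo, hi = template_latency_ms - 1.0, template_latency_ms + 1.0
    idx, props = find_peaks(x, prominence=0.0)
    in_window = idx[(t[idx] >= lo) & (t[idx] <= hi)]
    if in_window.size == 0:
        return None
    floor = 2.0 * _baseline_sd(rec)
    candidates = in_window[x[in_window] > floor]
    if candidates.size == 0:
        return None
    return int(candidates[np.argmax(x[candidates])])


def detect_wave1_onset(rec: ABRRecording, template_latency_ms: float) -> float:
    """Onset of wave I: the foot of the first prominent positive peak near a template.

    Walking back from the peak, onset is the latest sample that is non-positive,
    a local minimum, or below 10% of the peak height (whichever comes first);
    if no peak exceeds twice the baseline SD, the template latency is returned.
    The result is quantized to the sample grid.
    """
    x = rec.samples
    if x.size == 0 or not np.all(np.isfinite(x)) or np.all(x == 0):
        raise NoSignalError("recording contains no usable signal")
    if rec.duration_ms < 10.0:
        raise ValueError("recording must span at least 10 ms post-stimulus")
    peak = _wave1_peak_index(rec, template_latency_ms)
    if peak is None:
        return float(template_latency_ms)
    height = x[peak]
    j = peak - 1
    while j > 0:
        if x[j] <= 0 or x[j] < 0.1 * height:
            break
        if x[j] <= x[j - 1] and x[j] <= x[j + 1]:
            break
        j -= 1
    return float(j) * rec.sample_period_ms


def build_windows(onset_ms: float) -> WaveWindows:
    """Early [onset, onset+1.5) and late [onset+1.5, onset+7.5) windows."""
    if onset_ms < 0:
        raise ValueError("onset must be non-negative")
    return WaveWindows(wave1_onset_ms=float(onset_ms))


def rms_amplitude(rec: ABRRecording, window: tuple[float, float]) -> float:
    """Root-mean-square amplitude over a half-open [start, end) time window (ms).

    No baseline subtraction is applied: averaged responses are assumed zero-mean
    after the acquisition bandpass. Use :func:`bandpass` (or subtract the mean)
    for raw field data that violates this.
    """
    start, end = window
    if end <= start:
        raise InvalidWindowError("window end must exceed start")
    t = rec.times_ms
    mask = (t >= start) & (t < end)
    if not np.any(mask):
        raise InvalidWindowError(f"window [{start}, {end}) ms selects no samples")
    return float(np.sqrt(np.mean(rec.samples[mask] ** 2)))


def _chained_onsets(
    series: ABRLevelSeries, initial_template_ms: float
) -> dict[float, tuple[float, WaveWindows]]:
    """Wave-I peak template chained from high to low level.

    The detected peak latency at each level seeds the search at the next lower
    level, tracking the rightward drift of the analysis windows as intensity
    decreases.
    """
    out: dict[float, tuple[float, WaveWindows]] = {}
    template = float(initial_template_ms)
    for rec in sorted(series.recordings, key=lambda r: -r.level_db_spl):
        onset = detect_wave1_onset(rec, template)
        peak = _wave1_peak_index(rec, template)
        if peak is not None:
            template = rec.times_ms[peak]
        out[rec.level_db_spl] = (onset, build_windows(onset))
    return out


def build_io(
    series: ABRLevelSeries,
    window_kind: str = "early",
    initial_template_ms: float = 1.5,
) -> IOFunction:
    """RMS amplitude-versus-level function for the early or late window."""
    if window_kind not in ("early", "late"):
        raise ValueError("window_kind must be 'early' or 'late'")
    if len(series.recordings) < 2:
        raise ValueError("an I/O function needs at least two levels")
    onsets = _chained_onsets(series, initial_template_ms)
    points = []
    for rec in series.recordings:
        _, windows = onsets[rec.level_db_spl]
        win = windows.early if window_kind == "early" else windows.late
        points.append((rec.level_db_spl, rms_amplitude(rec, win)))
    return IOFunction(points=tuple(points), window_kind=window_kind)


def estimate_threshold(
    io: IOFunction, criterion_uv: float = DEFAULT_CRITERION_UV
) -> ThresholdResult:
    """Grid-valued threshold: lowest level above which RMS amplitude > criterion.

    All tested levels strictly above the threshold must exceed the criterion
    (suffix rule); if the top level fails, the threshold is "not reached".
    No interpolation between grid levels is performed.
    """
    if not io.points:
        raise ValueError("empty I/O function")
    exceeds = [a > criterion_uv for a in io.amplitudes]
    thr = suffix_threshold(io.levels, exceeds)
    return ThresholdResult(
        threshold_db=thr,
        criterion=criterion_uv,
        rule={"kind": "suffix", "comparison": ">", "window": io.window_kind},
    )


def peak_latencies(
    rec: ABRRecording,
    windows: WaveWindows,
    max_peaks: int = 6,
    min_separation_ms: float = 0.5,
) -> PeakLatencies:
    """Latencies of up to six positive peaks, labelled I-VI ordinally by time.

    Peaks are local maxima within [early start, late end) separated by at least
    ``min_separation_ms``; labelling is by temporal order starting in the early
    window, not by morphology. A flat or featureless trace yields an empty
    result with ``warning=True``.
    """
    t = rec.times_ms
    if rec.duration_ms < windows.late[1]:
        raise ValueError("recording does not span the late analysis window")
    region = (t >= windows.early[0]) & (t < windows.late[1])
    x = np.where(region, rec.samples, 0.0)
    distance = max(1, int(round(min_separation_ms * rec.sampling_rate_hz / 1000.0)))
    region_max = float(np.max(x)) if np.any(x > 0) else 0.0
    floor = max(2.0 * _baseline_sd(rec), 0.05 * region_max)
    idx, _ = find_peaks(x, distance=distance, height=floor if floor > 0 else None)
    idx = idx[region[idx]]
    if idx.size == 0:
        return PeakLatencies(latencies_ms={}, level_db_spl=rec.level_db_spl, warning=True)
    lats = {k + 1: float(t[i]) for k, i in enumerate(idx[:max_peaks])}
    return PeakLatencies(latencies_ms=lats, level_db_spl=rec.level_db_spl)


def threshold_shift(
    reference: Mapping[float, ThresholdResult],
    shifted: Mapping[float, ThresholdResult],
) -> ThresholdShiftResult:
    """Per-frequency threshold elevation (shifted - reference) and its flatness.

    Frequencies with an unreached threshold in either group are excluded and
    reported in ``excluded``. A conductive loss produces a frequency-flat shift
    (flatness no larger than the level grid step).
    """
    if set(reference) != set(shifted):
        raise ValueError("frequency sets must match")
    shifts: dict[float, float] = {}
    excluded: list[float] = []
    for freq in sorted(reference):
        a, b = reference[freq], shifted[freq]
        if not (a.reached and b.reached):
            excluded.append(freq)
            continue
        shifts[freq] = b.threshold_db - a.threshold_db
    if not shifts:
        raise ValueError("no frequency has a reached threshold in both groups")
    return ThresholdShiftResult(shifts_db=shifts, excluded=tuple(excluded))


def _nearest_grid_level(levels: Sequence[float], target: float) -> float:
    # ties broken toward the lower level
    return min(levels, key=lambda l: (abs(l - target), l))


def equal_sl_latency_compare(
    reference_series: ABRLevelSeries,
    reference_threshold: ThresholdResult,
    comparison_series: ABRLevelSeries,
    comparison_threshold: ThresholdResult,
    sl_db: float,
    initial_template_ms: float = 1.5,
    max_peaks: int = 6,
) -> EqualSLComparison:
    """Per-peak latencies at matched sensation level (threshold + sl, nearest grid level).

    Comparing at equal sensation level compensates for a conductive loss: the
    latency delays seen at equal absolute level should disappear. Differences
    are ``comparison - reference`` in ms.
    """
    rows = []
    picked: dict[str, tuple[float, PeakLatencies]] = {}
    for name, series, thr in (
        ("reference", reference_series, reference_threshold),
        ("comparison", comparison_series, comparison_threshold),
    ):
        if not thr.reached:
            raise ValueError(f"{name} series threshold not reached")
        target = thr.threshold_db + sl_db
        if target > max(series.levels) + 1e-9:
            raise ValueError(
                f"requested sensation level {sl_db} dB exceeds the {name} series grid "
                f"(needs {target} dB SPL, grid tops out at {max(series.levels)})"
            )
        level = _nearest_grid_level(series.levels, target)
        onsets = _chained_onsets(series, initial_template_ms)
        _, windows = onsets[level]
        lats = peak_latencies(series.at_level(level), windows, max_peaks=max_peaks)
        picked[name] = (level, lats)
    ref_level, ref_lats = picked["reference"]
    cmp_level, cmp_lats = picked["comparison"]
    for wave in sorted(set(ref_lats.latencies_ms) | set(cmp_lats.latencies_ms)):
        a = ref_lats.latencies_ms.get(wave)
        b = cmp_lats.latencies_ms.get(wave)
        rows.append(
            {
                "wave": wave,
                "reference_latency_ms": a,
                "comparison_latency_ms": b,
                "difference_ms": (b - a) if (a is not None and b is not None) else np.nan,
            }
        )
    table = pd.DataFrame(rows, columns=["wave", "reference_latency_ms", "comparison_latency_ms", "difference_ms"])
    return EqualSLComparison(
        table=table,
        reference_level_db=ref_level,
        comparison_level_db=cmp_level,
        sl_db=float(sl_db),
    )
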