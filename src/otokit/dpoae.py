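"""Distortion-product otoacoustic emission (DPOAE) extraction and thresholding.

Two primaries f1 < f2 (f2/f1 ~ 1.2, L1 = L2 + 10 dB) drive the cochlea, which
emits a distortion product at 2*f1 - f2 measured by an ear-canal microphone.
Amplitudes of F1, F2 and 2f1-f2 are read from an FFT in a 12.5 Hz band; the
noise floor is the mean bin power in two 25 Hz bands flanking the distortion
product (+/-25 to +/-50 Hz). The DPOAE threshold is the L2 level above which
the emission exceeds the mean noise floor by at least 5 dB at every higher
tested level.

The analysis segment is 80 ms, rectangular-windowed, taken 5 ms into the 90 ms
steady-state stimulus: 80 ms is the only segment length for which the stated
12.5 Hz band is exactly one FFT bin. Stimulus frequencies are quantized to
that bin grid (frequency-locked primaries) so that each tone occupies a single
bin; see :func:`design_stimulus`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.fft import rfft

from otokit._common import ThresholdResult, suffix_threshold

__all__ = [
    "DPOAEStimulus",
    "EarCanalRecording",
    "DPOAESweepResult",
    "DPOAEIOFunction",
    "design_stimulus",
    "band_amplitude",
    "noise_floor",
    "mean_noise_floor",
    "analyze_sweep",
    "build_dpoae_io",
    "dpoae_threshold",
]

#: reference pressure for dB SPL, Pa RMS
P_REF_PA = 20e-6
#: analysis bin width, Hz (exactly one FFT bin of the 80 ms segment)
ANALYSIS_BANDWIDTH_HZ = 12.5
SEGMENT_START_S = 0.005
SEGMENT_DURATION_S = 0.080
#: finite stand-in for minus infinity on zero-power bands, dB SPL
SENTINEL_FLOOR_DB = -150.0
DEFAULT_MARGIN_DB = 5.0
F2_F1_RATIO = 1.2


@dataclass(frozen=True)
class DPOAEStimulus:
    """Primary-tone pair; the distortion product sits at 2*f1 - f2."""

    f1_hz: float
    f2_hz: float
    l1_db_spl: float
    l2_db_spl: float

    def __post_init__(self) -> None:
        if self.f1_hz <= 0 or self.f2_hz <= 0:
            raise ValueError("primary frequencies must be positive")
        if self.dp_frequency_hz <= 0:
            raise ValueError("distortion-product frequency must be positive")
        if not math.isclose(self.l1_db_spl, self.l2_db_spl + 10.0, abs_tol=1e-9):
            raise ValueError("L1 must equal L2 + 10 dB")
        ratio = self.f2_hz / self.f1_hz
        if abs(ratio - F2_F1_RATIO) > 0.01 * F2_F1_RATIO:
            raise ValueError(f"f2/f1 ratio {ratio:.4f} too far from {F2_F1_RATIO}")

    @property
    def dp_frequency_hz(self) -> float:
        return 2.0 * self.f1_hz - self.f2_hz


@dataclass(frozen=True)
class EarCanalRecording:
    """Microphone pressure (Pa) recorded in the ear canal during one sweep."""

    samples: np.ndarray
    sampling_rate_hz: float
    stimulus: DPOAEStimulus

    def __post_init__(self) -> None:
        x = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(x)):
            raise ValueError("samples must be finite")
        object.__setattr__(self, "samples", x)

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz


@dataclass(frozen=True)
class DPOAESweepResult:
    """Extracted amplitudes (dB SPL) at one L2 step."""

    l2_db_spl: float
    f1_amp_db: float
    f2_amp_db: float
    dp_amp_db: float
    noise_floor_db: float


@dataclass(frozen=True)
class DPOAEIOFunction:
    """Distortion-product level versus L2, with per-point noise floors."""

    points: tuple[DPOAESweepResult, ...]
    f2_hz: float

    def __post_init__(self) -> None:
        pts = tuple(sorted(self.points, key=lambda p: p.l2_db_spl))
        levels = [p.l2_db_spl for p in pts]
        if len(set(levels)) != len(levels):
            raise ValueError("duplicate L2 levels")
        object.__setattr__(self, "points", pts)

    @property
    def l2_levels(self) -> tuple[float, ...]:
        return tuple(p.l2_db_spl for p in self.points)


def design_stimulus(
    f2_hz: float, l2_db_spl: float, bin_hz: float | None = ANALYSIS_BANDWIDTH_HZ
) -> DPOAEStimulus:
    """Primary pair for a nominal f2: f1 = f2/1.2, L1 = L2 + 10 dB.

    Both primaries are rounded to the spectral bin grid (``bin_hz``), the
    standard frequency-locking used by DPOAE rigs so that each tone and the
    distortion product fall exactly on analysis bins; pass ``bin_hz=None`` for
    the unquantized pair. The quantized ratio stays within ~0.1% of 1.2.
    """
    if f2_hz <= 0:
        raise ValueError("f2 must be positive")
    f1 = f2_hz / F2_F1_RATIO
    if bin_hz is not None:
        f2_hz = round(f2_hz / bin_hz) * bin_hz
        f1 = round(f1 / bin_hz) * bin_hz
    return DPOAEStimulus(
        f1_hz=f1, f2_hz=f2_hz, l1_db_spl=l2_db_spl + 10.0, l2_db_spl=l2_db_spl
    )


def _analysis_segment(rec: EarCanalRecording) -> np.ndarray:
    n = int(round(SEGMENT_DURATION_S * rec.sampling_rate_hz))
    start = int(round(SEGMENT_START_S * rec.sampling_rate_hz))
    if rec.samples.size < start + n:
        raise ValueError(
            f"recording too short: need {SEGMENT_DURATION_S * 1e3:.0f} ms from "
            f"{SEGMENT_START_S * 1e3:.0f} ms after onset"
        )
    return rec.samples[start : start + n]


def _bin_rms_spectrum(rec: EarCanalRecording) -> tuple[np.ndarray, np.ndarray]:
    """(bin center frequencies Hz, per-bin RMS pressure Pa) of the 80 ms segment."""
    seg = _analysis_segment(rec)
    n = seg.size
    spec = rfft(seg)
    rms = np.abs(spec) * (np.sqrt(2.0) / n)
    rms[0] = np.abs(spec[0]) / n
    if n % 2 == 0:
        rms[-1] = np.abs(spec[-1]) / n
    freqs = np.arange(rms.size) * (rec.sampling_rate_hz / n)
    return freqs, rms


def _power_to_db_spl(power_pa2: float) -> float:
    if power_pa2 <= 0:
        return SENTINEL_FLOOR_DB
    return float(max(10.0 * np.log10(power_pa2 / P_REF_PA**2), SENTINEL_FLOOR_DB))


def band_amplitude(
    rec: EarCanalRecording, f_center_hz: float, bandwidth_hz: float = ANALYSIS_BANDWIDTH_HZ
) -> float:
    """Level (dB SPL re 20 µPa RMS) in a half-open band [f-bw/2, f+bw/2) by bin center.

    Powers are summed over the bins whose centers fall in the band; with the
    80 ms rectangular segment the bin spacing is exactly 12.5 Hz, so the default
    band is a single bin. Zero in-band power reports the -150 dB SPL sentinel.
    """
    nyquist = rec.sampling_rate_hz / 2.0
    if f_center_hz + bandwidth_hz / 2.0 >= nyquist:
        raise ValueError("band extends to or beyond Nyquist")
    freqs, rms = _bin_rms_spectrum(rec)
    lo, hi = f_center_hz - bandwidth_hz / 2.0, f_center_hz + bandwidth_hz / 2.0
    mask = (freqs >= lo) & (freqs < hi)
    return _power_to_db_spl(float(np.sum(rms[mask] ** 2)))


def noise_floor(
    rec: EarCanalRecording,
    dp_frequency_hz: float,
    bandwidth_hz: float = ANALYSIS_BANDWIDTH_HZ,
    average_in_db: bool = False,
) -> float:
    """Noise floor (dB SPL) from two 25 Hz bands flanking the distortion product.

    Bins with centers in [dp-50, dp-25) and [dp+25, dp+50) Hz are averaged in
    the power domain (conventional for a "mean noise floor"; set
    ``average_in_db`` for a dB-domain mean) and scaled to the measurement
    bandwidth. The +/-25 Hz guard keeps the emission itself out of the estimate.
    """
    nyquist = rec.sampling_rate_hz / 2.0
    if dp_frequency_hz + 50.0 >= nyquist or dp_frequency_hz - 50.0 <= 0:
        raise ValueError("noise-floor bands clipped by the spectrum edge")
    freqs, rms = _bin_rms_spectrum(rec)
    lower = (freqs >= dp_frequency_hz - 50.0) & (freqs < dp_frequency_hz - 25.0)
    upper = (freqs >= dp_frequency_hz + 25.0) & (freqs < dp_frequency_hz + 50.0)
    powers = rms[lower | upper] ** 2
    if powers.size == 0:
        raise ValueError("no spectral bins fall in the noise-floor bands")
    bin_hz = freqs[1] - freqs[0]
    scale = bandwidth_hz / bin_hz
    if average_in_db:
        with np.errstate(divide="ignore"):
            db = 10.0 * np.log10(powers * scale / P_REF_PA**2)
        db = np.where(np.isfinite(db), db, SENTINEL_FLOOR_DB)
        return float(max(np.mean(db), SENTINEL_FLOOR_DB))
    return _power_to_db_spl(float(np.mean(powers)) * scale)


def analyze_sweep(recordings: Sequence[EarCanalRecording]) -> DPOAESweepResult:
    """Extract F1/F2/2f1-f2 levels and the noise floor at one L2 step.

    Multiple repetitions are averaged in the time domain before the FFT
    (synchronized sweep averaging); all must share stimulus and sampling rate.
    """
    if not recordings:
        raise ValueError("no recordings supplied")
    first = recordings[0]
    stim = first.stimulus
    if len(recordings) > 1:
        if any(
            r.stimulus != stim or r.sampling_rate_hz != first.sampling_rate_hz
            for r in recordings[1:]
        ):
            raise ValueError("repetitions must share stimulus and sampling rate")
        avg = np.mean([r.samples for r in recordings], axis=0)
        first = EarCanalRecording(avg, first.sampling_rate_hz, stim)
    return DPOAESweepResult(
        l2_db_spl=stim.l2_db_spl,
        f1_amp_db=band_amplitude(first, stim.f1_hz),
        f2_amp_db=band_amplitude(first, stim.f2_hz),
        dp_amp_db=band_amplitude(first, stim.dp_frequency_hz),
        noise_floor_db=noise_floor(first, stim.dp_frequency_hz),
    )


def build_dpoae_io(
    recordings_per_l2: Mapping[float, Sequence[EarCanalRecording]]
    | Iterable[EarCanalRecording],
) -> DPOAEIOFunction:
    """Assemble an I/O function from ear-canal recordings across L2 steps."""
    if isinstance(recordings_per_l2, Mapping):
        groups = {l2: list(recs) for l2, recs in recordings_per_l2.items()}
    else:
        groups = {}
        for rec in recordings_per_l2:
            groups.setdefault(rec.stimulus.l2_db_spl, []).append(rec)
    if len(groups) < 2:
        raise ValueError("an I/O function needs at least two L2 levels")
    points = tuple(analyze_sweep(recs) for _, recs in sorted(groups.items()))
    f2_values = {recs[0].stimulus.f2_hz for recs in groups.values()}
    if len(f2_values) != 1:
        raise ValueError("recordings span multiple f2 frequencies")
    return DPOAEIOFunction(points=points, f2_hz=f2_values.pop())


def mean_noise_floor(io: DPOAEIOFunction) -> float:
    """Mean noise floor of a sweep (dB SPL), averaged across levels in power.

    Pooling the flanking-band estimates of every L2 step (40 bins for the
    default 10-level grid) gives the stable per-curve floor that the threshold
    criterion is defined against.
    """
    powers = [10.0 ** (p.noise_floor_db / 10.0) for p in io.points]
    return _power_to_db_spl(float(np.mean(powers)) * P_REF_PA**2)


def dpoae_threshold(
    io: DPOAEIOFunction, margin_db: float = DEFAULT_MARGIN_DB
) -> ThresholdResult:
    """L2 level above which the emission clears the mean noise floor by >= margin.

    The criterion floor is the curve's mean noise floor (power-domain mean of
    the per-level flanking-band estimates); the suffix rule matches the ABR
    thresholds: every tested level strictly above the threshold must satisfy
    the criterion, and the threshold is "not reached" if the top level fails.
    """
    if not io.points:
        raise ValueError("empty I/O function")
    floor_db = mean_noise_floor(io)
    exceeds = [p.dp_amp_db >= floor_db + margin_db for p in io.points]
    thr = suffix_threshold(io.l2_levels, exceeds)
    return ThresholdResult(
        threshold_db=thr,
        criterion=margin_db,
        rule={
            "kind": "suffix",
            "comparison": ">= mean noise floor + margin",
            "mean_noise_floor_db": floor_db,
        },
    )
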