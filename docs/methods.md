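# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of otokit's analyses and of the synthetic generators that
drive them.

## ABR analysis

**Windows.** The early analysis window is 1.5 ms long and starts at the onset
of wave I; the late window is the contiguous 6.0 ms that follows. Windows are
half-open `[start, end)` on sample timestamps and the onset is quantized to
the sample grid, so no sample is counted twice and window arithmetic is exact.

**Wave-I onset.** Operational onset detection: the most prominent positive
peak within ±1 ms of a template latency is located (it must exceed twice the
baseline SD, estimated from the first 1 ms of the trace); walking back from
that peak, the onset is the latest sample that is non-positive, a local
minimum, or below 10% of the peak height. If no qualifying peak exists the
template latency itself is used. When a level series is analysed, the
detected peak latency at each level seeds the template for the next lower
level, so the windows drift rightward as intensity falls, tracking the
latency-intensity function.

**RMS and thresholds.** RMS is computed without baseline subtraction: averaged
responses are assumed zero-mean after the 300–3,000 Hz acquisition bandpass
(an optional zero-phase 4th-order Butterworth `bandpass` is provided for raw
field data; synthetic averages are generated in-band). The threshold is
grid-valued: the lowest tested level such that the RMS amplitude exceeds
0.1 µV at *every* strictly higher tested level (a suffix rule — robust to
non-monotonic near-threshold points), with "not reached" when the top level
fails. No interpolation between grid levels is performed, matching how such
thresholds are conventionally reported.

**Peak latencies.** Up to six positive local maxima between the early-window
start and the late-window end, with a minimum separation of 0.5 ms, labelled
I–VI ordinally by time (not by morphology). Peaks must exceed the larger of
twice the baseline SD and 5% of the largest peak in the region, which rejects
noise ripples without losing genuine late peaks. Note that when adjacent
biphasic peaks overlap, the composite waveform's local maxima are legitimately
displaced from the generator's nominal peak times (by ~0.03 ms with the
default widths); the detector is validated against the oversampled composite
waveform, and against nominal peak times when widths are chosen so the peaks
do not overlap.

**Equal-sensation-level comparison.** Each series is measured at the grid
level nearest to (own threshold + SL). Because thresholds are grid-valued,
the compensation applied is the measured threshold difference rounded to the
grid; when the true attenuation is not a multiple of the grid step, a
residual effective-level mismatch of up to half a grid step remains and
appears as a small residual latency difference (slope x mismatch). For
grid-multiple attenuations the comparison is exact.

## DPOAE analysis

**Stimulus.** f1 = f2/1.2 and L1 = L2 + 10 dB. Both primaries are rounded to
the 12.5 Hz spectral bin grid ("frequency locking", as acquisition rigs do),
which keeps each tone — and the distortion product 2f1−f2 — exactly on one
FFT bin; the realized f2/f1 ratio stays within ~0.1% of 1.2. Without this,
rectangular-window scalloping (up to ~3.9 dB) and primary leakage (tens of dB
above the emission) would corrupt the 12.5 Hz band measurement.

**Spectrum.** The analysis segment is 80 ms starting 5 ms after stimulus
onset, rectangular-windowed with no zero-padding — the unique choice for
which the stated 12.5 Hz measurement band is exactly one FFT bin of the 90 ms
stimulus. Band amplitudes sum bin powers over `[f − 6.25, f + 6.25)` Hz by
bin center and convert to dB SPL re 20 µPa RMS. Zero-power bands report a
finite sentinel (−150 dB SPL) so downstream arithmetic never sees −inf.

**Noise floor.** Per level, the mean bin power over `[dp−50, dp−25)` and
`[dp+25, dp+50)` Hz (power-domain averaging, the conventional reading of a
"mean" of a power spectrum; a dB-domain mean is available behind a flag),
scaled to the 12.5 Hz measurement bandwidth. The ±25 Hz guard bands keep the
emission itself out of the estimate. The *threshold criterion* uses the
power-domain mean of these per-level estimates across the whole sweep
(`mean_noise_floor`, 40 bins on the default 10-level grid): a single per-curve
floor is both what "exceeded the mean noise floor" describes and far more
stable than any per-level 4-bin estimate, whose F(2,8)-like fluctuations would
otherwise let sub-threshold levels pass spuriously with probability ~0.1–0.3.

**Threshold.** Same suffix rule as the ABR: the lowest L2 above which the
emission is at least 5 dB above the mean noise floor at every higher tested
level. The suffix reading mirrors the ABR threshold wording and makes the two
estimators directly comparable.

**Sweep averaging.** When repetitions of one stimulus are supplied they are
averaged in the time domain before the FFT, assuming exact synchronization.

## Synthetic generators

The generators emulate the study conditions the analyses assume; their
defaults are fixed and are not fitted to any measured data.

**ABR.** Levels 10–90 dB SPL in 10 dB steps; 800 sweeps averaged at ≥70 dB
SPL and 1,500 below (the averaged-noise SD is noise_sd/√n); sampling rate
24,414 Hz (≥ 8x the 3 kHz bandpass edge); 12.8 ms epochs. Six peaks with
latency intercepts 1.5/2.4/3.2/4.1/5.0/5.9 ms at 90 dB SPL effective level
and slope 0.02 ms/dB — plausible placeholder values for a mouse, stated as
defaults only. The peak kernel is a Gaussian first derivative: zero-mean,
biphasic, unit positive peak exactly at the nominal latency, trough of −1 two
widths later, giving a closed-form peak-to-peak of exactly 2 for tests.
Amplitudes grow sigmoidally (floor 0, per-peak ceilings 1.5·{1, 0.65, 0.55,
0.60, 0.45, 0.25} µV, common slope 8 dB) with per-frequency midpoints chosen
so control wave-I thresholds land near values typical for a normal-hearing
mouse (high at 4 kHz, best near 16 kHz) and 4 kHz responses are smaller.
Conductive loss is a pure frequency-flat input attenuation: the waveform at
level L with attenuation a is bit-identical to the attenuation-free waveform
at L − a, which is what makes threshold-shift and latency analyses exact
parameter-recovery problems.

**DPOAE.** 90 ms stimuli at 192 kHz; L2 from 25 to 70 dB SPL in 5 dB steps.
The emission level is `dp_gain(L2 − a)`: the growth function maps the
effective stimulus at the cochlea to the emission level measured in the
canal, so any reverse-path transmission loss is part of that mapping rather
than a second subtraction — with this convention the simulated threshold
elevation equals a exactly for any monotone growth function, matching the
observation that emission-threshold elevations track the conductive ABR
shift. The default growth is 2 dB/dB below a 45 dB knee and 0.4 dB/dB above
(within the physiological 0.5–2 dB/dB range near threshold); the steep
segment makes consecutive 5 dB grid steps span 10 dB of emission change, so
the criterion crossing is decisive against single-bin measurement noise, and
places the control threshold near 30 dB SPL — two steps above the grid floor,
so threshold jitter is not censored by the grid bottom. The noise floor
parameter is the expected per-12.5 Hz-bin level of the additive white noise
(default −15 dB SPL, a typical post-averaging floor); primaries are rendered
at their nominal canal levels, and only sub-Nyquist components are rendered.

**Cytocochleograms.** Cells on a regular lattice at the stated densities
(defaults 38 OHC and 12 IHC per 100 µm, three OHC rows pooled), each removed
independently with a dropout probability; ground-truth positions are returned
alongside the binned counts.

**CT phantoms.** Background density plus axis-aligned boxes/ellipsoids
(membership by voxel center; later shapes win on overlap) and optional
Gaussian voxel noise, at 5 µm isotropic resolution.

**Seeding.** Every generator derives per-record child streams from the master
seed keyed by (seed, frequency, level) or the analogue, so adding levels,
subjects or replicates never perturbs existing records, and identical
parameters always reproduce identical data.

## Cytocochleogram analysis

Positions are binned from the apex into half-open 100 µm bins (a cell exactly
at the measured end belongs to the last bin); counts are conserved by
construction. Summary densities average complete bins over an apical extent
that must be a whole number of bins — the pipeline uses 5,200 µm, the largest
whole-bin extent shared by both groups (a 5,250 µm extent is not
bin-aligned); densities are insensitive to the half bin. The projected count
difference is density x length-difference / 100, rounded to a whole cell: it
exposes the projection formula, and its output depends entirely on the
near-base density supplied.

## Morphometry

Segmentation keeps voxels with density ≥ 350 mg HA/cm³ and removes
26-connected components smaller than 5,000 voxels (625,000 µm³ at 5 µm
resolution); the cutoff is inclusive, so a voxel exactly at 350 is bone. The
Feret diameter is the maximum Euclidean distance between voxel centers,
convex-hull accelerated, accurate to within one voxel diagonal of the
physical extent (a single voxel reports 0). Cavity measurements operate on
user-supplied landmark rims because such measurement lines are placed
manually on registered cross-sections; image registration and rendering are
out of scope. Widths are shortest across-rim distances; the cavity depth
marches a ray from the opening-line midpoint through the mid-line midpoint in
half-voxel steps until it hits bone, erroring if it leaves the volume.
Distances are computed in µm and reported in mm (2 decimals in tables).
Left-sided volumes can be mirrored with an axis flip.

## Statistics

`rm_anova` implements the classical balanced two-way mixed design (one
between-subjects factor x one within-subjects factor, complete grids per
subject, group sizes may differ): the between effect is tested against
subjects-within-groups, the within effect and interaction against the
subject-by-level residual. The sums of squares satisfy the exact additive
decomposition (asserted to 1e-8 in tests, cross-checked against pingouin's
mixed ANOVA). Sums of squares below 1e-12 of the total are snapped to zero so
exactly-null effects report F = 0 rather than floating-point dust ratios.
Sphericity corrections are not applied (uncorrected degrees of freedom are
the reporting convention this mirrors). The Bonferroni family is the set of
per-level pairwise group comparisons within one analysis, with adjusted
p = min(1, m·p). `two_sample_t` is Student's pooled test by default with
Welch behind a flag; zero-variance degenerate inputs report t = 0, p = 1 for
equal means and an infinite-t sentinel with p = 0 otherwise.

## What passing tests show — and what they do not

The generators share the analyses' structural assumptions: peaks are smooth
and biphasic, noise is Gaussian and stationary, the conductive loss is a
pure frequency-flat attenuation, emissions sit exactly on FFT bins, and cell
lattices are regular. Passing the recovery tests therefore demonstrates that
the measurement chain is internally consistent and recovers known ground
truth under those assumptions; it does not show robustness to real-world
departures — myogenic artifacts, non-stationary noise, mixed
conductive/sensorineural losses, DPOAE fine structure, irregular hair-cell
spacing, or beam-hardening in CT. Automatic landmark detection for cavity
measurements is deliberately not attempted.

## Numerical conventions and degenerate inputs

Half-open intervals everywhere (windows, spectral bands, spatial bins);
boundary samples/bins/cells belong to the upper interval, except that a cell
at the measured cochlear end joins the last bin. Grid-valued thresholds use
the suffix rule and never interpolate. Zero-power spectral quantities report
the −150 dB SPL sentinel. All-zero or non-finite recordings raise a
no-signal error; flat traces yield an empty latency set with a warning flag
rather than an error. Problem sizes in the test suite and acceptance script
(10 subjects/group, 20 DPOAE noise replicates, ≤64³ oracle volumes) were
chosen so the full suite completes in well under a minute while leaving the
recovery statistics decisively inside their bands.
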