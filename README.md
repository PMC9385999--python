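# otokit

A Python toolkit for auditory phenotyping of rodent models, aimed at
hearing-research labs that need a reproducible, scriptable version of the
standard measurement chain used to diagnose **conductive hearing loss**:

* **ABR** (auditory brainstem response): dual-RMS-window amplitude analysis
  anchored at wave I, input/output functions, grid-valued thresholds, per-peak
  latencies, and equal-sensation-level comparisons;
* **DPOAE** (distortion-product otoacoustic emissions): FFT band extraction of
  F1, F2 and 2f1−f2, flanking-band noise floors, I/O functions and thresholds;
* **cytocochleograms**: hair-cell counts per 100 µm along the unrolled cochlea,
  summary densities and cochlear-length statistics;
* **microCT morphometry**: calibrated-density bone segmentation with a
  minimum-component-size filter, Feret diameter, and landmark-based
  tympanic-cavity / oval-window measurements;
* **group statistics**: two-way mixed-design ANOVA with Bonferroni post-hocs
  and two-sample t-tests.

Every analysis is paired with a synthetic-data generator (`otokit.synth`)
whose ground truth is a frequency-flat conductive attenuation *a*, so the
whole chain can be validated end to end without animal data. The hallmark
signature — a flat threshold shift, a parallel rightward I/O shift, and
latency delays that vanish at equal sensation level — falls out of the
analysis of the simulated cohorts.

## The model in brief

An averaged ABR waveform is modelled as six biphasic peaks,

  V(t) = Σₖ Aₖ(L_eff) · g((t − τₖ(L_eff)) / wₖ) + noise,  L_eff = L − a,

with g a Gaussian first derivative (unit positive peak, closed-form
peak-to-peak of 2), sigmoidal amplitude growth Aₖ and linear latency-intensity
functions τₖ = τₖ⁰ + s·(90 − L_eff). The early RMS window covers
[onset, onset + 1.5 ms] from the wave-I onset, the late window the following
6.0 ms; the threshold is the lowest tested level above which the window RMS
exceeds 0.1 µV at every higher level. DPOAEs use primaries with f2/f1 = 1.2
and L1 = L2 + 10 dB; the emission at 2f1−f2 grows compressively with the
effective stimulus, and the threshold is the L2 above which the emission
clears the mean noise floor by ≥ 5 dB. Because the conductive loss enters
only through L_eff, the attenuation is recoverable from either modality.

## Worked example

`python examples/abr_analysis.py` simulates a control ear and an ear with a
15 dB conductive attenuation at 8 kHz and prints:

```
wave-I RMS amplitude vs level (µV), control ear:
     10 dB SPL   0.0022
     ...
     40 dB SPL   0.0860
     50 dB SPL   0.2424
     ...
     90 dB SPL   0.8853
control threshold: 40.0 dB SPL (RMS > 0.1 µV rule)
conductive-loss threshold: 50.0 dB SPL
-> threshold shift 10 dB for a 15 dB attenuation (grid-quantized to the 10 dB level steps)

per-peak latencies at 30 dB sensation level (control at 70, loss at 80 dB SPL):
 wave  reference_latency_ms  comparison_latency_ms  difference_ms
    1              1.884165               2.007045        0.12288
    ...
```

The wave-I RMS amplitude grows sigmoidally with level and crosses the 0.1 µV
criterion between 40 and 50 dB SPL, so the grid-valued threshold is 40 dB SPL;
the attenuated ear crosses one step later. At matched sensation level the
latency difference collapses from the ~0.3 ms seen at equal absolute level to
~0.1 ms — the residual is exactly the 5 dB mismatch between the true 15 dB
attenuation and its 10 dB grid-quantized compensation times the 0.02 ms/dB
latency slope.

The other scripts in `examples/` cover DPOAE extraction, cytocochleograms,
morphometry, group statistics, and the end-to-end pipeline
(`otokit.pipeline.run_pipeline`), which writes a CSV/JSON report bundle.

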