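"""ABR analysis of a simulated conductive hearing loss.

Simulates one normal-hearing ear and one ear with a 15 dB frequency-flat
conductive attenuation, then runs the dual-RMS-window analysis: wave-I
input/output functions, grid-valued thresholds, and peak latencies compared
at equal absolute level and at equal sensation level.
"""

from otokit import abr, synth

control = synth.simulate_abr_series(synth.default_abr_params(8000.0, seed=1))
loss = synth.simulate_abr_series(
    synth.default_abr_params(8000.0, attenuation_db=15.0, seed=1), genotype="DS"
)

io_c = abr.build_io(control, window_kind="early")
io_l = abr.build_io(loss, window_kind="early")
thr_c = abr.estimate_threshold(io_c)
thr_l = abr.estimate_threshold(io_l)

print("wave-I RMS amplitude vs level (µV), control ear:")
for level, amp in io_c.points:
    print(f"  {level:5.0f} dB SPL   {amp:.4f}")
print(f"control threshold: {thr_c.threshold_db} dB SPL (RMS > {thr_c.criterion} µV rule)")
print(f"conductive-loss threshold: {thr_l.threshold_db} dB SPL")
print(
    f"-> threshold shift {thr_l.threshold_db - thr_c.threshold_db:.0f} dB for a "
    "15 dB attenuation (grid-quantized to the 10 dB level steps)"
)

cmp = abr.equal_sl_latency_compare(control, thr_c, loss, thr_l, sl_db=30.0)
print(
    f"\nper-peak latencies at 30 dB sensation level "
    f"(control at {cmp.reference_level_db:.0f}, loss at {cmp.comparison_level_db:.0f} dB SPL):"
)
print(cmp.table.to_string(index=False))
print(
    "-> at matched sensation level the latency delay largely disappears; the\n"
    "   residual difference reflects the grid-quantized threshold compensation."
)
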