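"""Cytocochleogram densities and the cochlear-length contrast.

Hair-cell positions are binned per 100 µm from the apex; group densities are
compared over a shared apical extent and the extra cells implied by a longer
cochlea are projected from the near-base density.
"""

from otokit import cochleogram, synth

long_ear = synth.simulate_cochleogram(
    synth.CochleogramSimParams(length_um=5888.0, ohc_density_per_100um=38.3,
                               ihc_density_per_100um=11.9, seed=1)
)
short_ear = synth.simulate_cochleogram(
    synth.CochleogramSimParams(length_um=5250.0, ohc_density_per_100um=37.8,
                               ihc_density_per_100um=11.7, seed=2)
)

for name, sim in (("long (control-like)", long_ear), ("short", short_ear)):
    g = sim.cochleogram
    print(
        f"{name:20s} length {g.total_length_um:6.0f} µm, "
        f"OHC {cochleogram.mean_density(g, 5200.0, 'ohc'):.1f}/100 µm, "
        f"IHC {cochleogram.mean_density(g, 5200.0, 'ihc'):.1f}/100 µm over the apical 5.2 mm"
    )

diff = cochleogram.length_difference([5888.0] * 4, [5250.0] * 6)
print(f"\nmean length difference: {diff.mean_difference_um:.0f} µm")
extra_ohc = cochleogram.projected_count_difference(38.3, diff.mean_difference_um)
print(
    f"projected extra OHCs in the longer cochlea at 38.3 cells/100 µm: {extra_ohc}\n"
    "-> equal densities but unequal lengths imply more total hair cells in the longer ear."
)
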