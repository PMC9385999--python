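"""Cytocochleogram analysis: hair-cell densities along the unrolled cochlea.

Cell positions are expressed as distance from the apex in µm and binned into
100 µm intervals. Outer-hair-cell (OHC) counts pool the three rows. Summary
densities are taken over a shared apical extent so that cochleae of different
lengths can be compared; total-count differences between groups are projected
from the density near the base times the length difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from otokit import stats as _stats

__all__ = [
    "Cytocochleogram",
    "LengthComparison",
    "bin_cells",
    "mean_density",
    "length_difference",
    "projected_count_difference",
]

DEFAULT_BIN_UM = 100.0


@dataclass(frozen=True)
class Cytocochleogram:
    """Per-bin OHC/IHC counts from the apex; the last bin may be partial."""

    bin_edges_um: np.ndarray
    ohc_counts: np.ndarray
    ihc_counts: np.ndarray
    total_length_um: float
    subject_id: str = "unknown"
    genotype: str = "unknown"

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_um, dtype=float)
        ohc = np.asarray(self.ohc_counts, dtype=int)
        ihc = np.asarray(self.ihc_counts, dtype=int)
        if edges.size != ohc.size + 1 or ohc.size != ihc.size:
            raise ValueError("bin_edges must have one more entry than the count arrays")
        if edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("bins must be contiguous from 0")
        if np.any(ohc < 0) or np.any(ihc < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "bin_edges_um", edges)
        object.__setattr__(self, "ohc_counts", ohc)
        object.__setattr__(self, "ihc_counts", ihc)

    @property
    def bin_um(self) -> float:
        return float(self.bin_edges_um[1] - self.bin_edges_um[0])

    @property
    def last_bin_partial(self) -> bool:
        return self.total_length_um < self.bin_edges_um[-1]

    @property
    def n_bins(self) -> int:
        return int(self.ohc_counts.size)


@dataclass(frozen=True)
class LengthComparison:
    """Group difference in cochlear length with its two-sample t-test."""

    mean_difference_um: float
    t: float
    df: float
    p: float


def _bin_positions(positions: Sequence[float], total_length_um: float, bin_um: float) -> np.ndarray:
    pos = np.asarray(positions, dtype=float)
    if pos.size and (pos.min() < 0 or pos.max() > total_length_um):
        raise ValueError("cell positions must lie within [0, total_length]")
    n_bins = max(1, int(np.ceil(total_length_um / bin_um)))
    idx = np.floor(pos / bin_um).astype(int)
    # a cell exactly at the measured end of the cochlea belongs to the last bin
    idx = np.minimum(idx, n_bins - 1)
    return np.bincount(idx, minlength=n_bins)


def bin_cells(
    ohc_positions_um: Sequence[float],
    ihc_positions_um: Sequence[float],
    total_length_um: float,
    bin_um: float = DEFAULT_BIN_UM,
    subject_id: str = "unknown",
    genotype: str = "unknown",
) -> Cytocochleogram:
    """Bin cell positions into half-open [k*bin, (k+1)*bin) intervals from the apex.

    Counts are conserved: the bin totals equal the numbers of input positions.
    """
    if total_length_um <= 0:
        raise ValueError("total_length_um must be positive")
    ohc = _bin_positions(ohc_positions_um, total_length_um, bin_um)
    ihc = _bin_positions(ihc_positions_um, total_length_um, bin_um)
    edges = np.arange(ohc.size + 1) * bin_um
    return Cytocochleogram(
        bin_edges_um=edges,
        ohc_counts=ohc,
        ihc_counts=ihc,
        total_length_um=float(total_length_um),
        subject_id=subject_id,
        genotype=genotype,
    )


def mean_density(
    c: Cytocochleogram, extent_um: float, cell_type: str = "ohc"
) -> float:
    """Mean cells per bin over the apical [0, extent) µm (complete bins only)."""
    if cell_type not in ("ohc", "ihc"):
        raise ValueError("cell_type must be 'ohc' or 'ihc'")
    if extent_um > c.total_length_um:
        raise ValueError("extent exceeds the measured cochlear length")
    n = extent_um / c.bin_um
    if abs(n - round(n)) > 1e-9:
        raise ValueError("extent must be a whole number of bins")
    n = int(round(n))
    counts = c.ohc_counts if cell_type == "ohc" else c.ihc_counts
    return float(np.mean(counts[:n]))


def length_difference(
    group_a_lengths_um: Sequence[float], group_b_lengths_um: Sequence[float]
) -> LengthComparison:
    """Mean cochlear-length difference (a - b) with a pooled two-sample t-test.

    With fewer than two animals in a group the difference is still reported but
    the test statistics are NaN.
    """
    a = np.asarray(group_a_lengths_um, dtype=float)
    b = np.asarray(group_b_lengths_um, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    diff = float(a.mean() - b.mean())
    if a.size < 2 or b.size < 2:
        return LengthComparison(diff, float("nan"), float("nan"), float("nan"))
    res = _stats.two_sample_t(a, b)
    return LengthComparison(diff, res.t, res.df, res.p)


def projected_count_difference(
    density_near_base_per_bin: float, delta_length_um: float, bin_um: float = DEFAULT_BIN_UM
) -> int:
    """Extra cells implied by a length difference at the near-base density.

    ``density * delta_length / bin`` rounded to the nearest whole cell.
    """
    if density_near_base_per_bin < 0 or delta_length_um < 0:
        raise ValueError("inputs must be non-negative")
    return int(round(density_near_base_per_bin * delta_length_um / bin_um))
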