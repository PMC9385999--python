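"""MicroCT temporal-bone morphometry.

Calibrated-density volumes (mg hydroxyapatite / cm³, isotropic voxels) are
segmented with a fixed density cutoff (default 350 mg HA/cm³) and a
minimum-component-size filter (default 5,000 voxels = 625,000 µm³ at 5 µm
resolution, 26-connected). Bone length is the Feret (maximum caliper)
diameter of the retained mask. Tympanic-cavity and oval-window measurements
operate on user-supplied landmarks, mirroring measurements placed manually on
registered cross-sections; registration itself is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

from otokit._common import DegenerateLandmarkError, MissingLandmarkError

__all__ = [
    "DensityVolume",
    "BoneMask",
    "CavityMeasurements",
    "segment_bone",
    "feret_diameter",
    "cavity_measurements",
    "percent_of_reference",
    "mirror_volume",
]

DEFAULT_CUTOFF_MG_HA_CM3 = 350.0
DEFAULT_MIN_VOXELS = 5000


@dataclass(frozen=True)
class DensityVolume:
    """Calibrated 3D density image (mg HA/cm³) with isotropic voxel size (µm)."""

    voxels: np.ndarray
    voxel_size_um: float
    orientation: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("densities must be finite")
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")
        object.__setattr__(self, "voxels", v)


@dataclass(frozen=True)
class BoneMask:
    """Binary bone mask with 26-connected component labels, aligned to its source."""

    mask: np.ndarray
    labels: np.ndarray
    voxel_size_um: float

    @property
    def component_sizes(self) -> dict[int, int]:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}

    @property
    def n_components(self) -> int:
        return len(self.component_sizes)


@dataclass(frozen=True)
class CavityMeasurements:
    """Middle-ear cavity dimensions in mm (internal computation in µm)."""

    opening_width_mm: float
    mid_width_mm: float
    depth_mm: float
    oval_window_width_mm: float
    bone_length_mm: float | None = None

    def as_dict(self, decimals: int = 2) -> dict[str, float | None]:
        """Values rounded for reporting (2 decimals matches conventional tables)."""
        out = {}
        for name in (
            "opening_width_mm",
            "mid_width_mm",
            "depth_mm",
            "oval_window_width_mm",
            "bone_length_mm",
        ):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, decimals)
        return out


def mirror_volume(v: DensityVolume, axis: int = 0) -> DensityVolume:
    """Axis flip used to mirror left-sided temporal bones onto right-sided ones."""
    return DensityVolume(np.flip(v.voxels, axis=axis).copy(), v.voxel_size_um, v.orientation)


def segment_bone(
    v: DensityVolume,
    cutoff: float = DEFAULT_CUTOFF_MG_HA_CM3,
    min_voxels: int = DEFAULT_MIN_VOXELS,
) -> BoneMask:
    """Threshold at >= cutoff and drop 26-connected components below min_voxels.

    An empty mask is a valid result (no bone above cutoff, or nothing survives
    the size filter).
    """
    binary = v.voxels >= cutoff
    labels = measure.label(binary, connectivity=3)
    if labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_voxels)
        small = small[small > 0]
        if small.size:
            labels[np.isin(labels, small)] = 0
        # relabel survivors consecutively
        labels = measure.label(labels > 0, connectivity=3)
    mask = labels > 0
    return BoneMask(mask=mask, labels=labels, voxel_size_um=v.voxel_size_um)


def feret_diameter(m: BoneMask) -> float:
    """Feret (maximum caliper) diameter of the retained mask, in µm.

    Computed as the maximum Euclidean distance between voxel centers,
    convex-hull accelerated; accurate to within one voxel diagonal of the
    physical extent. A single-voxel mask has diameter 0.
    """
    coords = np.argwhere(m.mask).astype(float) * m.voxel_size_um
    if coords.shape[0] == 0:
        raise ValueError("empty mask has no Feret diameter")
    if coords.shape[0] == 1:
        return 0.0
    pts = coords
    if coords.shape[0] > 4:
        try:
            hull = ConvexHull(coords)
            pts = coords[hull.vertices]
        except QhullError:
            pass  # degenerate (coplanar/collinear) sets fall back to all points
    return float(np.max(pdist(pts)))


def _as_points(obj: Sequence[Sequence[float]], name: str) -> np.ndarray:
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] == 0:
        raise DegenerateLandmarkError(f"landmark set '{name}' must be a non-empty Nx3 array")
    return pts


def _shortest_across(landmarks: Mapping, key: str) -> tuple[float, np.ndarray]:
    """Shortest distance between the two rims of a named landmark pair.

    Returns the distance (µm) and the midpoint of the realizing segment.
    """
    if key not in landmarks:
        raise MissingLandmarkError(f"landmark set '{key}' missing")
    side_a, side_b = landmarks[key]
    a = _as_points(side_a, f"{key}/a")
    b = _as_points(side_b, f"{key}/b")
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    i, j = np.unravel_index(np.argmin(d), d.shape)
    return float(d[i, j]), (a[i] + b[j]) / 2.0


def _ray_depth(m: BoneMask, origin_um: np.ndarray, through_um: np.ndarray) -> float:
    """Length of the ray from origin through a second point to the far cavity wall.

    The ray is marched in half-voxel steps starting past the ``through`` point
    until it hits bone; marching out of the volume without a hit is an error.
    """
    direction = through_um - origin_um
    norm = float(np.linalg.norm(direction))
    if norm < 1e-9:
        raise DegenerateLandmarkError("opening and mid-cavity midpoints coincide")
    direction = direction / norm
    step = m.voxel_size_um / 2.0
    t = norm + step
    shape = np.asarray(m.mask.shape)
    while True:
        p = origin_um + t * direction
        idx = np.round(p / m.voxel_size_um).astype(int)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise ValueError("depth ray left the volume without reaching the cavity wall")
        if m.mask[tuple(idx)]:
            return t
        t += step


def cavity_measurements(
    m: BoneMask,
    landmarks: Mapping[str, tuple[Sequence[Sequence[float]], Sequence[Sequence[float]]]],
    include_bone_length: bool = False,
) -> CavityMeasurements:
    """Tympanic-cavity and oval-window dimensions from labelled landmark rims.

    ``landmarks`` maps each of ``"opening"`` (tympanic annulus), ``"mid"``
    (mid-cavity ridge) and ``"oval_window"`` to a pair of point lists (µm, one
    per rim side). Widths are the shortest across-rim distances; the cavity
    depth runs from the midpoint of the opening line through the midpoint of
    the mid-cavity line to the far cavity wall of the bone mask along that ray.
    """
    opening_um, opening_mid = _shortest_across(landmarks, "opening")
    mid_um, mid_mid = _shortest_across(landmarks, "mid")
    oval_um, _ = _shortest_across(landmarks, "oval_window")
    depth_um = _ray_depth(m, opening_mid, mid_mid)
    bone_length_mm = feret_diameter(m) / 1000.0 if include_bone_length else None
    return CavityMeasurements(
        opening_width_mm=opening_um / 1000.0,
        mid_width_mm=mid_um / 1000.0,
        depth_mm=depth_um / 1000.0,
        oval_window_width_mm=oval_um / 1000.0,
        bone_length_mm=bone_length_mm,
    )


def percent_of_reference(value: float, reference: float) -> float:
    """Normalise a group mean to a reference group mean, in percent."""
    if reference <= 0:
        raise ValueError("reference mean must be positive")
    return 100.0 * value / reference
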