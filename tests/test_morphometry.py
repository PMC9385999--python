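"""Segmentation, Feret diameter, and landmark-based cavity geometry."""

from collections import Counter, deque

import numpy as np
import pytest

from otokit import morphometry, synth
from otokit._common import DegenerateLandmarkError, MissingLandmarkError


def flood_fill_components(binary):
    """Brute-force 26-connected component sizes (independent oracle)."""
    binary = np.asarray(binary, dtype=bool)
    seen = np.zeros_like(binary)
    sizes = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(binary & ~seen)):
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        size = 0
        while queue:
            x, y, z = queue.popleft()
            size += 1
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= c < s for c, s in zip(p, binary.shape)):
                    if binary[p] and not seen[p]:
                        seen[p] = True
                        queue.append(p)
        sizes.append(size)
    return sizes


class TestSegmentation:
    def test_cutoff_is_inclusive_at_boundary(self):
        vol = morphometry.DensityVolume(np.full((8, 8, 8), 349.9), 5.0)
        assert morphometry.segment_bone(vol, min_voxels=1).n_components == 0
        vol2 = morphometry.DensityVolume(np.full((8, 8, 8), 350.0), 5.0)
        assert morphometry.segment_bone(vol2, min_voxels=1).n_components == 1

    def test_min_size_rule_drops_small_component(self):
        spec = synth.PhantomSpec(
            shapes=(
                synth.Box((0.0, 0.0, 0.0), (100.0, 100.0, 75.0), 800.0),
                synth.Box((0.0, 0.0, 200.0), (100.0, 100.0, 50.0), 800.0),
            ),
            dims_voxels=(30, 30, 60),
        )
        mask = morphometry.segment_bone(synth.simulate_phantom(spec))
        assert mask.n_components == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_components_match_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        binary = rng.random((20, 20, 20)) < 0.18
        vol = morphometry.DensityVolume(np.where(binary, 600.0, 0.0), 5.0)
        for min_voxels in (1, 4):
            mask = morphometry.segment_bone(vol, min_voxels=min_voxels)
            expected = [s for s in flood_fill_components(binary) if s >= min_voxels]
            assert Counter(mask.component_sizes.values()) == Counter(expected)

    def test_segmentation_idempotent(self):
        rng = np.random.default_rng(3)
        vol = morphometry.DensityVolume(
            np.where(rng.random((16, 16, 16)) < 0.3, 700.0, 0.0), 5.0
        )
        mask1 = morphometry.segment_bone(vol, min_voxels=10)
        as_density = morphometry.DensityVolume(
            np.where(mask1.mask, 1000.0, 0.0), 5.0
        )
        mask2 = morphometry.segment_bone(as_density, min_voxels=10)
        np.testing.assert_array_equal(mask1.mask, mask2.mask)


class TestFeret:
    def test_box_diagonal_within_voxel_diagonal(self):
        spec = synth.PhantomSpec(
            shapes=(synth.Box((0.0, 0.0, 0.0), (300.0, 400.0, 1200.0), 800.0),),
            dims_voxels=(60, 80, 240),
        )
        mask = morphometry.segment_bone(synth.simulate_phantom(spec))
        assert morphometry.feret_diameter(mask) == pytest.approx(
            1300.0, abs=np.sqrt(3) * 5.0
        )

    def test_single_voxel_zero(self):
        labels = np.zeros((5, 5, 5), dtype=int)
        labels[2, 2, 2] = 1
        mask = morphometry.BoneMask(labels > 0, labels, 5.0)
        assert morphometry.feret_diameter(mask) == 0.0

    def test_two_voxels_center_distance(self):
        labels = np.zeros((10, 10, 10), dtype=int)
        labels[0, 0, 0] = labels[3, 4, 0] = 1
        mask = morphometry.BoneMask(labels > 0, labels, 5.0)
        assert morphometry.feret_diameter(mask) == pytest.approx(25.0)

    def test_empty_mask_rejected(self):
        labels = np.zeros((4, 4, 4), dtype=int)
        with pytest.raises(ValueError):
            morphometry.feret_diameter(morphometry.BoneMask(labels > 0, labels, 5.0))

    def test_feret_bounds_any_sampled_pair(self):
        rng = np.random.default_rng(5)
        binary = rng.random((15, 15, 15)) < 0.3
        binary[0, 0, 0] = True
        mask = morphometry.BoneMask(binary, binary.astype(int), 5.0)
        d = morphometry.feret_diameter(mask)
        coords = np.argwhere(binary) * 5.0
        for _ in range(50):
            i, j = rng.integers(0, coords.shape[0], 2)
            assert d >= np.linalg.norm(coords[i] - coords[j]) - 1e-9


def cylindrical_cavity(radius_um=200.0, wall_um=50.0, depth_um=600.0, voxel=10.0):
    """Hollow cylinder along z, open at z=0, closed by a far wall."""
    nr = int((radius_um + wall_um) * 2 / voxel) + 4
    nz = int((depth_um + wall_um) / voxel) + 4
    x = (np.arange(nr) - nr // 2) * voxel
    grid_x, grid_y = np.meshgrid(x, x, indexing="ij")
    r = np.sqrt(grid_x**2 + grid_y**2)
    vol = np.zeros((nr, nr, nz))
    ring = (r >= radius_um) & (r < radius_um + wall_um)
    for iz in range(nz):
        z = iz * voxel
        if z < depth_um:
            vol[:, :, iz][ring] = 800.0
        else:
            vol[:, :, iz][r < radius_um + wall_um] = 800.0  # far wall
    return morphometry.DensityVolume(vol, voxel), nr // 2 * voxel


class TestCavityMeasurements:
    def test_cylinder_opening_width_is_diameter(self):
        vol, c = cylindrical_cavity()
        mask = morphometry.segment_bone(vol, min_voxels=1)
        landmarks = {
            "opening": ([[c - 200.0, c, 0.0]], [[c + 200.0, c, 0.0]]),
            "mid": ([[c - 200.0, c, 300.0]], [[c + 200.0, c, 300.0]]),
            "oval_window": ([[c, c - 100.0, 0.0]], [[c, c + 100.0, 0.0]]),
        }
        m = morphometry.cavity_measurements(mask, landmarks)
        assert m.opening_width_mm == pytest.approx(0.4, abs=vol.voxel_size_um / 1000.0)
        assert m.mid_width_mm == pytest.approx(0.4, abs=vol.voxel_size_um / 1000.0)
        assert m.oval_window_width_mm == pytest.approx(0.2, abs=0.01)

    def test_depth_follows_constructed_ray(self):
        """The depth ray starts at the opening midpoint, passes the mid-cavity
        midpoint, and ends on the far wall at z = 600 µm."""
        vol, c = cylindrical_cavity()
        mask = morphometry.segment_bone(vol, min_voxels=1)
        landmarks = {
            "opening": ([[c - 200.0, c, 0.0]], [[c + 200.0, c, 0.0]]),
            "mid": ([[c - 200.0, c, 300.0]], [[c + 200.0, c, 300.0]]),
            "oval_window": ([[c, c - 100.0, 0.0]], [[c, c + 100.0, 0.0]]),
        }
        m = morphometry.cavity_measurements(mask, landmarks)
        assert m.depth_mm == pytest.approx(0.6, abs=2 * vol.voxel_size_um / 1000.0)

    def test_coincident_midpoints_rejected(self):
        vol, c = cylindrical_cavity()
        mask = morphometry.segment_bone(vol, min_voxels=1)
        landmarks = {
            "opening": ([[c - 200.0, c, 0.0]], [[c + 200.0, c, 0.0]]),
            "mid": ([[c - 200.0, c, 0.0]], [[c + 200.0, c, 0.0]]),
            "oval_window": ([[c, c - 100.0, 0.0]], [[c, c + 100.0, 0.0]]),
        }
        with pytest.raises(DegenerateLandmarkError):
            morphometry.cavity_measurements(mask, landmarks)

    def test_missing_landmark_named(self):
        vol, c = cylindrical_cavity()
        mask = morphometry.segment_bone(vol, min_voxels=1)
        with pytest.raises(MissingLandmarkError, match="oval_window"):
            morphometry.cavity_measurements(
                mask,
                {
                    "opening": ([[0.0, 0.0, 0.0]], [[1.0, 0.0, 0.0]]),
                    "mid": ([[0.0, 0.0, 5.0]], [[1.0, 0.0, 5.0]]),
                },
            )


class TestPercentOfReference:
    @pytest.mark.parametrize(
        "ds,wt,expected", [(1.0, 1.0, 100.0), (0.5, 1.0, 50.0), (6.22, 6.91, 90.0)]
    )
    def test_ratio(self, ds, wt, expected):
        assert morphometry.percent_of_reference(ds, wt) == pytest.approx(expected, abs=0.05)

    def test_mirroring_is_involutive(self):
        rng = np.random.default_rng(1)
        vol = morphometry.DensityVolume(rng.random((4, 5, 6)), 5.0)
        twice = morphometry.mirror_volume(morphometry.mirror_volume(vol))
        np.testing.assert_array_equal(twice.voxels, vol.voxels)
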