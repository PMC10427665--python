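import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import neobrainage as nb
from neobrainage.morphometrics import _surface_mask

from conftest import make_random_volume


def brute_force_surface_count(vox, region_id):
    """Literal triple-loop neighbor check; out-of-bounds = background."""
    nx, ny, nz = vox.shape
    count = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if vox[x, y, z] != region_id:
                    continue
                for dx, dy, dz in [(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                                   (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    a, b, c = x + dx, y + dy, z + dz
                    neighbor = (
                        vox[a, b, c]
                        if 0 <= a < nx and 0 <= b < ny and 0 <= c < nz
                        else 0
                    )
                    if neighbor != region_id:
                        count += 1
                        break
    return count


class TestRegionVolumes:
    def test_two_regions(self):
        vox = np.zeros((10, 10, 1), dtype=int)
        vox.ravel()[:30] = 1
        vox.ravel()[30:100] = 2
        assert nb.region_volumes(nb.LabelVolume(voxels=vox)) == {1: 30, 2: 70}

    def test_all_background(self):
        assert nb.region_volumes(nb.LabelVolume(voxels=np.zeros((4, 4, 4), int))) == {}

    def test_matches_brute_force_tally(self, random_volume):
        counts = nb.region_volumes(random_volume)
        tally = {}
        for v in random_volume.voxels.ravel():
            if v != 0:
                tally[int(v)] = tally.get(int(v), 0) + 1
        assert counts == tally


class TestSurfaceVoxelCount:
    def test_isolated_voxel(self):
        vox = np.zeros((5, 5, 5), int)
        vox[2, 2, 2] = 1
        assert nb.surface_voxel_count(nb.LabelVolume(voxels=vox), 1) == 1

    def test_centered_3cube(self):
        vox = np.zeros((7, 7, 7), int)
        vox[2:5, 2:5, 2:5] = 1
        assert nb.surface_voxel_count(nb.LabelVolume(voxels=vox), 1) == 26

    def test_rod(self):
        vox = np.zeros((3, 3, 5), int)
        vox[1, 1, 1:4] = 1
        assert nb.surface_voxel_count(nb.LabelVolume(voxels=vox), 1) == 3

    def test_5cube(self):
        vox = np.zeros((9, 9, 9), int)
        vox[2:7, 2:7, 2:7] = 1
        assert nb.surface_voxel_count(nb.LabelVolume(voxels=vox), 1) == 98

    def test_background_rejected(self, random_volume):
        with pytest.raises(ValueError, match="background"):
            nb.surface_voxel_count(random_volume, 0)

    def test_border_voxels_are_surface(self):
        vox = np.ones((4, 4, 4), int)  # fills the whole grid
        assert nb.surface_voxel_count(nb.LabelVolume(voxels=vox), 1) == 64 - 8

    @pytest.mark.parametrize("seed", range(5))
    def test_oracle_equivalence(self, seed):
        vol = make_random_volume(shape=(12, 12, 12), n_labels=5, seed=seed)
        for rid in vol.region_ids:
            assert nb.surface_voxel_count(vol, rid) == brute_force_surface_count(
                vol.voxels, rid
            )

    @pytest.mark.parametrize("edges", [(3, 3, 3), (3, 4, 5), (4, 4, 4), (5, 3, 6)])
    def test_analytic_cuboid(self, edges):
        a, b, c = edges
        vox = np.zeros((a + 4, b + 4, c + 4), int)
        vox[2 : 2 + a, 2 : 2 + b, 2 : 2 + c] = 7
        expected = a * b * c - (a - 2) * (b - 2) * (c - 2)
        assert nb.surface_voxel_count(nb.LabelVolume(voxels=vox), 7) == expected

    def test_internal_boundary_counts(self):
        # two touching half-blocks: every voxel touches either background
        # or the other label, so all are surface voxels
        vox = np.zeros((4, 4, 4), int)
        vox[:2] = 1
        vox[2:] = 2
        vol = nb.LabelVolume(voxels=vox)
        assert nb.surface_voxel_count(vol, 1) == 32
        assert nb.surface_voxel_count(vol, 2) == 32

    def test_connectivity_option_monotone(self):
        vol = make_random_volume(shape=(10, 10, 10), n_labels=3, seed=3)
        for rid in vol.region_ids:
            c6 = nb.surface_voxel_count(vol, rid, connectivity=6)
            c18 = nb.surface_voxel_count(vol, rid, connectivity=18)
            c26 = nb.surface_voxel_count(vol, rid, connectivity=26)
            assert c6 <= c18 <= c26

    def test_invalid_connectivity(self, random_volume):
        with pytest.raises(ValueError, match="connectivity"):
            nb.surface_voxel_count(random_volume, 1, connectivity=10)


class TestRatios:
    def test_relational_volume_examples(self):
        assert nb.relational_volume({1: 30, 2: 70}, 1) == pytest.approx(0.30)
        assert nb.relational_volume({5: 123}, 5) == 1.0
        eq = {r: 10 for r in range(1, 88)}
        assert nb.relational_volume(eq, 42) == pytest.approx(1 / 87)

    def test_relational_volume_empty_rejected(self):
        with pytest.raises(ValueError, match="no structures"):
            nb.relational_volume({}, 1)

    def test_svr_examples(self):
        assert nb.surface_to_volume_ratio(1, 1) == 1.0
        assert nb.surface_to_volume_ratio(26, 27) == pytest.approx(26 / 27)
        assert nb.surface_to_volume_ratio(0, 0) == 0.0

    def test_svr_geometry_violation(self):
        with pytest.raises(ValueError, match="exceed"):
            nb.surface_to_volume_ratio(5, 4)


class TestExtractFeatures:
    def test_missing_region_flagged(self):
        vox = np.zeros((6, 6, 6), int)
        vox[1:3, 1:3, 1:3] = 1
        morphs = nb.extract_features(nb.LabelVolume(voxels=vox), expected_regions=[1, 2])
        assert len(morphs) == 2
        assert morphs[1].absent and morphs[1].voxel_count == 0
        assert morphs[1].rv == 0.0 and morphs[1].svr == 0.0
        assert not morphs[0].absent and morphs[0].rv == 1.0

    def test_deterministic(self, random_volume):
        regions = random_volume.region_ids
        assert nb.extract_features(random_volume, regions) == nb.extract_features(
            random_volume, regions
        )

    def test_rv_denominator_uses_all_present_labels(self):
        # label 3 is present but not expected; it still counts in the total
        vox = np.zeros((6, 6, 1), int)
        vox.ravel()[:10] = 1
        vox.ravel()[10:30] = 3
        morphs = nb.extract_features(nb.LabelVolume(voxels=vox), expected_regions=[1])
        assert morphs[0].rv == pytest.approx(10 / 30)

    def test_empty_expected_rejected(self, random_volume):
        with pytest.raises(ValueError, match="non-empty"):
            nb.extract_features(random_volume, expected_regions=[])

    @given(
        vox=arrays(
            dtype=np.int8,
            shape=st.tuples(*[st.integers(2, 8)] * 3),
            elements=st.integers(0, 4),
        )
    )
    @settings(max_examples=60, deadline=None)
    def test_rv_sums_to_one_and_svr_bounded(self, vox):
        vol = nb.LabelVolume(voxels=vox.astype(int))
        if not vol.region_ids:
            return
        morphs = nb.extract_features(vol, expected_regions=vol.region_ids)
        assert abs(sum(m.rv for m in morphs) - 1.0) < 1e-12
        for m in morphs:
            assert 0.0 <= m.svr <= 1.0
            assert m.surface_voxel_count <= m.voxel_count

    def test_affine_metadata_invariance(self):
        vox = make_random_volume(shape=(10, 10, 10), seed=5).voxels
        a = nb.LabelVolume(voxels=vox, spacing=(1, 1, 1))
        b = nb.LabelVolume(voxels=vox, spacing=(0.5, 0.7, 2.0), affine=np.diag([2, 3, 4, 1.0]))
        assert nb.extract_features(a, a.region_ids) == nb.extract_features(b, b.region_ids)

    def test_sphere_svr_decreases_with_radius(self):
        svrs = []
        for radius in range(3, 11):
            n = 2 * radius + 3
            g = np.indices((n, n, n)) - n // 2
            vox = ((g**2).sum(axis=0) <= radius**2).astype(int)
            vol = nb.LabelVolume(voxels=vox)
            s = nb.surface_voxel_count(vol, 1)
            v = nb.region_volumes(vol)[1]
            svrs.append(s / v)
        assert all(a > b for a, b in zip(svrs, svrs[1:]))

    def test_protrusion_never_decreases_surface_numerator(self):
        vox = np.zeros((9, 9, 9), int)
        vox[3:6, 3:6, 3:6] = 1
        base = nb.surface_voxel_count(nb.LabelVolume(voxels=vox), 1)
        vox2 = vox.copy()
        vox2[6, 4, 4] = 1  # protrusion voxel on a face
        after = nb.surface_voxel_count(nb.LabelVolume(voxels=vox2), 1)
        assert after >= base


class TestDice:
    def _vol(self, vox):
        return nb.LabelVolume(voxels=vox)

    def test_identical(self, random_volume):
        for rid in random_volume.region_ids:
            assert nb.dice_coefficient(random_volume, random_volume, rid) == 1.0

    def test_disjoint(self):
        a = np.zeros((4, 4, 4), int)
        b = np.zeros((4, 4, 4), int)
        a[0, 0, 0] = 1
        b[3, 3, 3] = 1
        assert nb.dice_coefficient(self._vol(a), self._vol(b), 1) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), int)
        b = np.zeros((4, 4, 4), int)
        a[0, 0, :4] = 1
        b[0, 0, 2:4] = 1
        b[0, 1, :2] = 1
        assert nb.dice_coefficient(self._vol(a), self._vol(b), 1) == pytest.approx(0.5)

    def test_both_empty_is_one(self):
        z = self._vol(np.zeros((3, 3, 3), int))
        assert nb.dice_coefficient(z, z, 9) == 1.0

    def test_shape_mismatch(self):
        a = self._vol(np.zeros((3, 3, 3), int))
        b = self._vol(np.zeros((4, 4, 4), int))
        with pytest.raises(ValueError, match="shape"):
            nb.dice_coefficient(a, b, 1)

    def test_mean_dice(self):
        a = np.zeros((4, 4, 4), int)
        b = np.zeros((4, 4, 4), int)
        a[0] = 1
        b[0] = 1  # region 1 perfect
        a[1] = 2
        b[2] = 2  # region 2 disjoint
        assert nb.mean_dice(self._vol(a), self._vol(b), [1, 2]) == pytest.approx(0.5)
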