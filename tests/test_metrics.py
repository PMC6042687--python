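import numpy as np
import pytest

import _oracles as oracle
from ctquant import (
    compacity,
    in_contact,
    intermixing_fraction,
    min_edge_distance,
    overlap_fraction,
    shell_distribution,
    shell_partition,
    volume_fraction,
)


def _cuboid(shape, sl):
    m = np.zeros(shape, bool)
    m[sl] = True
    return m


def _ball(radius, pad=1):
    n = 2 * (radius + pad) + 1
    c = radius + pad
    zz, yy, xx = np.ogrid[:n, :n, :n]
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


class TestVolumeFraction:
    def test_simple_ratio(self):
        nuc = _cuboid((10, 10, 10), np.s_[:, :, :])
        ct = _cuboid((10, 10, 10), np.s_[0, :, :])
        assert volume_fraction(ct, nuc) == pytest.approx(0.10)

    def test_mask_equal_to_nucleus_is_one(self):
        nuc = _cuboid((5, 5, 5), np.s_[1:4, 1:4, 1:4])
        assert volume_fraction(nuc, nuc) == 1.0

    def test_empty_mask_is_zero_and_empty_nucleus_errors(self):
        nuc = _cuboid((5, 5, 5), np.s_[1:4, 1:4, 1:4])
        assert volume_fraction(np.zeros_like(nuc), nuc) == 0.0
        with pytest.raises(ValueError, match="nucleus"):
            volume_fraction(nuc, np.zeros_like(nuc))


class TestOverlapFraction:
    def test_identical_masks(self):
        m = _cuboid((8, 8, 8), np.s_[2:6, 2:6, 2:6])
        assert overlap_fraction(m, m) == 1.0

    def test_disjoint_masks(self):
        a = _cuboid((8, 8, 8), np.s_[0:2, :, :])
        b = _cuboid((8, 8, 8), np.s_[5:8, :, :])
        assert overlap_fraction(a, b) == 0.0

    def test_asymmetric_normalization(self):
        # ref 10x10x10 fully inside a 20x10x10 A
        shape = (10, 10, 20)
        a = _cuboid(shape, np.s_[:, :, 0:20])
        ref = _cuboid(shape, np.s_[:, :, 0:10])
        assert overlap_fraction(a, ref) == 1.0
        assert overlap_fraction(ref, a) == 0.5

    def test_empty_reference_is_an_error(self):
        a = _cuboid((4, 4, 4), np.s_[:2])
        with pytest.raises(ValueError, match="empty reference"):
            overlap_fraction(a, np.zeros_like(a))


class TestIntermixing:
    def test_disjoint_others(self):
        t = _cuboid((8, 8, 8), np.s_[0:2, :, :])
        o = _cuboid((8, 8, 8), np.s_[5:8, :, :])
        assert intermixing_fraction(t, [o]) == 0.0

    def test_target_inside_union(self):
        t = _cuboid((8, 8, 8), np.s_[2:4, 2:4, 2:4])
        o1 = _cuboid((8, 8, 8), np.s_[2:3, :, :])
        o2 = _cuboid((8, 8, 8), np.s_[3:5, :, :])
        assert intermixing_fraction(t, [o1, o2]) == 1.0

    def test_half_covered_target(self):
        t = _cuboid((4, 4, 8), np.s_[:, :, 0:8])
        o = _cuboid((4, 4, 8), np.s_[:, :, 0:4])
        assert intermixing_fraction(t, [o]) == 0.5


class TestContact:
    def test_overlapping_masks_touch(self):
        a = _cuboid((6, 6, 6), np.s_[0:3, :, :])
        b = _cuboid((6, 6, 6), np.s_[2:5, :, :])
        assert in_contact(a, b)

    def test_two_voxel_gap_is_no_contact(self):
        a = _cuboid((8, 8, 8), np.s_[0:2, :, :])
        b = _cuboid((8, 8, 8), np.s_[4:6, :, :])
        assert not in_contact(a, b)

    def test_face_adjacent_cuboids_touch(self):
        a = _cuboid((8, 8, 8), np.s_[0:3, :, :])
        b = _cuboid((8, 8, 8), np.s_[3:6, :, :])
        assert in_contact(a, b)
        assert not in_contact(a, b, adjacency=False)


class TestMinEdgeDistance:
    def test_intersecting_masks(self):
        a = _cuboid((6, 6, 6), np.s_[0:4, :, :])
        b = _cuboid((6, 6, 6), np.s_[3:6, :, :])
        assert min_edge_distance(a, b, (1, 1, 1)) == 0.0

    def test_isotropic_axis_distance(self):
        shape = (3, 3, 12)
        a = _cuboid(shape, np.s_[1, 1, 0:1])
        b = _cuboid(shape, np.s_[1, 1, 10:11])
        assert min_edge_distance(a, b, (1, 1, 1)) == pytest.approx(10.0)

    def test_anisotropic_spacing_scales_z(self):
        shape = (5, 3, 3)
        a = _cuboid(shape, np.s_[0:1, 1, 1])
        b = _cuboid(shape, np.s_[2:3, 1, 1])
        assert min_edge_distance(a, b, (3, 1, 1)) == pytest.approx(6.0)

    def test_empty_mask_errors(self):
        a = _cuboid((4, 4, 4), np.s_[:2])
        with pytest.raises(ValueError, match="non-empty"):
            min_edge_distance(a, np.zeros_like(a), (1, 1, 1))


class TestCompacity:
    def test_ball_limit(self):
        assert compacity(_ball(20), (1, 1, 1)) >= 0.95

    def test_cube_value(self):
        cube = _cuboid((32, 32, 32), np.s_[1:31, 1:31, 1:31])
        assert compacity(cube, (1, 1, 1)) == pytest.approx((np.pi / 6) ** (1 / 3), abs=0.03)

    def test_box_elongation_ordering(self):
        cube = _cuboid((18, 18, 18), np.s_[1:17, 1:17, 1:17])
        box4 = _cuboid((10, 10, 34), np.s_[1:9, 1:9, 1:33])
        box16 = _cuboid((6, 6, 66), np.s_[1:5, 1:5, 1:65])
        psis = [compacity(m, (1, 1, 1)) for m in (cube, box4, box16)]
        assert psis[0] > psis[1] > psis[2]

    def test_thin_rod_far_below_cube(self):
        rod = _cuboid((3, 3, 102), np.s_[1, 1, 1:101])
        psi = compacity(rod, (1, 1, 1))
        assert psi < 0.45  # marching-cubes surface of a 1-voxel rod (diamond section)

    def test_anisotropic_spacing_respected(self):
        # a voxel-space box that is a physical cube under 2:1:1 spacing;
        # z staircase smoothing is limited at high anisotropy, so the
        # tolerance is looser than in the isotropic case
        box = _cuboid((12, 22, 22), np.s_[1:11, 1:21, 1:21])
        psi = compacity(box, (2, 1, 1))
        assert psi == pytest.approx((np.pi / 6) ** (1 / 3), abs=0.06)

    def test_tiny_mask_warns_but_returns(self):
        m = _cuboid((4, 4, 4), np.s_[1:2, 1:3, 1:3])
        with pytest.warns(UserWarning, match="unreliable"):
            psi = compacity(m, (1, 1, 1))
        assert 0 < psi <= 1


class TestShells:
    def test_equal_count_partition_on_sphere(self):
        nuc = _ball(15)
        labels = shell_partition(nuc, 5, (1, 1, 1))
        counts = np.bincount(labels[nuc])[1:]
        total = nuc.sum()
        assert len(counts) == 5
        assert counts.max() - counts.min() <= 1
        assert abs(counts - total / 5).max() <= total % 5 + 1

    def test_center_voxel_in_innermost_shell(self):
        nuc = _ball(10)
        labels = shell_partition(nuc, 5, (1, 1, 1))
        center = tuple(np.array(nuc.shape) // 2)
        assert labels[center] == 5

    def test_shell_ordering_by_distance(self):
        from scipy import ndimage as ndi

        nuc = _ball(12)
        labels = shell_partition(nuc, 5, (1, 1, 1))
        dist = ndi.distance_transform_edt(nuc)
        assert dist[labels == 1].max() <= dist[labels == 5].min()

    def test_distribution_of_whole_nucleus_is_uniform(self):
        nuc = _ball(10)
        labels = shell_partition(nuc, 5, (1, 1, 1))
        fr = shell_distribution(nuc, labels)
        assert fr.sum() == pytest.approx(1.0)
        assert np.allclose(fr, 0.2, atol=2 / nuc.sum() + 1e-9)

    def test_central_blob_in_shell_five(self):
        nuc = _ball(12)
        labels = shell_partition(nuc, 5, (1, 1, 1))
        c = np.array(nuc.shape) // 2
        blob = np.zeros_like(nuc)
        blob[c[0] - 1 : c[0] + 2, c[1] - 1 : c[1] + 2, c[2] - 1 : c[2] + 2] = True
        fr = shell_distribution(blob, labels)
        assert fr[4] == 1.0

    def test_random_mask_fractions_sum_to_one(self, rng):
        nuc = _ball(9)
        labels = shell_partition(nuc, 5, (1, 1, 1))
        m = nuc & (rng.random(nuc.shape) > 0.5)
        assert shell_distribution(m, labels).sum() == pytest.approx(1.0, abs=1e-12)


class TestOracleEquivalence:
    """Exact agreement with brute-force voxel enumeration on random masks."""

    def test_overlap_intermixing_contact_distance(self, rng):
        for _ in range(30):
            shape = tuple(int(rng.integers(6, 20)) for _ in range(3))
            a = oracle.random_blob_mask(rng, shape)
            b = oracle.random_blob_mask(rng, shape)
            if b.any() and a.any():
                assert overlap_fraction(a, b) == oracle.overlap_bruteforce(a, b)
                assert intermixing_fraction(a, [b]) == oracle.intermixing_bruteforce(a, [b])
                assert in_contact(a, b) == oracle.contact_bruteforce(a, b)
                spacing = tuple(rng.uniform(0.1, 2.0, 3))
                assert min_edge_distance(a, b, spacing) == pytest.approx(
                    oracle.min_edge_distance_bruteforce(a, b, spacing), rel=1e-9
                )


class TestInvariants:
    def test_reciprocity_of_overlap(self, rng):
        for _ in range(10):
            shape = (10, 14, 14)
            a = oracle.random_blob_mask(rng, shape)
            b = oracle.random_blob_mask(rng, shape)
            if not (a.any() and b.any()):
                continue
            va, vb = a.sum(), b.sum()
            assert overlap_fraction(a, b) * vb == pytest.approx(
                overlap_fraction(b, a) * va, rel=1e-9
            )

    def test_contact_consistency_with_distance(self, rng):
        for _ in range(10):
            shape = (10, 12, 12)
            a = oracle.random_blob_mask(rng, shape)
            b = oracle.random_blob_mask(rng, shape)
            if not (a.any() and b.any()):
                continue
            d = min_edge_distance(a, b, (1, 1, 1))
            assert (d == 0.0) == bool(np.any(a & b))
            if np.any(a & b):
                assert in_contact(a, b)

    def test_dilation_never_decreases_overlap(self, rng):
        from scipy import ndimage as ndi

        for _ in range(8):
            shape = (10, 12, 12)
            a = oracle.random_blob_mask(rng, shape)
            b = oracle.random_blob_mask(rng, shape)
            if not (a.any() and b.any()):
                continue
            bigger = ndi.binary_dilation(a, np.ones((3, 3, 3), bool))
            assert overlap_fraction(bigger, b) >= overlap_fraction(a, b)

    def test_metrics_scale_consistently_with_spacing(self, rng):
        """Doubling the voxel spacing scales volumes 8x and distances 2x."""
        shape = (8, 10, 10)
        a = oracle.random_blob_mask(rng, shape)
        b = oracle.random_blob_mask(rng, shape)
        b &= ~a  # force disjoint so the distance is non-zero
        if not b.any():
            b[7, 9, 9] = True
        s1, s2 = (0.5, 0.2, 0.2), (1.0, 0.4, 0.4)
        assert a.sum() * np.prod(s2) == pytest.approx(8 * a.sum() * np.prod(s1))
        assert min_edge_distance(a, b, s2) == pytest.approx(
            2 * min_edge_distance(a, b, s1), rel=1e-9
        )
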