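import numpy as np
import pytest

import _oracles as oracle
from ctquant import (
    ImageStack,
    auto_thresholds,
    cell_rng,
    detect_spots_3d,
    hysteresis_segment,
    pairing_state,
    render_microscopy,
    segment_cell,
    segment_nucleus,
    simulate_cell,
)
from ctquant.segment import NoNucleusError, TerritoryComponents
from ctquant.stackio import BinaryMask


def _stack(volume, spacing=(1.0, 1.0, 1.0), name="ch"):
    return ImageStack(np.asarray(volume)[None], spacing, [name])


def _full_nucleus(shape, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.ones(shape, bool), spacing)


class TestNucleusSegmentation:
    def test_recovers_synthetic_nucleus(self, fast_params):
        truth = simulate_cell(fast_params, rng=cell_rng(1, 0))
        stack = render_microscopy(truth, fast_params, rng=cell_rng(1, 1))
        mask, info = segment_nucleus(stack, "dna")
        inter = np.count_nonzero(mask.voxels & truth.nucleus_mask)
        union = np.count_nonzero(mask.voxels | truth.nucleus_mask)
        assert inter / union >= 0.90
        assert info["border_touching"] is False

    def test_interior_hole_is_filled(self):
        vol = np.zeros((12, 12, 12), np.uint16)
        vol[2:10, 2:10, 2:10] = 200
        vol[5, 5, 5] = 0
        mask, _ = segment_nucleus(_stack(vol, name="dna"), "dna")
        assert mask.voxels[5, 5, 5]

    def test_only_largest_blob_retained(self):
        vol = np.zeros((12, 20, 20), np.uint16)
        vol[2:10, 2:12, 2:12] = 200  # large
        vol[2:5, 15:18, 15:18] = 200  # small
        mask, _ = segment_nucleus(_stack(vol, name="dna"), "dna")
        assert mask.voxels[5, 5, 5]
        assert not mask.voxels[3, 16, 16]

    def test_border_touching_flagged(self):
        vol = np.zeros((8, 8, 8), np.uint16)
        vol[0:4, 2:6, 2:6] = 200
        _, info = segment_nucleus(_stack(vol, name="dna"), "dna")
        assert info["border_touching"] is True

    def test_constant_channel_raises(self):
        with pytest.raises(NoNucleusError):
            segment_nucleus(_stack(np.zeros((4, 4, 4), np.uint16), name="dna"), "dna")


class TestHysteresis:
    def test_ring_included_when_low_reaches_it(self):
        vol = np.full((12, 12, 12), 10, np.uint16)
        vol[4:8, 4:8, 4:8] = 120  # ring
        vol[5:7, 5:7, 5:7] = 200  # core
        comps = hysteresis_segment(_stack(vol), "ch", low=100, high=150,
                                   nucleus=_full_nucleus(vol.shape))
        assert comps.n_components == 1
        assert comps.labels[4, 4, 4] == 1  # ring voxel grown from the core

    def test_ring_excluded_when_low_above_it(self):
        vol = np.full((12, 12, 12), 10, np.uint16)
        vol[4:8, 4:8, 4:8] = 120
        vol[5:7, 5:7, 5:7] = 200
        comps = hysteresis_segment(_stack(vol), "ch", low=150, high=150,
                                   nucleus=_full_nucleus(vol.shape))
        assert comps.labels[4, 4, 4] == 0
        assert comps.labels[5, 5, 5] == 1

    def test_everything_below_low_gives_zero_components(self):
        vol = np.full((8, 8, 8), 10, np.uint16)
        comps = hysteresis_segment(_stack(vol), "ch", low=100, high=150,
                                   nucleus=_full_nucleus(vol.shape))
        assert comps.n_components == 0

    def test_low_above_high_rejected(self):
        vol = np.zeros((4, 4, 4), np.uint16)
        with pytest.raises(ValueError, match="exceeds"):
            hysteresis_segment(_stack(vol), "ch", low=200, high=100)

    def test_min_volume_discards_specks(self):
        vol = np.full((10, 16, 16), 0, np.uint16)
        vol[2:8, 2:10, 2:10] = 200
        vol[2, 13, 13] = 200  # single-voxel speck
        comps = hysteresis_segment(_stack(vol), "ch", low=100, high=150,
                                   min_volume=2.0, nucleus=_full_nucleus(vol.shape))
        assert comps.n_components == 1

    def test_labels_sorted_by_descending_volume(self):
        vol = np.zeros((8, 20, 20), np.uint16)
        vol[2:6, 2:6, 2:6] = 200
        vol[2:7, 10:17, 10:17] = 200
        comps = hysteresis_segment(_stack(vol), "ch", low=100, high=150,
                                   nucleus=_full_nucleus(vol.shape))
        assert comps.n_components == 2
        assert comps.volumes[0] >= comps.volumes[1]
        assert comps.labels[3, 12, 12] == 1  # the bigger blob got label 1

    def test_matches_bruteforce_flood_fill(self, rng):
        """Exact equivalence with an independent frontier-growth flood fill."""
        for _ in range(25):
            shape = tuple(int(rng.integers(5, 16)) for _ in range(3))
            img = rng.integers(0, 255, size=shape).astype(np.uint16)
            low, high = sorted(rng.integers(40, 220, size=2).tolist())
            comps = hysteresis_segment(_stack(img), "ch", low=low, high=high,
                                       nucleus=_full_nucleus(shape))
            np.testing.assert_array_equal(
                comps.labels > 0, oracle.hysteresis_bruteforce(img, low, high)
            )

    def test_lowering_low_never_shrinks_components(self, rng):
        for _ in range(10):
            shape = (8, 10, 10)
            img = rng.integers(0, 255, size=shape).astype(np.uint16)
            nuc = _full_nucleus(shape)
            hi = 180
            m1 = hysteresis_segment(_stack(img), "ch", low=120, high=hi, nucleus=nuc).labels > 0
            m2 = hysteresis_segment(_stack(img), "ch", low=60, high=hi, nucleus=nuc).labels > 0
            assert np.all(m2 >= m1)  # superset property


class TestAutoThresholds:
    def test_bimodal_threshold_between_modes(self, rng):
        vol = np.where(rng.random((10, 10, 10)) < 0.5, 10, 200).astype(np.uint16)
        stack = _stack(vol)
        low, high = auto_thresholds(stack, "ch", _full_nucleus(vol.shape))
        assert 10 < high < 200
        assert low == high / 2
        # exhaustive between-class-variance oracle agrees on the gap
        t_oracle = oracle.otsu_bruteforce(vol.ravel())
        assert 10 < t_oracle < 200

    def test_override_returned_verbatim(self, rng):
        vol = rng.integers(0, 255, (6, 6, 6)).astype(np.uint16)
        low, high = auto_thresholds(_stack(vol), "ch", _full_nucleus(vol.shape),
                                    override=(40, 90))
        assert (low, high) == (40.0, 90.0)

    def test_constant_channel_is_an_error(self):
        vol = np.full((6, 6, 6), 7, np.uint16)
        with pytest.raises(ValueError, match="constant"):
            auto_thresholds(_stack(vol), "ch", _full_nucleus(vol.shape))


class TestSpotDetection:
    @staticmethod
    def _render_spots(centers, shape=(24, 48, 48), sigma=1.5, amp=500.0):
        zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        img = np.zeros(shape)
        for c in centers:
            img += amp * np.exp(
                -((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) / (2 * sigma**2)
            )
        return img + 10

    def test_recovers_rendered_spots(self):
        centers = [(6, 8, 8), (6, 8, 40), (6, 40, 8), (18, 40, 40), (18, 8, 24), (12, 24, 24)]
        img = self._render_spots(centers)
        stack = _stack(img)
        foci = detect_spots_3d(stack, "ch", (1.5, 1.5, 1.5), peak_threshold=5.0)
        assert len(foci) == len(centers)
        for c in centers:
            d = np.linalg.norm(foci - np.asarray(c, float), axis=1)
            assert d.min() <= np.sqrt(3)  # within one voxel

    def test_blank_image_has_no_foci(self):
        stack = _stack(np.full((10, 10, 10), 10.0))
        assert len(detect_spots_3d(stack, "ch", 1.5, peak_threshold=1.0)) == 0

    def test_separation_resolves_or_merges_pairs(self):
        sigma = 1.5
        far = self._render_spots([(12, 24, 12), (12, 24, 12 + int(5 * sigma))], sigma=sigma)
        near = self._render_spots([(12, 24, 23), (12, 24, 24)], sigma=sigma)
        assert len(detect_spots_3d(_stack(far), "ch", sigma, peak_threshold=5.0)) == 2
        assert len(detect_spots_3d(_stack(near), "ch", sigma, peak_threshold=5.0)) == 1


class TestPairingState:
    def _comps(self, volumes):
        labels = np.zeros((2, 4, max(len(volumes), 1)), np.int32)
        return TerritoryComponents(labels=labels, volumes=np.asarray(volumes, float),
                                   voxel_spacing=(1, 1, 1))

    def test_single_blob_paired(self):
        assert pairing_state(self._comps([100.0])) == (1, True)

    def test_two_equal_blobs_unpaired(self):
        assert pairing_state(self._comps([100.0, 100.0])) == (2, False)

    def test_speck_below_relative_min_ignored(self):
        assert pairing_state(self._comps([1000.0, 20.0])) == (1, True)

    def test_no_components_is_missing(self):
        n, paired = pairing_state(self._comps([]))
        assert n == 0 and paired is None


class TestSegmentCell:
    def test_recovery_of_volume_and_pairing_on_synthetic_cells(self, default_params):
        """Segmented volume within ±10% of truth; pairing call matches."""
        hits, total = 0, 0
        for i in range(5):
            truth = simulate_cell(default_params, rng=cell_rng(51, i))
            stack = render_microscopy(truth, default_params, rng=cell_rng(51, i))
            cell = segment_cell(stack, {"dna_channel": "dna"})
            for ch, true_mask in truth.masks.items():
                v_true = np.count_nonzero(true_mask)
                v_meas = np.count_nonzero(cell.territories[ch].labels > 0)
                assert v_meas == pytest.approx(v_true, rel=0.10)
                _, paired = pairing_state(cell.territories[ch])
                hits += paired == truth.true_pairing[ch]
                total += 1
        assert hits / total >= 0.95

    def test_missing_dna_channel_is_config_error(self, fast_params):
        truth = simulate_cell(fast_params, rng=cell_rng(53, 0))
        stack = render_microscopy(truth, fast_params, rng=cell_rng(53, 0))
        with pytest.raises(ValueError, match="dna"):
            segment_cell(stack, {"dna_channel": "hoechst"})

    def test_territories_clipped_to_nucleus(self, fast_params):
        truth = simulate_cell(fast_params, rng=cell_rng(57, 0))
        stack = render_microscopy(truth, fast_params, rng=cell_rng(57, 0))
        cell = segment_cell(stack, {"dna_channel": "dna"})
        for comps in cell.territories.values():
            assert not np.any((comps.labels > 0) & ~cell.nucleus.voxels)
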