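"""Contour, difference-histogram, delineation and distance metrics."""

import numpy as np
import pytest

from petmrac import (
    AnalysisError,
    bin_histogram,
    bone_mask,
    dice,
    distance_to_agreement,
    external_contour,
    gtv_metrics,
    percent_diff_map,
    threshold_gtv,
)
from petmrac.metrics import N_BINS, PercentDiffResult


class TestExternalContour:
    def test_uniform_body_recovers_support(self):
        suv = np.zeros((16, 16, 3))
        suv[4:12, 4:12, :] = 1.0
        mask = external_contour(suv, 0.05)
        assert np.array_equal(mask, suv > 0)

    def test_threshold_above_max_raises(self):
        with pytest.raises(AnalysisError):
            external_contour(np.full((4, 4, 1), 0.01), 0.05)

    def test_largest_component_kept(self):
        suv = np.zeros((20, 20, 1))
        suv[2:10, 2:10] = 1.0  # 64 voxels
        suv[14:17, 14:17] = 1.0  # 9 voxels
        mask = external_contour(suv, 0.05)
        assert mask[3, 3, 0] and not mask[15, 15, 0]
        assert mask.sum() == 64


class TestPercentDiff:
    def test_identical_images_zero(self):
        ref = np.full((8, 8, 1), 2.0)
        contour = np.ones_like(ref, dtype=bool)
        res = percent_diff_map(ref, ref, contour)
        assert np.all(res.values == 0)

    def test_uniform_scale(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(0.5, 3.0, size=(8, 8, 2))
        contour = np.ones_like(ref, dtype=bool)
        res = percent_diff_map(1.1 * ref, ref, contour)
        np.testing.assert_allclose(res.values, 10.0)

    def test_against_voxelwise_oracle(self):
        rng = np.random.default_rng(1)
        ref = rng.uniform(0, 2.0, size=(10, 10, 2))
        ev = rng.uniform(0, 2.0, size=(10, 10, 2))
        contour = rng.uniform(size=ref.shape) > 0.3
        res = percent_diff_map(ev, ref, contour)
        # brute-force oracle
        oracle = []
        nzero = 0
        for idx in np.ndindex(ref.shape):
            if contour[idx]:
                if ref[idx] > 0:
                    oracle.append(100 * (ev[idx] - ref[idx]) / ref[idx])
                else:
                    nzero += 1
        assert res.n_excluded_zero_ref == nzero
        assert res.mean == pytest.approx(np.mean(oracle))


class TestHistogram:
    def test_all_zero_diffs_fill_zero_bin(self):
        res = PercentDiffResult(np.zeros(500), 500, 0)
        hist = bin_histogram([res])
        zero_bin = np.searchsorted(hist.bin_edges, 0.0, side="right") - 1
        assert hist.mean_per_bin[zero_bin] == 100.0
        assert hist.mean_per_bin.sum() == 100.0

    def test_single_patient_flags_undefined_se(self):
        hist = bin_histogram([np.array([1.0, 2.0])])
        assert not hist.se_defined
        assert np.all(hist.se_per_bin == 0)

    def test_two_disjoint_single_bin_patients(self):
        a = PercentDiffResult(np.full(100, 10.1), 100, 0)
        b = PercentDiffResult(np.full(100, -49.9), 100, 0)
        hist = bin_histogram([a, b])
        occupied = hist.mean_per_bin > 0
        assert occupied.sum() == 2
        np.testing.assert_allclose(hist.mean_per_bin[occupied], 50.0)
        # closed-form SE: sd of {100, 0} is 70.71, / sqrt(2) -> 50
        np.testing.assert_allclose(hist.se_per_bin[occupied], 50.0)

    def test_bin_structure(self):
        hist = bin_histogram([np.array([0.0])])
        assert hist.bin_edges.size == N_BINS + 1
        assert hist.bin_edges[0] == -100.0 and hist.bin_edges[-1] == 100.0
        np.testing.assert_allclose(np.diff(hist.bin_edges), 0.5)

    def test_voxel_count_conservation(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 80, size=4000)  # some outside +/-100
        res = PercentDiffResult(vals, 4100, 100)
        hist = bin_histogram([res])
        binned = hist.per_patient_fraction[0].sum() / 100.0 * 4100
        assert binned + hist.n_excluded[0] == pytest.approx(4100)


class TestBoneMask:
    def test_recovers_phantom_bone_label(self, small_patient):
        from petmrac.phantoms import BONE

        mask = bone_mask(small_patient.hu_volume, 200.0, 50)
        truth = small_patient.tissue_labels == BONE
        assert (mask ^ truth).sum() / truth.sum() < 0.01

    def test_high_threshold_warns_empty(self, small_patient):
        with pytest.warns(UserWarning, match="empty"):
            mask = bone_mask(small_patient.hu_volume, 2000.0, 50)
        assert not mask.any()

    def test_speckle_removed(self):
        hu = np.full((16, 16, 1), 0.0)
        hu[2:10, 2:10] = 700.0
        hu[14, 14] = 700.0
        hu[14, 15] = 700.0
        mask = bone_mask(hu, 200.0, min_component_voxels=10)
        assert mask[5, 5, 0] and not mask[14, 14, 0]


class TestThresholdGtv:
    def test_uniform_suv_fills_manual_volume(self):
        suv = np.full((10, 10, 3), 4.0)
        manual = np.zeros_like(suv, dtype=bool)
        manual[3:7, 3:7, 1] = True
        assert np.array_equal(threshold_gtv(suv, manual), manual)

    def test_plateau_threshold_oracle(self):
        suv = np.full((20, 20, 1), 1.0)
        suv[8:12, 8:12] = 8.0
        manual = np.zeros_like(suv, dtype=bool)
        manual[5:15, 5:15] = True
        gtv = threshold_gtv(suv, manual, 0.4)
        assert np.array_equal(gtv, manual & (suv >= 3.2))
        assert gtv.sum() == 16

    def test_fraction_one_keeps_argmax_only(self):
        suv = np.zeros((6, 6, 1))
        suv[2, 2] = 5.0
        suv[3, 3] = 4.0
        manual = np.ones_like(suv, dtype=bool)
        gtv = threshold_gtv(suv, manual, 1.0)
        assert gtv.sum() == 1 and gtv[2, 2, 0]

    def test_zero_suv_raises(self):
        with pytest.raises(AnalysisError):
            threshold_gtv(np.zeros((4, 4, 1)), np.ones((4, 4, 1), bool))


class TestDice:
    def test_identical(self):
        a = np.zeros((6, 6, 1), bool)
        a[1:4, 1:4] = True
        assert dice(a, a) == 1.0

    def test_disjoint(self):
        a = np.zeros((6, 6, 1), bool)
        b = np.zeros((6, 6, 1), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert dice(a, b) == 0.0

    def test_hand_count(self):
        a = np.zeros((20, 20, 1), bool)
        b = np.zeros((20, 20, 1), bool)
        a[0:10, 0:10] = True  # 100
        b[0:10, 1:11] = True  # 100, overlap 90
        assert dice(a, b) == pytest.approx(0.90)

    def test_both_empty_undefined(self):
        with pytest.raises(AnalysisError):
            dice(np.zeros((3, 3, 1), bool), np.zeros((3, 3, 1), bool))


class TestDistanceToAgreement:
    def test_identical_masks_zero(self):
        a = np.zeros((8, 8, 3), bool)
        a[2:6, 2:6, 1] = True
        assert distance_to_agreement(a, a, (3.0, 3.0, 3.0)) == (0.0, 0.0)

    def test_one_voxel_face_adjacent_ring(self):
        """A mask against its 4-connected one-voxel dilation: every added
        boundary voxel is face-adjacent, so dta_max is one 3 mm voxel."""
        from scipy import ndimage

        inner = np.zeros((12, 12, 1), bool)
        inner[3:9, 3:9] = True
        cross = ndimage.generate_binary_structure(3, 1)
        outer = ndimage.binary_dilation(inner, structure=cross)
        dmean, dmax = distance_to_agreement(outer, inner, (3.0, 3.0, 3.0))
        assert dmax == pytest.approx(3.0)
        assert 0 < dmean <= 3.0

    def test_concentric_squares_corner_diagonal(self):
        # plain concentric squares: the outer corner's nearest inner boundary
        # voxel sits diagonally, sqrt(2) x 3 mm away
        outer = np.zeros((12, 12, 1), bool)
        inner = np.zeros((12, 12, 1), bool)
        outer[2:10, 2:10] = True
        inner[3:9, 3:9] = True
        _, dmax = distance_to_agreement(outer, inner, (3.0, 3.0, 3.0))
        assert dmax == pytest.approx(3.0 * np.sqrt(2.0))

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(10, 10, 3)) > 0.6
        b = rng.uniform(size=(10, 10, 3)) > 0.6
        assert distance_to_agreement(a, b, (3, 3, 3)) == distance_to_agreement(
            b, a, (3, 3, 3)
        )

    def test_translation_invariance(self):
        a = np.zeros((16, 16, 1), bool)
        b = np.zeros((16, 16, 1), bool)
        a[2:6, 2:6] = True
        b[3:7, 2:6] = True
        r1 = distance_to_agreement(a, b, (3, 3, 3))
        a2, b2 = np.roll(a, 5, axis=1), np.roll(b, 5, axis=1)
        assert distance_to_agreement(a2, b2, (3, 3, 3)) == r1

    def test_empty_rejected(self):
        a = np.zeros((4, 4, 1), bool)
        b = np.ones((4, 4, 1), bool)
        with pytest.raises(AnalysisError):
            distance_to_agreement(a, b, (3, 3, 3))


def lesion_image():
    suv = np.full((24, 24, 5), 1.0)
    suv[9:15, 9:15, 1:4] = 8.0
    manual = np.zeros_like(suv, dtype=bool)
    manual[6:18, 6:18, :] = True
    return suv, manual


class TestGtvMetrics:
    def test_identical_images(self):
        suv, manual = lesion_image()
        res = gtv_metrics(
            {"CTAC": suv, "sCTAC": suv, "MRAC": suv}, manual, (3, 3, 3)
        )
        for cand in ("sCTAC", "MRAC"):
            assert res.dsc[cand] == 1.0
            assert res.dta_mean_mm[cand] == 0.0
            assert res.volume_pct_diff[cand] == 0.0
            assert res.suv_max_pct_diff[cand] == 0.0
            assert res.suv_mean_pct_diff[cand] == 0.0

    def test_global_rescale_shifts_suv_not_gtv(self):
        suv, manual = lesion_image()
        res = gtv_metrics(
            {"CTAC": suv, "sCTAC": 0.95 * suv, "MRAC": suv}, manual, (3, 3, 3)
        )
        assert np.array_equal(res.masks["sCTAC"], res.masks["CTAC"])
        assert res.dsc["sCTAC"] == 1.0
        assert res.suv_max_pct_diff["sCTAC"] == pytest.approx(-5.0)
        assert res.suv_mean_pct_diff["sCTAC"] == pytest.approx(-5.0)

    def test_volume_sign_convention(self):
        suv, manual = lesion_image()
        bigger = suv.copy()
        bigger[8:16, 8:16, 1:4] = 8.0  # larger hot region
        res = gtv_metrics(
            {"CTAC": suv, "sCTAC": bigger, "MRAC": suv}, manual, (3, 3, 3)
        )
        assert res.volume_pct_diff["sCTAC"] > 0
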