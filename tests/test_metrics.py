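import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from octaskin import (
    BoxCountParams, CALParams, VesselMask,
    cal_area, cal_connectivity, cal_index, cal_length, count_components,
    evaluate, fractal_dimension, overlap_metrics, relative_percent_difference,
    skeletonize, vascular_density,
)
from oracles import exhaustive_fd, flood_fill_count


def mask2d(arr):
    return VesselMask(data=np.asarray(arr, dtype=bool))


def random_mask(rng, shape, density=0.25):
    return VesselMask(data=rng.random(shape) < density)


class TestOverlapMetrics:
    def test_identical_nonempty_masks_score_one(self, rng):
        m = random_mask(rng, (16, 16))
        assert overlap_metrics(m, m) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_nonempty_masks_score_zero_overlap(self):
        s = mask2d(np.eye(8))
        sgt = mask2d(np.flip(np.eye(8), 1))
        sgt.data[np.eye(8, dtype=bool)] = False
        dice, precision, recall, _ = overlap_metrics(s, sgt)
        assert (dice, precision, recall) == (0.0, 0.0, 0.0)

    def test_hand_counted_dice_two_thirds(self):
        s = np.zeros((4, 4), bool)
        sgt = np.zeros((4, 4), bool)
        s[0, :3] = True          # |S| = 3
        sgt[0, 1:4] = True       # |Sgt| = 3, overlap = 2
        dice, precision, recall, _ = overlap_metrics(mask2d(s), mask2d(sgt))
        assert dice == pytest.approx(2 * 2 / 6)
        assert precision == pytest.approx(2 / 3)
        assert recall == pytest.approx(2 / 3)

    def test_both_empty_masks_score_one(self):
        e = mask2d(np.zeros((6, 6)))
        assert overlap_metrics(e, e) == (1.0, 1.0, 1.0, 1.0)

    def test_identical_full_masks_score_one(self):
        f = mask2d(np.ones((6, 6)))
        assert overlap_metrics(f, f) == (1.0, 1.0, 1.0, 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            overlap_metrics(mask2d(np.zeros((4, 4))), mask2d(np.zeros((5, 5))))


class TestDensityAndComponents:
    def test_density_is_the_vessel_fraction(self):
        data = np.zeros((4, 5), bool)
        data.ravel()[:5] = True
        assert vascular_density(mask2d(data)) == 0.25
        assert vascular_density(mask2d(np.zeros((4, 5)))) == 0.0
        assert vascular_density(mask2d(np.ones((4, 5)))) == 1.0

    def test_diagonal_touch_merges_in_2d(self):
        data = np.zeros((4, 4), bool)
        data[0, 0] = data[1, 1] = True
        assert count_components(mask2d(data)) == 1

    def test_corner_touch_merges_in_3d(self):
        data = np.zeros((4, 4, 4), bool)
        data[0, 0, 0] = data[1, 1, 1] = True
        assert count_components(VesselMask(data=data)) == 1

    def test_separated_blobs_counted(self):
        data = np.zeros((8, 8), bool)
        data[0:2, 0:2] = True
        data[5:7, 5:7] = True
        assert count_components(mask2d(data)) == 2

    @pytest.mark.parametrize("shape,density", [((32, 32), 0.35), ((16, 16, 16), 0.2)])
    def test_matches_flood_fill_oracle(self, rng, shape, density):
        for _ in range(5):
            m = random_mask(rng, shape, density)
            assert count_components(m) == flood_fill_count(m.data)


class TestFractalDimension:
    def test_filled_square_approaches_dimension_two(self):
        # discretization at large box sizes biases the slope low, so the
        # area-filling limit needs a large mask to land within 0.1 of 2
        m = mask2d(np.ones((512, 512)))
        assert fractal_dimension(m) == pytest.approx(2.0, abs=0.1)

    def test_straight_line_approaches_dimension_one(self):
        data = np.zeros((512, 512), bool)
        data[256, :] = True
        assert fractal_dimension(mask2d(data)) == pytest.approx(1.0, abs=0.1)

    def test_single_pixel_has_dimension_zero(self):
        data = np.zeros((64, 64), bool)
        data[10, 20] = True
        assert fractal_dimension(mask2d(data)) == pytest.approx(0.0, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            fractal_dimension(mask2d(np.zeros((32, 32))))

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_box_count_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_mask(rng, (64, 64), 0.15)
        assert fractal_dimension(m) == pytest.approx(exhaustive_fd(m.data),
                                                     abs=1e-9)

    def test_3d_oracle_agreement(self, rng):
        m = random_mask(rng, (16, 16, 16), 0.1)
        assert fractal_dimension(m) == pytest.approx(exhaustive_fd(m.data),
                                                     abs=1e-9)


class TestSkeletonize:
    def test_wide_bar_thins_to_one_pixel_line(self):
        data = np.zeros((11, 20), bool)
        data[4:7, 2:18] = True  # 3-pixel-wide bar
        sk = skeletonize(mask2d(data))
        cols = sk.data[:, 4:16]
        assert np.all(cols.sum(axis=0) == 1)  # one pixel per column
        assert sk.data[~data].sum() == 0      # skeleton inside the bar

    def test_empty_mask_stays_empty(self):
        assert skeletonize(mask2d(np.zeros((8, 8)))).count == 0

    def test_component_count_preserved_on_two_blobs(self):
        data = np.zeros((24, 24), bool)
        data[2:8, 2:10] = True
        data[14:20, 12:22] = True
        sk = skeletonize(mask2d(data))
        assert count_components(sk) == 2


class TestCALComponents:
    def test_connectivity_equal_counts_scores_one(self, rng):
        m = random_mask(rng, (16, 16))
        assert cal_connectivity(m, m) == 1.0

    def test_connectivity_hand_case_point_seven(self):
        # #c(Sgt)=2, #c(S)=5, |Sgt|=10 -> 1 - 3/10
        sgt = np.zeros((20, 20), bool)
        sgt[0, 0:5] = True   # component 1, 5 px
        sgt[10, 0:5] = True  # component 2, 5 px
        s = np.zeros((20, 20), bool)
        for i in range(5):
            s[2 * i, 10 + 2 * i] = True  # 5 isolated pixels
        assert cal_connectivity(mask2d(s), mask2d(sgt)) == pytest.approx(0.7)

    def test_connectivity_clamps_at_zero(self):
        sgt = np.zeros((20, 20), bool)
        sgt[0, 0:2] = True  # 1 component, 2 px
        s = np.zeros((20, 20), bool)
        for i in range(5):
            s[2 * i, 10 + 2 * i] = True  # 5 components, diff 4 > 2
        assert cal_connectivity(mask2d(s), mask2d(sgt)) == 0.0

    def test_connectivity_monotone_in_component_difference(self):
        sgt = np.zeros((30, 30), bool)
        sgt[0, 0:10] = True  # 1 component, 10 px
        values = []
        for n in range(1, 7):
            s = np.zeros((30, 30), bool)
            for i in range(n):
                s[3 * i + 2, 20] = True
            values.append(cal_connectivity(mask2d(s), mask2d(sgt)))
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            cal_connectivity(mask2d(np.ones((4, 4))), mask2d(np.zeros((4, 4))))

    def test_area_identity_and_within_alpha_offset(self):
        sgt = np.zeros((16, 16), bool)
        sgt[7, 3:13] = True
        import scipy.ndimage as ndi
        s = ndi.binary_dilation(sgt)  # 1-dilation, within alpha=2
        assert cal_area(mask2d(sgt), mask2d(sgt)) == 1.0
        assert cal_area(mask2d(s), mask2d(sgt)) == 1.0

    def test_area_zero_beyond_alpha_separation(self):
        s = np.zeros((16, 16), bool)
        sgt = np.zeros((16, 16), bool)
        s[2, 2] = True
        sgt[12, 12] = True
        assert cal_area(mask2d(s), mask2d(sgt)) == 0.0

    def test_area_symmetric(self, rng):
        a = random_mask(rng, (20, 20), 0.2)
        b = random_mask(rng, (20, 20), 0.2)
        assert cal_area(a, b) == cal_area(b, a)

    def test_length_identity_and_one_pixel_shift(self):
        sgt = np.zeros((16, 32), bool)
        sgt[8, 4:28] = True
        s = np.zeros((16, 32), bool)
        s[9, 4:28] = True  # 1-pixel lateral shift, within beta=3
        assert cal_length(mask2d(sgt), mask2d(sgt)) == 1.0
        assert cal_length(mask2d(s), mask2d(sgt)) == 1.0

    def test_length_zero_beyond_beta_separation(self):
        s = np.zeros((24, 24), bool)
        sgt = np.zeros((24, 24), bool)
        s[2, 2:10] = True
        sgt[20, 2:10] = True
        assert cal_length(mask2d(s), mask2d(sgt)) == 0.0

    def test_length_symmetric(self, rng):
        a = random_mask(rng, (20, 20), 0.3)
        b = random_mask(rng, (20, 20), 0.3)
        assert cal_length(a, b) == cal_length(b, a)

    def test_index_is_the_product(self):
        sgt = np.zeros((24, 24), bool)
        sgt[4, 2:12] = True
        s = np.zeros((24, 24), bool)
        s[5, 2:8] = True
        s[15, 14:20] = True
        expected = (cal_connectivity(mask2d(s), mask2d(sgt))
                    * cal_area(mask2d(s), mask2d(sgt))
                    * cal_length(mask2d(s), mask2d(sgt)))
        assert cal_index(mask2d(s), mask2d(sgt)) == pytest.approx(expected)

    def test_index_one_for_perfect_and_zero_for_disjoint(self, gt_mask):
        assert cal_index(gt_mask, gt_mask) == 1.0
        s = np.zeros((32, 32), bool)
        sgt = np.zeros((32, 32), bool)
        s[2:5, 2:5] = True
        sgt[25:28, 25:28] = True
        assert cal_index(mask2d(s), mask2d(sgt)) == 0.0


class TestRelativePercentDifference:
    def test_signed_values(self):
        assert relative_percent_difference(1.0, 1.0) == 0.0
        assert relative_percent_difference(1.1, 1.0) == pytest.approx(10.0)
        assert relative_percent_difference(0.9, 1.0) == pytest.approx(-10.0)

    def test_zero_reference_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="zero reference"):
            assert math.isnan(relative_percent_difference(1.0, 0.0))


class TestEvaluate:
    def test_perfect_prediction_2d_and_3d(self, rng, gt_mask):
        for m in (random_mask(rng, (32, 32), 0.3), gt_mask):
            rep = evaluate(m, m)
            assert rep.dice == rep.precision == rep.recall == 1.0
            assert rep.balanced_accuracy == 1.0
            assert rep.cal == 1.0
            assert rep.rpd_vd == rep.rpd_vf == rep.rpd_fd == 0.0

    def test_empty_prediction_against_nonempty_reference(self):
        s = mask2d(np.zeros((32, 32)))
        sgt = np.zeros((32, 32), bool)
        sgt[10:20, 10:20] = True
        rep = evaluate(s, mask2d(sgt))
        assert rep.dice == 0.0 and rep.recall == 0.0
        assert rep.rpd_vd == pytest.approx(-100.0)
        assert math.isnan(rep.fd_pred) and math.isnan(rep.rpd_fd)

    def test_report_product_invariant_on_random_pairs(self, rng):
        s = random_mask(rng, (24, 24), 0.25)
        sgt = random_mask(rng, (24, 24), 0.25)
        rep = evaluate(s, sgt)
        assert rep.cal == pytest.approx(rep.cal_conn * rep.cal_area * rep.cal_length)

    def test_dimensionality_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            evaluate(random_mask(rng, (8, 8)), random_mask(rng, (8, 8, 8)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_bounded_metrics_stay_in_unit_interval(seed):
    """Every bounded metric lies in [0, 1] for arbitrary mask pairs."""
    rng = np.random.default_rng(seed)
    s = VesselMask(data=rng.random((12, 12)) < rng.uniform(0.05, 0.6))
    sgt_data = rng.random((12, 12)) < rng.uniform(0.05, 0.6)
    sgt_data[0, 0] = True  # keep the reference nonempty
    sgt = VesselMask(data=sgt_data)
    dice, precision, recall, bal = overlap_metrics(s, sgt)
    params = CALParams()
    vals = [dice, precision, recall, bal,
            cal_connectivity(s, sgt), cal_area(s, sgt, params),
            cal_length(s, sgt, params), cal_index(s, sgt, params),
            vascular_density(s)]
    assert all(0.0 <= v <= 1.0 for v in vals)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_dice_is_one_only_for_identical_masks(seed):
    rng = np.random.default_rng(seed)
    s = VesselMask(data=rng.random((10, 10)) < 0.4)
    sgt = VesselMask(data=rng.random((10, 10)) < 0.4)
    dice = overlap_metrics(s, sgt)[0]
    if np.array_equal(s.data, sgt.data):
        assert dice == 1.0
    elif s.count or sgt.count:
        assert dice < 1.0
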