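"""Agreement metrics against brute-force oracles and closed-form geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.distance import directed_hausdorff as scipy_directed_hausdorff

from contourvar import (
    LabelVolume,
    MetricUndefinedError,
    PairMetrics,
    boundary_points,
    directed_hd,
    directed_percentile_hd,
    dsc,
    hd95,
    pair_metrics,
    undirected_hd,
)

from _oracles import (
    brute_directed_hd,
    brute_nearest_distances,
    brute_percentile,
    random_mask_pair,
)


def _vol(vox, spacing=(1.0, 1.0, 3.0)):
    return LabelVolume(np.asarray(vox, dtype=bool), spacing)


def _cube(shape, lo, hi, spacing=(1.0, 1.0, 1.0)):
    vox = np.zeros(shape, dtype=bool)
    vox[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return LabelVolume(vox, spacing)


class TestDsc:
    def test_identical_masks_exactly_one(self, rng):
        vox = rng.random((6, 6, 4)) < 0.5
        vox[0, 0, 0] = True
        assert dsc(_vol(vox), _vol(vox.copy())) == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((4, 4, 4), dtype=bool); a[0] = True
        b = np.zeros((4, 4, 4), dtype=bool); b[2] = True
        assert dsc(_vol(a), _vol(b)) == 0.0

    def test_half_overlap(self):
        a = np.zeros((4, 4, 4), dtype=bool); a.reshape(-1)[:8] = True
        b = np.zeros((4, 4, 4), dtype=bool); b.reshape(-1)[4:12] = True
        assert dsc(_vol(a), _vol(b)) == pytest.approx(0.5)

    def test_both_empty_undefined(self):
        with pytest.raises(MetricUndefinedError):
            dsc(_vol(np.zeros((3, 3, 3))), _vol(np.zeros((3, 3, 3))))

    def test_symmetric(self, rng):
        a, b = random_mask_pair(rng)
        assert dsc(a, b) == dsc(b, a)


class TestDirectedHd:
    def test_3_4_5_triangle(self):
        assert directed_hd(np.array([[0, 0, 0.]]), np.array([[3, 4, 0.]])) == 5.0

    def test_subset_gives_zero(self, rng):
        y = rng.random((20, 3)) * 10
        x = y[:7]
        assert directed_hd(x, y) == 0.0

    def test_asymmetry_witness(self):
        x = np.array([[0, 0, 0], [10, 0, 0.]])
        y = np.array([[0, 0, 0.]])
        assert directed_hd(x, y) == 10.0
        assert directed_hd(y, x) == 0.0
        assert undirected_hd(x, y) == undirected_hd(y, x) == 10.0

    def test_empty_set_undefined(self):
        with pytest.raises(MetricUndefinedError):
            directed_hd(np.empty((0, 3)), np.array([[0, 0, 0.]]))


class TestPercentileHd:
    def test_constant_distances_any_percentile(self):
        x = np.array([[0, 0, 2.], [5, 0, 2.], [9, 0, 2.]])
        y = x + np.array([0, 0, 2.0])  # every nearest distance = 2
        for q in (5, 50, 95, 100):
            assert directed_percentile_hd(x, y, q) == pytest.approx(2.0)

    def test_q100_reduces_to_directed_hd(self):
        x = np.array([[0, 0, 0], [10, 0, 0.]])
        y = np.array([[0, 0, 0.]])
        assert directed_percentile_hd(x, y, 100) == directed_hd(x, y) == 10.0

    def test_outlier_robustness_matches_interpolation_oracle(self):
        # 100 points: 99 at distance 1, one at distance 50
        x = np.zeros((100, 3))
        x[:, 0] = np.arange(100) * 100.0
        y = x.copy()
        y[:, 1] = 1.0
        y[0, 1] = 50.0
        dists = brute_nearest_distances(x, y)
        expected = brute_percentile(dists, 95)
        assert directed_percentile_hd(x, y, 95) == pytest.approx(expected, abs=1e-12)
        assert expected < 50.0  # the outlier no longer dominates

    @pytest.mark.parametrize("q", [0.0, -5.0, 100.5])
    def test_invalid_percentile_rejected(self, q):
        x = np.array([[0, 0, 0.]])
        with pytest.raises(ValueError, match="percentile"):
            directed_percentile_hd(x, x, q)


class TestOracleAgreement:
    """k-d-tree paths must equal the exhaustive double loop exactly."""

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(15):
            a, b = random_mask_pair(rng)
            x, y = boundary_points(a), boundary_points(b)
            assert directed_hd(x, y) == pytest.approx(brute_directed_hd(x, y), abs=1e-9)
            assert undirected_hd(x, y) == pytest.approx(
                max(brute_directed_hd(x, y), brute_directed_hd(y, x)), abs=1e-9
            )
            for q in (37.5, 95.0):
                assert directed_percentile_hd(x, y, q) == pytest.approx(
                    brute_percentile(brute_nearest_distances(x, y), q), abs=1e-9
                )

    def test_matches_scipy_directed_hausdorff(self, rng):
        a, b = random_mask_pair(rng)
        x, y = boundary_points(a), boundary_points(b)
        assert directed_hd(x, y) == pytest.approx(
            scipy_directed_hausdorff(x, y)[0], abs=1e-12
        )


class TestHd95:
    def test_identical_masks_zero(self, rng):
        a, _ = random_mask_pair(rng)
        assert hd95(a, a) == 0.0

    def test_translated_cube_matches_oracle(self):
        # 6-voxel cube shifted 2 voxels (= 2 mm) along x
        a = _cube((12, 10, 10), (1, 1, 1), (7, 7, 7))
        b = _cube((12, 10, 10), (3, 1, 1), (9, 7, 7))
        x, y = boundary_points(a), boundary_points(b)
        expected = 0.5 * (
            brute_percentile(brute_nearest_distances(x, y), 95)
            + brute_percentile(brute_nearest_distances(y, x), 95)
        )
        assert hd95(a, b) == pytest.approx(expected, abs=1e-9)
        assert undirected_hd(x, y) == pytest.approx(2.0)

    def test_symmetric_and_bounded_by_hd(self, rng):
        for _ in range(10):
            a, b = random_mask_pair(rng)
            if a.is_empty() or b.is_empty():
                continue
            v = hd95(a, b)
            assert v == pytest.approx(hd95(b, a), abs=1e-12)
            assert v <= undirected_hd(boundary_points(a), boundary_points(b)) + 1e-12

    def test_empty_mask_undefined(self):
        a = _vol(np.zeros((3, 3, 3)))
        b = _vol(np.ones((3, 3, 3)))
        with pytest.raises(MetricUndefinedError):
            hd95(a, b)

    def test_filled_point_set_option(self, rng):
        a, b = random_mask_pair(rng)
        # filled sets include interior voxels: value may differ but is defined
        v = hd95(a, b, points="filled")
        assert v >= 0
        with pytest.raises(ValueError, match="points"):
            hd95(a, b, points="mesh")


class TestScaleCovariance:
    @given(scale=st.floats(0.25, 4.0))
    def test_spacing_scales_distances_not_dsc(self, scale):
        rng = np.random.default_rng(5)
        a, b = random_mask_pair(rng)
        sa = LabelVolume(a.voxels, tuple(s * scale for s in a.spacing))
        sb = LabelVolume(b.voxels, tuple(s * scale for s in b.spacing))
        assert dsc(sa, sb) == dsc(a, b)
        assert hd95(sa, sb) == pytest.approx(scale * hd95(a, b), rel=1e-9)


class TestTranslationMonotonicity:
    def test_dsc_decreases_hd95_increases_with_shift(self):
        base = _cube((30, 12, 12), (1, 1, 1), (11, 11, 11))
        dscs, hds = [], []
        for t in range(0, 9, 2):
            shifted = _cube((30, 12, 12), (1 + t, 1, 1), (11 + t, 11, 11))
            dscs.append(dsc(base, shifted))
            hds.append(hd95(base, shifted))
        assert all(d1 >= d2 for d1, d2 in zip(dscs, dscs[1:]))
        assert all(h1 <= h2 for h1, h2 in zip(hds, hds[1:]))


class TestPairMetrics:
    def test_consistent_with_individual_metrics(self, rng):
        a, b = random_mask_pair(rng)
        pm = pair_metrics(a, b)
        assert pm.dsc == pytest.approx(dsc(a, b))
        assert pm.hd95 == pytest.approx(hd95(a, b))
        assert pm.hd95 <= pm.hd

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            PairMetrics(dsc=1.2, hd=1, hd95=1, volume_a=1, volume_b=1)
        with pytest.raises(ValueError):
            PairMetrics(dsc=0.5, hd=1.0, hd95=2.0, volume_a=1, volume_b=1)
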