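"""Segmentation: thresholding, fuzzy c-means, MR metal regions, contours."""

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import ndimage

from oralphan.phantom import ConfigurationError
from oralphan.segment import (FcmDegenerateError, FcmParams, auto_contour,
                              dice, fcm, fcm_objective, fcm_with_threshold,
                              mr_metal_region, oral_roi, threshold_segment)
from oralphan.volume import ImageVolume


def _ct(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, float), spacing, "CT", "HU")


def _mr(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, float), spacing, "MR")


finite_values = st.lists(
    st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
    min_size=6, max_size=40,
)


class TestThresholdSegment:
    def test_window_selects_exact_range(self):
        vol = _ct(np.linspace(0, 4000, 64).reshape(4, 4, 4))
        mask = threshold_segment(vol, 1200, 3500)
        np.testing.assert_array_equal(
            mask, (vol.data >= 1200) & (vol.data <= 3500)
        )

    def test_degenerate_window_is_level_set(self):
        vol = _ct(np.array([[[1200.0, 1300.0], [1200.0, 0.0]]]))
        mask = threshold_segment(vol, 1200, 1200)
        assert mask.sum() == 2

    def test_all_air_image_empty(self):
        assert not threshold_segment(_ct(np.full((4, 4, 4), -1000.0))).any()

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            threshold_segment(_ct(np.zeros((2, 2, 2))), 3500, 1200)

    def test_requires_ct_modality(self):
        with pytest.raises(ConfigurationError):
            threshold_segment(_mr(np.zeros((2, 2, 2))))

    def test_idempotent_on_own_support(self):
        rng = np.random.default_rng(0)
        vol = _ct(rng.uniform(0, 4000, (6, 6, 6)))
        mask = threshold_segment(vol)
        masked = vol.data.copy()
        masked[~mask] = -1000.0
        again = threshold_segment(_ct(masked))
        np.testing.assert_array_equal(mask, again)


class TestFcm:
    def test_two_well_separated_groups(self):
        res = fcm([0, 0, 0, 10, 10, 10],
                  FcmParams(n_clusters=2, epsilon=1e-5, seed=0))
        assert sorted(np.round(res.centers, 2)) == pytest.approx([0.0, 10.0],
                                                                 abs=0.05)
        assert np.all(res.memberships.max(axis=1) > 0.99)

    def test_single_cluster_closed_form(self):
        values = np.array([1.0, 2.0, 4.0, 9.0])
        res = fcm(values, FcmParams(n_clusters=1))
        assert res.centers[0] == pytest.approx(values.mean())
        assert res.objective_trace[-1] == pytest.approx(
            np.sum((values - values.mean()) ** 2)
        )

    @given(finite_values)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_membership_rows_sum_to_one(self, values):
        values = np.asarray(values)
        assume(np.ptp(values) > 1e-6)
        res = fcm(values, FcmParams(n_clusters=2, max_iter=50, seed=1))
        np.testing.assert_allclose(res.memberships.sum(axis=1), 1.0,
                                   atol=1e-9)

    @given(finite_values)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_objective_trace_never_increases(self, values):
        values = np.asarray(values)
        assume(np.ptp(values) > 1e-6)
        res = fcm(values, FcmParams(n_clusters=2, max_iter=60, seed=2))
        trace = res.objective_trace
        assert np.all(np.diff(trace) <= 1e-9 * max(trace[0], 1.0))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 100, 25)
        perm = rng.permutation(25)
        params = FcmParams(n_clusters=2, epsilon=1e-9, max_iter=500, seed=4)
        a = fcm(values, params)
        b = fcm(values[perm], params)
        assert np.allclose(sorted(a.centers), sorted(b.centers), atol=1e-5)
        # memberships follow the permutation (up to cluster relabelling)
        order_a = np.argsort(a.centers)
        order_b = np.argsort(b.centers)
        np.testing.assert_allclose(
            a.memberships[perm][:, order_a], b.memberships[:, order_b],
            atol=1e-5,
        )

    def test_identical_values_degenerate(self):
        with pytest.raises(FcmDegenerateError):
            fcm([5.0] * 10, FcmParams(n_clusters=2))

    def test_grid_search_oracle_agreement(self):
        """J of the returned c=2 solution matches a dense center-pair grid
        search of the objective to 1e-3."""
        rng = np.random.default_rng(11)
        for _ in range(5):
            values = rng.uniform(0, 1, rng.integers(8, 30))
            res = fcm(values, FcmParams(n_clusters=2, epsilon=1e-7,
                                        max_iter=500, seed=7))
            j_fcm = res.objective_trace[-1]
            j_grid = _grid_search_j(values, n_grid=220)
            assert j_fcm <= j_grid + 1e-3

    def test_fuzzifier_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            FcmParams(fuzzifier=1.0)


def _grid_search_j(values, n_grid=200):
    """Independent oracle: minimize the c=2 fuzzy objective by evaluating
    the optimal-membership objective on a dense grid of center pairs."""
    lo, hi = values.min(), values.max()
    grid = np.linspace(lo, hi, n_grid)
    best = np.inf
    for i in range(n_grid):
        d1 = (values[None, :] - grid[i]) ** 2
        d2 = (values[None, :] - grid[:, None]) ** 2
        with np.errstate(divide="ignore", invalid="ignore"):
            # optimal memberships for F=2: u_b proportional to 1/d_b
            inv1, inv2 = 1.0 / d1, 1.0 / d2
            total = inv1 + inv2
            j = np.where(
                np.isfinite(total),
                (inv1 / total) ** 2 * d1 + (inv2 / total) ** 2 * d2,
                0.0,  # a point coinciding with a center contributes 0
            ).sum(axis=1)
        best = min(best, j.min())
    return best


class TestFcmWithThreshold:
    def test_bright_population_recovered_exactly(self):
        data = np.zeros((8, 8, 8))
        data[2:4, 2:4, 2:4] = 100.0
        data[5:7, 5:7, 5:7] = 2000.0
        roi = np.ones_like(data, bool)
        mask = fcm_with_threshold(_ct(data), roi,
                                  FcmParams(n_clusters=2, seed=0))
        np.testing.assert_array_equal(mask, data == 2000.0)

    def test_uniform_roi_exercises_degeneracy_contract(self):
        data = np.full((6, 6, 6), 1500.0)
        with pytest.raises(FcmDegenerateError):
            fcm_with_threshold(_ct(data), np.ones_like(data, bool),
                               FcmParams(n_clusters=2, seed=0))

    def test_empty_roi_rejected(self):
        with pytest.raises(ConfigurationError):
            fcm_with_threshold(_ct(np.zeros((4, 4, 4))),
                               np.zeros((4, 4, 4), bool))

    def test_oral_roi_is_padded_bounding_box(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[4:6, 4:6, 4:6] = True
        roi = oral_roi(mask, pad=2)
        assert roi[2:8, 2:8, 2:8].all()
        assert roi.sum() == 6**3


class TestMrMetalRegion:
    def test_all_zero_image_gives_empty_mask(self):
        assert not mr_metal_region(_mr(np.zeros((16, 16, 16)))).any()

    def test_artifact_free_solution_false_positive_rate_below_one_percent(
        self, phantom_none_small
    ):
        from oralphan.mr_sim import MrSequence, simulate_mr
        from oralphan.phantom import ground_truth_mask

        img = simulate_mr(phantom_none_small, None, MrSequence.se(290), seed=5)
        mask = mr_metal_region(img)
        sol = ground_truth_mask(phantom_none_small, {"solution"})
        assert (mask & sol).sum() < 0.01 * sol.sum()

    def test_requires_mr_modality(self):
        with pytest.raises(ConfigurationError):
            mr_metal_region(_ct(np.zeros((4, 4, 4))))


class TestAutoContour:
    @pytest.fixture(scope="class")
    def sphere(self):
        n = 48
        x = np.arange(n) - n / 2 + 0.5
        xx, yy, zz = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt(xx**2 + yy**2 + zz**2)
        img = _mr(np.where(r <= 8, 1.0, 0.1))
        return img, r <= 8

    def test_exact_seed_locks_onto_boundary(self, sphere):
        img, truth = sphere
        out = auto_contour(img, truth)
        assert dice(out, truth) > 0.95

    def test_dilated_seed_shrinks_to_edge(self, sphere):
        img, truth = sphere
        seed = ndimage.binary_dilation(truth, iterations=3)
        out = auto_contour(img, seed)
        assert dice(out, truth) > 0.9

    def test_constant_image_returns_seed(self):
        seed = np.zeros((12, 12, 12), bool)
        seed[4:8, 4:8, 4:8] = True
        out = auto_contour(_mr(np.ones((12, 12, 12))), seed)
        np.testing.assert_array_equal(out, seed)

    def test_empty_seed_rejected(self):
        with pytest.raises(ConfigurationError):
            auto_contour(_mr(np.zeros((4, 4, 4))), np.zeros((4, 4, 4), bool))
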