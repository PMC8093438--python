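"""t-map computation, thresholding, perturbations, and their invariances."""

import numpy as np
import pytest
from scipy import ndimage, stats

import tmasking as tm
from tmasking.cohort import CohortError

from conftest import full_mask, make_stack


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        vol = rng.normal(size=(9, 9, 9))
        out = tm.smooth_volume(vol, tm.SmoothingSpec(0.0), (1, 1, 1))
        np.testing.assert_array_equal(out, vol)

    def test_impulse_mass_preserved(self):
        vol = np.zeros((33, 33, 33))
        vol[16, 16, 16] = 1.0
        out = tm.smooth_volume(vol, tm.SmoothingSpec(6.0), (1, 1, 1))
        assert abs(out.sum() - 1.0) < 1e-3
        assert np.unravel_index(out.argmax(), out.shape) == (16, 16, 16)

    def test_sigma_conversion(self):
        # 6 mm FWHM at 1 mm voxels -> sigma = 6 / (2 sqrt(2 ln 2))
        assert abs(tm.fwhm_to_sigma(6.0, 1.0) - 2.548) < 1e-3
        # anisotropic voxels get per-axis sigmas
        s = tm.SmoothingSpec(6.0).sigmas_vox((1.0, 2.0, 3.0))
        np.testing.assert_allclose(s * np.array([1.0, 2.0, 3.0]), s[0])

    def test_matches_discrete_gaussian_kernel(self, rng):
        # separable-kernel oracle on an interior impulse
        sigma = tm.fwhm_to_sigma(6.0, 1.0)
        vol = np.zeros((33, 33, 33))
        vol[16, 16, 16] = 1.0
        out = tm.smooth_volume(vol, tm.SmoothingSpec(6.0), (1, 1, 1))
        r = 16
        x = np.arange(-r, r + 1)
        g1 = np.exp(-0.5 * (x / sigma) ** 2)
        g1 /= g1.sum()
        expected = g1[:, None, None] * g1[None, :, None] * g1[None, None, :]
        np.testing.assert_allclose(out, expected, atol=1e-4)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError):
            tm.SmoothingSpec(-1.0)


class TestComputeTmap:
    def test_standard_mode_matches_reference_ttest(self, rng):
        brain = full_mask((8, 8, 8))
        for trial in range(20):
            vols = rng.normal(size=(20, 8, 8, 8))
            stack = make_stack(vols, np.r_[np.zeros(10, int), np.ones(10, int)])
            t = tm.compute_tmap(stack, brain, tm.SmoothingSpec(0.0), mode="standard")
            ref = np.abs(stats.ttest_ind(vols[:10], vols[10:], axis=0).statistic)
            np.testing.assert_allclose(t.grid, ref, atol=1e-6)

    def test_literal_mode_matches_direct_evaluation(self, rng):
        vols = rng.normal(size=(12, 6, 6, 6))
        stack = make_stack(vols, np.r_[np.zeros(6, int), np.ones(6, int)])
        t = tm.compute_tmap(stack, full_mask((6, 6, 6)), tm.SmoothingSpec(0.0), mode="literal")
        mu0, mu1 = vols[:6].mean(axis=0), vols[6:].mean(axis=0)
        s0, s1 = vols[:6].std(axis=0, ddof=1), vols[6:].std(axis=0, ddof=1)
        ref = np.abs(mu0 - mu1) / np.sqrt(0.5 * (s0**2 + s1**2))
        np.testing.assert_allclose(t.grid, ref, atol=1e-10)

    def test_single_voxel_worked_example(self):
        # group0 = (1,2,3,4), group1 = (3,4,5,6): effect-size mode 1.5492,
        # pooled-t mode 2.1909
        v = np.zeros((8, 1, 1, 1))
        v[:, 0, 0, 0] = [1, 2, 3, 4, 3, 4, 5, 6]
        stack = make_stack(v, [0, 0, 0, 0, 1, 1, 1, 1])
        brain = full_mask((1, 1, 1))
        lit = tm.compute_tmap(stack, brain, tm.SmoothingSpec(0.0), "literal").grid.item()
        std = tm.compute_tmap(stack, brain, tm.SmoothingSpec(0.0), "standard").grid.item()
        assert abs(lit - 1.5492) < 1e-4
        assert abs(std - 2.1909) < 1e-4
        ref = abs(stats.ttest_ind([1, 2, 3, 4], [3, 4, 5, 6]).statistic)
        assert abs(std - ref) < 1e-10

    def test_identical_groups_give_zero(self, rng):
        half = rng.normal(size=(5, 4, 4, 4))
        stack = make_stack(np.concatenate([half, half]), np.r_[np.zeros(5, int), np.ones(5, int)])
        t = tm.compute_tmap(stack, full_mask((4, 4, 4)), tm.SmoothingSpec(0.0))
        np.testing.assert_array_equal(t.grid, 0.0)

    @pytest.mark.parametrize("mode", ["literal", "standard"])
    def test_invariances(self, rng, mode):
        vols = rng.normal(size=(12, 5, 5, 5))
        labels = np.r_[np.zeros(6, int), np.ones(6, int)]
        brain = full_mask((5, 5, 5))
        spec = tm.SmoothingSpec(0.0)
        base = tm.compute_tmap(make_stack(vols, labels), brain, spec, mode).grid
        swapped = tm.compute_tmap(make_stack(vols, 1 - labels), brain, spec, mode).grid
        np.testing.assert_allclose(swapped, base, atol=1e-12)
        shifted = tm.compute_tmap(make_stack(vols + 7.3, labels), brain, spec, mode).grid
        np.testing.assert_allclose(shifted, base, atol=1e-8)
        scaled = tm.compute_tmap(make_stack(vols * 4.2, labels), brain, spec, mode).grid
        np.testing.assert_allclose(scaled, base, atol=1e-8)

    def test_zero_variance_voxel_gets_zero(self):
        vols = np.zeros((8, 2, 1, 1))
        vols[:, 0, 0, 0] = [1, 2, 3, 4, 5, 6, 7, 8]  # informative voxel
        stack = make_stack(vols, [0, 0, 0, 0, 1, 1, 1, 1])
        t = tm.compute_tmap(stack, full_mask((2, 1, 1)), tm.SmoothingSpec(0.0))
        assert t.grid[1, 0, 0] == 0.0
        assert t.grid[0, 0, 0] > 0

    def test_leakage_contract_only_training_labels_matter(self, rng):
        # the map is a pure function of the training stack it receives
        vols = rng.normal(size=(10, 4, 4, 4))
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        stack = make_stack(vols, labels)
        brain = full_mask((4, 4, 4))
        t1 = tm.compute_tmap(stack, brain, tm.SmoothingSpec(0.0)).grid
        t2 = tm.compute_tmap(stack, brain, tm.SmoothingSpec(0.0)).grid
        np.testing.assert_array_equal(t1, t2)

    def test_single_class_rejected(self, rng):
        stack = make_stack(rng.normal(size=(4, 3, 3, 3)), [1, 1, 1, 1])
        with pytest.raises(CohortError, match="one-group"):
            tm.compute_tmap(stack, full_mask((3, 3, 3)), tm.SmoothingSpec(0.0))

    def test_insufficient_per_group_rejected(self, rng):
        stack = make_stack(rng.normal(size=(3, 3, 3, 3)), [0, 1, 1])
        with pytest.raises(CohortError, match="insufficient"):
            tm.compute_tmap(stack, full_mask((3, 3, 3)), tm.SmoothingSpec(0.0))


class TestThresholdMask:
    def _toy_tmap(self, values):
        grid = np.array(values, dtype=float).reshape(-1, 1, 1)
        brain = full_mask(grid.shape)
        return tm.TMap(grid=grid, mode="standard", fwhm_mm=0.0, n0=5, n1=5, brain_mask=brain)

    def test_strict_inequality_on_toy_triple(self):
        t = self._toy_tmap([0.5, 3.7, 4.1])
        mask = tm.threshold_mask(t, 3.6)
        np.testing.assert_array_equal(mask.grid.ravel(), [0, 1, 1])
        # boundary: a voxel exactly at the threshold is NOT selected
        t2 = self._toy_tmap([3.6, 3.7])
        np.testing.assert_array_equal(tm.threshold_mask(t2, 3.6).grid.ravel(), [0, 1])

    def test_zero_threshold_selects_whole_brain(self, rng):
        vols = rng.normal(size=(10, 5, 5, 5))
        stack = make_stack(vols, np.r_[np.zeros(5, int), np.ones(5, int)])
        brain = full_mask((5, 5, 5))
        t = tm.compute_tmap(stack, brain, tm.SmoothingSpec(0.0))
        mask = tm.threshold_mask(t, 0.0)
        np.testing.assert_array_equal(mask.grid, brain.grid)

    def test_above_max_gives_empty_mask(self, rng):
        t = self._toy_tmap([0.5, 3.7, 4.1])
        assert tm.threshold_mask(t, 8.0).n_active == 0

    def test_mask_nesting_along_grid(self, rng):
        vols = rng.normal(size=(20, 6, 6, 6))
        stack = make_stack(vols, np.r_[np.zeros(10, int), np.ones(10, int)])
        brain = full_mask((6, 6, 6))
        t = tm.compute_tmap(stack, brain, tm.SmoothingSpec(0.0))
        prev = None
        rates = []
        for thr in tm.threshold_grid():
            m = tm.threshold_mask(t, thr)
            rates.append(tm.selection_rate(m, brain))
            if prev is not None:
                assert np.all(m.grid <= prev.grid), "higher threshold must select a subset"
            prev = m
        assert all(a >= b for a, b in zip(rates, rates[1:]))


class TestPerturbations:
    def _tmap(self, rng, n=10_000):
        grid = rng.uniform(1.0, 5.0, size=(n, 1, 1))
        brain = full_mask(grid.shape)
        return tm.TMap(grid=grid, mode="standard", fwhm_mm=0.0, n0=5, n1=5, brain_mask=brain)

    def test_gaussian_sd_zero_unchanged(self, rng):
        t = self._tmap(rng, 100)
        out = tm.perturb_tmap_gaussian(t, 0.0, seed=0)
        np.testing.assert_array_equal(out.grid, t.grid)

    def test_gaussian_noise_empirical_sd(self, rng):
        t = self._tmap(rng)  # all t >= 1, so clipping never triggers at sd 0.2
        out = tm.perturb_tmap_gaussian(t, 0.2, seed=1)
        diff = out.grid - t.grid
        assert 0.19 <= diff.std() <= 0.21
        assert abs(diff.mean()) < 0.01

    def test_gaussian_determinism_and_clipping(self, rng):
        t = self._tmap(rng, 500)
        a = tm.perturb_tmap_gaussian(t, 2.0, seed=7)
        b = tm.perturb_tmap_gaussian(t, 2.0, seed=7)
        np.testing.assert_array_equal(a.grid, b.grid)
        assert (a.grid >= 0).all()

    def test_bernoulli_knockout_statistics(self, rng):
        mask = tm.BinaryMask(np.ones((10_000, 1, 1), dtype=np.uint8))
        out = tm.perturb_mask_bernoulli(mask, 0.05, seed=3)
        assert 9435 <= out.n_active <= 9565  # 3-sigma binomial band
        np.testing.assert_array_equal(
            out.grid, tm.perturb_mask_bernoulli(mask, 0.05, seed=3).grid
        )

    def test_bernoulli_edge_probabilities(self, rng):
        mask = tm.BinaryMask((rng.random((20, 20, 20)) > 0.5).astype(np.uint8))
        same = tm.perturb_mask_bernoulli(mask, 0.0, seed=0)
        np.testing.assert_array_equal(same.grid, mask.grid)
        assert tm.perturb_mask_bernoulli(mask, 1.0, seed=0).n_active == 0
        with pytest.raises(ValueError):
            tm.perturb_mask_bernoulli(mask, 1.5, seed=0)

    def test_random_mask_survival_rate(self):
        brain = tm.BinaryMask(np.ones((100_000, 1, 1), dtype=np.uint8))
        out = tm.random_mask(brain, 0.99, seed=9)
        assert 1000 - 94 <= out.n_active <= 1000 + 94
        np.testing.assert_array_equal(out.grid, tm.random_mask(brain, 0.99, seed=9).grid)

    def test_random_mask_p_zero_keeps_brain(self, rng):
        brain = tm.BinaryMask((rng.random((10, 10, 10)) > 0.3).astype(np.uint8))
        np.testing.assert_array_equal(tm.random_mask(brain, 0.0, seed=0).grid, brain.grid)


class TestApplyMaskAndSelectionRate:
    def test_full_and_empty_masks(self, rng):
        stack = make_stack(rng.normal(size=(3, 4, 4, 4)), [0, 1, 0])
        full = full_mask((4, 4, 4))
        np.testing.assert_array_equal(tm.apply_mask(stack, full).volumes, stack.volumes)
        empty = tm.BinaryMask(np.zeros((4, 4, 4), dtype=np.uint8))
        assert np.all(tm.apply_mask(stack, empty).volumes == 0)

    def test_active_voxel_count_bounds_nonzeros(self, rng):
        stack = make_stack(rng.normal(size=(3, 6, 6, 6)), [0, 1, 0])
        grid = (rng.random((6, 6, 6)) > 0.7).astype(np.uint8)
        mask = tm.BinaryMask(grid)
        out = tm.apply_mask(stack, mask)
        for v in out.volumes:
            assert np.count_nonzero(v) <= mask.n_active
        assert out.subject_ids == stack.subject_ids
        np.testing.assert_array_equal(out.labels, stack.labels)

    def test_selection_rate_counting(self):
        brain = tm.BinaryMask(np.ones((100, 1, 1), dtype=np.uint8))
        grid = np.zeros((100, 1, 1), dtype=np.uint8)
        grid[:10] = 1
        assert tm.selection_rate(tm.BinaryMask(grid), brain) == pytest.approx(0.1)
        assert tm.selection_rate(brain, brain) == 1.0
        empty_brain = tm.BinaryMask(np.zeros((4, 1, 1), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty brain"):
            tm.selection_rate(brain, empty_brain)
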