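"""Resampling, block downsampling, correlation and group tests."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from betaquant.multimodal import (
    VOIMask,
    correlate,
    downsample_blocks,
    rank_sum,
    resample_to_reference,
    summarize_region,
    welch_t,
)
from betaquant.volume import ImageVolume


class TestResample:
    def test_identity_transform_is_bitwise_identity(self, rng):
        vol = ImageVolume(rng.normal(size=(6, 5, 4)))
        out, valid = resample_to_reference(vol, np.eye(4), vol)
        assert valid.all()
        np.testing.assert_array_equal(out.data, vol.data)

    def test_one_voxel_translation_shifts_and_invalidates_boundary(self, rng):
        vol = ImageVolume(rng.normal(size=(6, 6, 6)))
        t = np.eye(4)
        t[0, 3] = vol.voxel_size_mm[0]  # shift source +1 voxel along x
        out, valid = resample_to_reference(vol, t, vol)
        np.testing.assert_allclose(out.data[1:], vol.data[:-1], atol=1e-12)
        assert not valid[0].any()
        assert valid[1:].all()

    def test_constant_volume_invariant_under_affine(self):
        vol = ImageVolume(np.full((8, 8, 8), 3.5))
        t = np.eye(4)
        t[:3, :3] = [[0.9, 0.1, 0.0], [-0.1, 0.9, 0.0], [0.0, 0.0, 1.1]]
        t[:3, 3] = [0.3, -0.2, 0.1]
        out, valid = resample_to_reference(vol, t, vol)
        assert valid.any()
        np.testing.assert_allclose(out.data[valid], 3.5, atol=1e-9)

    def test_singular_transform_rejected(self):
        vol = ImageVolume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            resample_to_reference(vol, np.zeros((4, 4)), vol)


class TestDownsample:
    def test_constant_region_preserved(self):
        arr = np.full((8, 8, 8), 2.5)
        mask = np.ones_like(arr, dtype=bool)
        np.testing.assert_allclose(downsample_blocks(arr, mask, (2, 2, 2)), 2.5)

    def test_factor_one_is_passthrough(self, rng):
        arr = rng.normal(size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) > 0.4
        got = downsample_blocks(arr, mask, (1, 1, 1))
        assert sorted(got) == sorted(arr[mask])

    @pytest.mark.parametrize("factors", [(9, 1, 1), (0, 2, 2), (2, 2, 10)])
    def test_factor_bounds_enforced(self, factors):
        arr = np.ones((8, 8, 8))
        with pytest.raises(ValueError):
            downsample_blocks(arr, np.ones_like(arr, dtype=bool), factors)

    def test_voi_mean_preserved_for_fully_inmask_blocks(self, rng):
        # an 8x8x8 all-true mask tiles exactly into 2x2x2 blocks, so the
        # grand mean must survive block averaging exactly
        arr = rng.normal(size=(8, 8, 8))
        mask = np.ones_like(arr, dtype=bool)
        blocks = downsample_blocks(arr, mask, (2, 2, 2))
        assert blocks.mean() == pytest.approx(arr.mean(), rel=1e-12)

    def test_partial_blocks_dropped_below_fraction(self):
        arr = np.ones((4, 4, 4))
        mask = np.zeros_like(arr, dtype=bool)
        mask[:2, :2, :2] = True          # one full block
        mask[2, 2, 2] = True             # 1/8 of another block
        got = downsample_blocks(arr, mask, (2, 2, 2), min_in_mask=0.5)
        assert got.size == 1


class TestCorrelate:
    def test_perfect_line_gives_r_one(self):
        x = np.arange(1.0, 6.0)
        res = correlate(x, 2 * x + 1, transform="none")
        assert res.r == pytest.approx(1.0)
        assert res.n == 5

    def test_anticorrelation_gives_minus_one(self):
        x = np.arange(1.0, 6.0)
        res = correlate(x, -x, transform="none")
        assert res.r == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        x = rng.normal(2.0, 1.0, 8)
        y = 0.5 * x + rng.normal(0, 0.3, 8)
        res = correlate(x, y, transform="none")
        r_direct = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert res.r == pytest.approx(r_direct, rel=1e-10)
        t = r_direct * math.sqrt(6 / (1 - r_direct**2))
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), 6), rel=1e-10)

    def test_log10_excludes_nonpositive_pairwise(self):
        x = np.array([1.0, 10.0, 100.0, -1.0, 5.0])
        y = np.array([1.0, 2.0, 4.0, 3.0, 0.0])
        res = correlate(x, y, transform="log10")
        assert res.n == 3
        assert res.n_excluded == 2

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], transform="none")

    def test_region_mean_level_equals_correlating_region_means(self, rng):
        # correlating k region summaries must equal a direct Pearson on the
        # independently computed k-vector of summaries
        vols = rng.lognormal(0, 0.3, size=(6, 5, 5, 5))
        mr = rng.lognormal(0, 0.3, size=(6, 5, 5, 5))
        mask = np.ones((5, 5, 5), dtype=bool)
        pet_means = [summarize_region(v, mask, "median") for v in vols]
        mr_means = [summarize_region(v, mask, "median") for v in mr]
        res = correlate(pet_means, mr_means, level="region_mean", transform="log10")
        r_direct, _ = stats.pearsonr(np.log10(pet_means), np.log10(mr_means))
        assert res.r == pytest.approx(r_direct, rel=1e-12)
        assert res.level == "region_mean"


class TestWelch:
    def test_identical_groups_give_t_zero(self):
        res = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert 2.0 <= res.df <= 4.0

    def test_matches_closed_form(self):
        a, b = np.array([1.0, 2, 3, 4]), np.array([2.0, 4, 6, 8])
        res = welch_t(a, b)
        va, vb = a.var(ddof=1) / 4, b.var(ddof=1) / 4
        t = (a.mean() - b.mean()) / math.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 3 + vb**2 / 3)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.df == pytest.approx(df, rel=1e-12)
        assert res.p == pytest.approx(2 * stats.t.sf(abs(t), df), rel=1e-10)

    def test_satterthwaite_df_within_bounds(self, rng):
        for _ in range(25):
            a = rng.normal(0, 1, rng.integers(2, 9))
            b = rng.normal(1, 3, rng.integers(2, 9))
            res = welch_t(a, b)
            assert min(len(a), len(b)) - 1 <= res.df <= len(a) + len(b) - 2

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestRankSum:
    def test_extreme_ordering_exact_p(self):
        # {1,2} vs {3,4}: the most extreme of the 6 assignments, p = 1/3
        res = rank_sum([1.0, 2.0], [3.0, 4.0])
        assert res.statistic == pytest.approx(3.0)
        assert res.p == pytest.approx(1.0 / 3.0)

    def test_identical_singletons_give_p_one(self):
        res = rank_sum([5.0], [5.0])
        assert res.p == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        a, b = rng.normal(0, 1, 6), rng.normal(1, 1, 5)
        base = rank_sum(a, b)
        shifted = rank_sum(a + 17.3, b + 17.3)
        assert shifted.statistic == pytest.approx(base.statistic)
        assert shifted.p == pytest.approx(base.p)

    def test_exact_p_matches_brute_force_enumeration(self, rng):
        # independent oracle: enumerate every assignment of pooled midranks
        for _ in range(30):
            n1, n2 = int(rng.integers(2, 5)), int(rng.integers(2, 6))
            pooled = np.round(rng.normal(0, 1, n1 + n2), 1)  # induces ties
            a, b = pooled[:n1], pooled[n1:]
            res = rank_sum(a, b)
            ranks = stats.rankdata(pooled)
            w_obs = ranks[:n1].sum()
            sums = [sum(c) for c in itertools.combinations(ranks, n1)]
            lo = sum(s <= w_obs + 1e-9 for s in sums) / len(sums)
            hi = sum(s >= w_obs - 1e-9 for s in sums) / len(sums)
            assert res.p == pytest.approx(min(1.0, 2 * min(lo, hi)), abs=1e-12)

    def test_exact_p_matches_scipy_on_tie_free_data(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, 4)
            b = rng.normal(0.5, 1, 5)
            res = rank_sum(a, b)
            ref = stats.mannwhitneyu(a, b, method="exact", alternative="two-sided")
            assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_sample_normal_approximation_close_to_scipy(self, rng):
        a, b = rng.normal(0, 1, 20), rng.normal(0.8, 1, 18)
        res = rank_sum(a, b)
        ref = stats.ranksums(a, b)
        # ours adds a continuity correction, so demand closeness not equality
        assert res.p == pytest.approx(ref.pvalue, rel=0.2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum([], [1.0])


def test_voimask_rejects_empty():
    with pytest.raises(ValueError):
        VOIMask(np.zeros((3, 3, 3), dtype=bool), name="Pancreas^Control")
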