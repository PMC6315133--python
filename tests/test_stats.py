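"""Correlation, conjunction, FDR, voxelwise and ANOVA machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cuejudge.stats import (
    bh_fdr,
    bonferroni_threshold,
    conjunction_fdr,
    conjunction_max_p,
    fisher_independent_z,
    meng_dependent_z,
    mixed_anova_interaction,
    pearson_correlation,
    sphere_average,
    voxelwise_correlation,
    voxelwise_one_sample_t,
    voxelwise_two_sample_t,
)
from cuejudge.volumes import StatVolume


class TestPearson:
    def test_perfect_positive(self):
        res = pearson_correlation([1, 2, 3, 4], [3, 5, 7, 9])
        assert res.r == pytest.approx(1.0)

    def test_perfect_negative(self):
        res = pearson_correlation([1, 2, 3, 4], [-1, -2, -3, -4])
        assert res.r == pytest.approx(-1.0)

    def test_hand_value(self):
        res = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.r == pytest.approx(0.8)

    def test_one_tailed_halves_p(self):
        two = pearson_correlation([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], tails="two")
        one = pearson_correlation([1, 2, 3, 4, 5], [1, 3, 2, 5, 4], tails="one")
        assert one.p == pytest.approx(two.p / 2)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1, 1], [1, 2, 3, 4])


class TestMengDependentZ:
    def test_equal_correlations_give_zero(self):
        res = meng_dependent_z(0.4, 0.4, 0.3, n=74)
        assert res.z == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a = meng_dependent_z(0.5, 0.3, 0.2, n=100)
        b = meng_dependent_z(0.3, 0.5, 0.2, n=100)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_against_independent_formula(self):
        """Direct re-evaluation of the published closed form."""
        r_jk, r_jh, r_kh, n = 0.5, 0.3, 0.2, 100
        rbar2 = (r_jk**2 + r_jh**2) / 2
        f = min((1 - r_kh) / (2 * (1 - rbar2)), 1.0)
        h = (1 - f * rbar2) / (1 - rbar2)
        z_expect = (np.arctanh(r_jk) - np.arctanh(r_jh)) * math.sqrt(
            (n - 3) / (2 * (1 - r_kh) * h)
        )
        res = meng_dependent_z(r_jk, r_jh, r_kh, n=n)
        assert res.z == pytest.approx(z_expect)
        assert res.p_two_tailed == pytest.approx(2 * sps.norm.sf(abs(z_expect)))

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(ValueError):
            meng_dependent_z(0.9, -0.9, 0.9, n=50)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            meng_dependent_z(0.5, 0.3, 0.2, n=3)


class TestFisherIndependentZ:
    def test_equal_correlations_give_zero(self):
        assert fisher_independent_z(0.4, 50, 0.4, 60).z == 0.0

    def test_sign_flips_with_groups(self):
        a = fisher_independent_z(0.5, 50, 0.2, 50)
        b = fisher_independent_z(0.2, 50, 0.5, 50)
        assert a.z == pytest.approx(-b.z)

    def test_closed_form_value(self):
        z_expect = (np.arctanh(0.5) - np.arctanh(0.2)) / math.sqrt(1 / 47 + 1 / 47)
        res = fisher_independent_z(0.5, 50, 0.2, 50)
        assert res.z == pytest.approx(z_expect)

    def test_degenerate_r_rejected(self):
        with pytest.raises(ValueError):
            fisher_independent_z(1.0, 50, 0.2, 50)


def brute_force_bh(p, q):
    """Independent step-up scan over all candidate thresholds i*q/m."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * q / m:
            k = i
    mask = np.zeros(m, dtype=bool)
    mask[order[:k]] = True
    return mask


class TestBHFDR:
    def test_all_ones_no_rejections(self):
        mask, crit = bh_fdr([1.0] * 6, 0.05)
        assert not mask.any() and crit == 0.0

    def test_uniform_grid_all_rejected(self):
        mask, crit = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], 0.05)
        assert mask.all()
        assert crit == pytest.approx(0.05)

    def test_single_p_reduces_to_threshold(self):
        mask, _ = bh_fdr([0.04], 0.05)
        assert mask.all()
        mask, _ = bh_fdr([0.06], 0.05)
        assert not mask.any()

    @given(
        st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
        st.sampled_from([0.01, 0.05, 0.1, 0.2]),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_step_up(self, p, q):
        mask, _ = bh_fdr(p, q)
        assert np.array_equal(mask, brute_force_bh(p, q))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([], 0.05)


def pvol(data, **kw):
    return StatVolume(np.asarray(data, dtype=float), kind="p", **kw)


class TestConjunction:
    def test_elementwise_max(self):
        a = pvol(np.full((1, 1, 2), [[[0.01, 0.2]]]))
        b = pvol(np.full((1, 1, 2), [[[0.05, 0.1]]]))
        out = conjunction_max_p([a, b])
        assert np.allclose(out.data.ravel(), [0.05, 0.2])

    def test_idempotent_commutative_associative(self, rng):
        vols = [pvol(rng.uniform(size=(3, 3, 3))) for _ in range(3)]
        same = conjunction_max_p([vols[0], vols[0]])
        assert np.array_equal(same.data, vols[0].data)
        ab = conjunction_max_p([vols[0], vols[1]])
        ba = conjunction_max_p([vols[1], vols[0]])
        assert np.array_equal(ab.data, ba.data)
        abc1 = conjunction_max_p([conjunction_max_p([vols[0], vols[1]]), vols[2]])
        abc2 = conjunction_max_p([vols[0], conjunction_max_p([vols[1], vols[2]])])
        assert np.array_equal(abc1.data, abc2.data)

    def test_output_dominates_inputs(self, rng):
        vols = [pvol(rng.uniform(size=(4, 4, 4))) for _ in range(4)]
        out = conjunction_max_p(vols)
        for v in vols:
            assert np.all(out.data >= v.data)

    def test_grid_mismatch_rejected(self, rng):
        a = pvol(rng.uniform(size=(3, 3, 3)))
        b = pvol(rng.uniform(size=(4, 4, 4)))
        with pytest.raises(ValueError):
            conjunction_max_p([a, b])

    def test_all_ones_volume_kills_significance(self, rng):
        a = pvol(rng.uniform(size=(4, 4, 4)) * 1e-4)
        b = pvol(np.ones((4, 4, 4)))
        res = conjunction_fdr([a, b], q=0.05)
        assert res.n_significant == 0

    def test_planted_overlap_region_recovered(self):
        """Power check: d = 1.5, n = 20 per group, shared active region.

        The region counts as recovered when at least 90% of its voxels
        survive the conjunction FDR threshold and false alarms stay rare.
        """
        from cuejudge.simulate import simulate_stat_volumes

        shape = (10, 10, 10)
        mask = np.zeros(shape, bool)
        mask[4:7, 4:7, 4:7] = True
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            groups = simulate_stat_volumes(shape, [mask, mask], 1.5, 20, seed=seed)
            p_vols = [voxelwise_one_sample_t(g)[1] for g in groups]
            res = conjunction_fdr(p_vols, q=0.05)
            recovered = res.mask[mask].mean() >= 0.9
            clean = res.mask[~mask].sum() <= 0.05 * res.n_significant + 1
            hits += bool(recovered and clean)
        assert hits >= 0.9 * n_seeds


class TestVoxelwiseT:
    def test_null_p_distribution_uniform(self):
        gen = np.random.default_rng(0)
        a = gen.normal(size=(15, 6, 6, 6))
        b = gen.normal(size=(15, 6, 6, 6))
        _, p = voxelwise_two_sample_t(a, b)
        assert sps.kstest(p.data.ravel(), "uniform").pvalue > 0.01

    def test_t_sign_matches_mean_shift(self):
        gen = np.random.default_rng(1)
        a = gen.normal(2.0, 1.0, size=(50, 2, 2, 2))
        b = gen.normal(0.0, 1.0, size=(50, 2, 2, 2))
        t, _ = voxelwise_two_sample_t(a, b)
        assert np.all(t.data > 0)

    def test_matches_per_voxel_textbook_computation(self, rng):
        a = rng.normal(size=(8, 3, 3, 3))
        b = rng.normal(size=(10, 3, 3, 3))
        t, p = voxelwise_two_sample_t(a, b)
        for idx in np.ndindex(3, 3, 3):
            res = sps.ttest_ind(a[(slice(None), *idx)], b[(slice(None), *idx)])
            assert t.data[idx] == pytest.approx(res.statistic)
            assert p.data[idx] == pytest.approx(res.pvalue)

    def test_zero_variance_voxel_flagged_p_one(self):
        a = np.ones((5, 2, 2, 2))
        b = np.ones((5, 2, 2, 2))
        t, p = voxelwise_two_sample_t(a, b)
        assert np.all(t.data == 0.0)
        assert np.all(p.data == 1.0)


class TestVoxelwiseCorrelation:
    def test_injected_covariate_attains_unit_correlation(self, rng):
        cov = rng.normal(size=12)
        vols = rng.normal(size=(12, 3, 3, 3))
        vols[:, 1, 1, 1] = 2.0 * cov + 3.0
        r, p = voxelwise_correlation(vols, cov)
        assert r.data[1, 1, 1] == pytest.approx(1.0)

    def test_matches_looped_pearson(self, rng):
        cov = rng.normal(size=10)
        vols = rng.normal(size=(10, 2, 2, 2))
        r, p = voxelwise_correlation(vols, cov)
        from cuejudge.stats import pearson_correlation

        for idx in np.ndindex(2, 2, 2):
            res = pearson_correlation(vols[(slice(None), *idx)], cov)
            assert r.data[idx] == pytest.approx(res.r)
            assert p.data[idx] == pytest.approx(res.p)

    def test_permuted_covariate_null_uniform(self):
        gen = np.random.default_rng(2)
        cov = gen.normal(size=30)
        vols = gen.normal(size=(30, 6, 6, 6))
        _, p = voxelwise_correlation(vols, cov)
        assert sps.kstest(p.data.ravel(), "uniform").pvalue > 0.01

    def test_constant_covariate_rejected(self, rng):
        with pytest.raises(ValueError):
            voxelwise_correlation(rng.normal(size=(8, 2, 2, 2)), np.ones(8))


class TestSphereAverage:
    def test_constant_volume(self):
        vol = StatVolume(np.full((5, 5, 5), 7.0), voxel_size=2.0)
        res = sphere_average(vol, center_mm=(4, 4, 4), radius_mm=5.0)
        assert res.value == 7.0

    def test_tiny_radius_selects_single_voxel(self, rng):
        data = rng.normal(size=(5, 5, 5))
        vol = StatVolume(data, voxel_size=2.0)
        res = sphere_average(vol, center_mm=(4, 4, 4), radius_mm=1.0)
        assert res.n_voxels == 1
        assert res.value == pytest.approx(data[2, 2, 2])

    def test_plus_shaped_neighborhood(self, rng):
        """Radius = voxel size selects the 7-voxel face neighborhood."""
        data = rng.normal(size=(3, 3, 3))
        vol = StatVolume(data, voxel_size=2.0)
        res = sphere_average(vol, center_mm=(2, 2, 2), radius_mm=2.0)
        assert res.n_voxels == 7
        neigh = [data[1, 1, 1], data[0, 1, 1], data[2, 1, 1],
                 data[1, 0, 1], data[1, 2, 1], data[1, 1, 0], data[1, 1, 2]]
        assert res.value == pytest.approx(np.mean(neigh))

    def test_center_outside_grid_rejected(self):
        vol = StatVolume(np.zeros((3, 3, 3)), voxel_size=2.0)
        with pytest.raises(ValueError):
            sphere_average(vol, center_mm=(100, 0, 0), radius_mm=2.0)


def difference_score_t_squared(values, groups):
    """Algebraic oracle: interaction F = t^2 on within-subject differences."""
    d = values[:, 0] - values[:, 1]
    labels = np.unique(groups)
    t = sps.ttest_ind(d[groups == labels[0]], d[groups == labels[1]], equal_var=True)
    return t.statistic**2, t.pvalue


class TestMixedAnova:
    def test_interaction_equals_difference_score_t_squared(self, rng):
        for _ in range(5):
            n = 16
            values = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            groups = np.repeat(["a", "b"], n // 2)
            values[groups == "b", 1] += rng.uniform(0, 2)
            res = mixed_anova_interaction(values, groups)
            F_expect, p_expect = difference_score_t_squared(values, groups)
            assert res.F == pytest.approx(F_expect, rel=1e-6)
            assert res.p == pytest.approx(p_expect, rel=1e-6)

    def test_identical_within_levels_zero_interaction(self):
        values = np.column_stack([np.arange(10.0), np.arange(10.0)])
        groups = np.repeat(["a", "b"], 5)
        res = mixed_anova_interaction(values, groups)
        assert res.F == 0.0

    def test_strong_groupwise_difference_shift_is_significant(self, rng):
        n = 20
        values = np.tile(rng.normal(size=(n, 1)), (1, 2)) + rng.normal(size=(n, 2)) * 0.1
        groups = np.repeat(["a", "b"], n // 2)
        values[groups == "b", 1] += 5.0
        res = mixed_anova_interaction(values, groups)
        assert res.p < 1e-6

    def test_missing_cells_rejected(self):
        with pytest.raises(ValueError):
            mixed_anova_interaction(np.zeros((4, 2)), ["a", "a", "a", "b"])


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha, m, expected", [(0.05, 1, 0.05), (0.05, 2, 0.025), (0.05, 8, 0.00625)]
    )
    def test_threshold(self, alpha, m, expected):
        assert bonferroni_threshold(alpha, m) == pytest.approx(expected)

    def test_invalid_family_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
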