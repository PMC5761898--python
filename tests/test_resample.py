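"""Core subsampling, out-of-bag differences, block pooling, ROC, loess."""

import math

import numpy as np
import pytest

import tilsampling as ts
from tilsampling.resample import loess_fit


class TestSlideReference:
    def test_two_point_formula(self):
        ref = ts.slide_reference([2.0, 4.0])
        assert ref.core_mean == 3.0
        assert ref.core_sd == pytest.approx(math.sqrt(2.0))

    def test_constant_set(self):
        ref = ts.slide_reference([5.0, 5.0, 5.0])
        assert (ref.core_mean, ref.core_sd) == (5.0, 0.0)

    def test_single_core_sd_undefined(self):
        ref = ts.slide_reference([7.0])
        assert ref.core_mean == 7.0
        assert math.isnan(ref.core_sd)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ts.slide_reference([])


class TestSubsampleCores:
    def test_constant_cores_trivial_statistics(self):
        v = [5.0] * 20
        s = ts.subsample_cores(v, k=3, n_reps=100, seed=1)
        assert np.all(s.estimates == 5.0)
        assert s.within_1sd_rate == 1.0
        assert np.all(s.oob_diffs == 0.0)

    def test_exhaustive_single_core_within_1sd_rate(self):
        """k = 1 over 16 known cores: the within-1-SD rate converges to the
        exact fraction of cores within 1 SD of the mean (enumeration)."""
        rng = np.random.default_rng(2)
        v = rng.uniform(0, 20, 16)
        mean, sd = v.mean(), v.std(ddof=1)
        exact = np.mean(np.abs(v - mean) <= sd)
        n_reps = 8000
        s = ts.subsample_cores(v, k=1, n_reps=n_reps, seed=3)
        se = math.sqrt(exact * (1 - exact) / n_reps)
        assert abs(s.within_1sd_rate - exact) < 4 * se

    def test_oob_mean_difference_unbiased(self):
        rng = np.random.default_rng(4)
        v = rng.gamma(2.0, 3.0, 40)
        s = ts.subsample_cores(v, k=2, n_reps=2000, seed=5)
        se = s.oob_diff_sd / math.sqrt(s.n_reps)
        assert abs(s.oob_diff_mean) < 4 * se

    def test_max_summary_dominates_mean_summary(self):
        """Same seed means the same draws, so the max of each drawn set is
        >= its mean, replicate by replicate."""
        rng = np.random.default_rng(6)
        v = rng.uniform(0, 30, 25)
        s_mean = ts.subsample_cores(v, k=3, summary_stat="mean", n_reps=500, seed=7)
        s_max = ts.subsample_cores(v, k=3, summary_stat="max", n_reps=500, seed=7)
        assert np.all(s_max.estimates >= s_mean.estimates)
        # and the max summary is biased upward relative to the core mean
        assert s_max.estimates.mean() >= v.mean()

    def test_restriction_and_argument_errors(self):
        v = list(range(10))
        with pytest.raises(ValueError):
            ts.subsample_cores(v, k=1)  # < 15 cores in restricted mode
        with pytest.raises(ValueError):
            ts.subsample_cores(v, k=10, restricted=False)  # empty out-of-bag
        with pytest.raises(ValueError):
            ts.subsample_cores(v, k=0, restricted=False)
        s = ts.subsample_cores(v, k=1, restricted=False, n_reps=50, seed=8)
        assert s.n_reps == 50

    def test_identical_seed_identical_draws(self):
        v = np.arange(20.0)
        a = ts.subsample_cores(v, k=2, n_reps=100, seed=9)
        b = ts.subsample_cores(v, k=2, n_reps=100, seed=9)
        assert np.array_equal(a.estimates, b.estimates)
        assert np.array_equal(a.oob_diffs, b.oob_diffs)


class TestBlockPool:
    def test_pooled_mean(self):
        pooled, ref = ts.block_pool([[2.0, 4.0], [6.0, 8.0]])
        assert ref.core_mean == 5.0
        assert pooled.tolist() == [2.0, 4.0, 6.0, 8.0]

    def test_single_slide_degenerates_to_slide_reference(self):
        pooled, ref = ts.block_pool([[1.0, 3.0, 5.0]])
        direct = ts.slide_reference([1.0, 3.0, 5.0])
        assert ref.core_mean == direct.core_mean
        assert ref.core_sd == direct.core_sd

    def test_pooled_sd_matches_direct_recomputation(self):
        rng = np.random.default_rng(10)
        slides = [rng.uniform(0, 10, n) for n in (5, 9, 3)]
        pooled, ref = ts.block_pool(slides)
        flat = np.concatenate(slides)
        assert ref.core_sd == pytest.approx(flat.std(ddof=1), abs=1e-12)

    def test_cell_weighted_option(self):
        slides = [([10.0, 20.0], [100, 300])]
        _, ref = ts.block_pool(slides, weights="cells")
        assert ref.core_mean == pytest.approx(17.5)

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            ts.block_pool([[]])


class TestRoc:
    def test_single_class_cohort_flags_sensitivity(self):
        units = {"a": np.full(16, 1.0), "b": np.full(16, 2.0)}
        pts = ts.roc_over_cutoffs(units, ks=(1,), summary_stats=("mean",),
                                  cutoffs=(50.0,), n_reps=50, seed=1)
        (p,) = pts
        assert math.isnan(p.sensitivity)
        assert p.specificity == 100.0
        assert p.accuracy == 100.0

    def test_exhaustive_draw_with_mean_is_perfect(self):
        rng = np.random.default_rng(2)
        units = {u: rng.uniform(0, 20, 16) for u in "abcd"}
        pts = ts.roc_over_cutoffs(units, ks=(16,), summary_stats=("mean",),
                                  cutoffs=(1.0, 5.0, 10.0), n_reps=20, seed=3,
                                  restricted=False)
        for p in pts:
            for metric in (p.sensitivity, p.specificity, p.accuracy):
                if not math.isnan(metric):
                    assert metric == 100.0

    def test_two_unit_enumeration_oracle(self):
        """k = 1 draws are uniform over each unit's cores, so sensitivity
        and specificity follow from direct enumeration."""
        units = {"hi": np.array([4.0, 8.0]), "lo": np.array([2.0, 6.0])}
        # truths: hi = 6 (>= 5), lo = 4 (< 5) at the 5% cutoff
        # hi draws: 4 (miss), 8 (hit)  -> E[sens] = 50%
        # lo draws: 2 (hit),  6 (miss) -> E[spec] = 50%
        n_reps = 4000
        pts = ts.roc_over_cutoffs(units, ks=(1,), summary_stats=("mean",),
                                  cutoffs=(5.0,), n_reps=n_reps, seed=4,
                                  restricted=False)
        (p,) = pts
        se = 100 * math.sqrt(0.25 / n_reps)
        assert abs(p.sensitivity - 50.0) < 4 * se
        assert abs(p.specificity - 50.0) < 4 * se

    def test_empty_units_rejected(self):
        with pytest.raises(ValueError):
            ts.roc_over_cutoffs({}, n_reps=10)
        with pytest.raises(ValueError):
            ts.roc_over_cutoffs({"a": np.arange(3.0)}, ks=(1,), n_reps=10)


class TestLoess:
    def test_reproduces_a_line_exactly(self):
        x = np.linspace(0, 10, 30)
        y = 2.5 * x - 4.0
        grid, fitted = loess_fit(x, y, span=0.5)
        assert np.allclose(fitted, 2.5 * grid - 4.0, atol=1e-8)

    def test_reproduces_a_quadratic_exactly(self):
        x = np.linspace(-3, 3, 25)
        y = x**2 - x + 1
        grid, fitted = loess_fit(x, y, span=0.7)
        assert np.allclose(fitted, grid**2 - grid + 1, atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loess_fit([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            loess_fit(np.arange(10), np.arange(10), span=0.0)

    def test_single_grid_point_matches_direct_wls_oracle(self):
        """One evaluation checked against an independent tricube-weighted
        normal-equations solve."""
        rng = np.random.default_rng(11)
        x = np.sort(rng.uniform(0, 10, 20))
        y = np.sin(x) + 0.1 * rng.normal(size=20)
        x0 = 4.321
        span = 0.6
        _, fitted = loess_fit(x, y, span=span, grid=np.array([x0]))

        q = math.ceil(span * len(x))
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:q]
        w = (1 - (d[idx] / d[idx].max()) ** 3) ** 3
        X = np.column_stack([np.ones(q), x[idx] - x0, (x[idx] - x0) ** 2])
        W = np.diag(w)
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[idx])
        assert fitted[0] == pytest.approx(beta[0], abs=1e-8)

    def test_sd_curve_log2_scale_handles_zero_means(self):
        pts = [(0.0, 1.0), (1.0, 1.2), (2.0, 0.9), (5.0, 1.5),
               (8.0, 1.1), (12.0, 1.3), (20.0, 1.0)]
        out = ts.loess_sd_curve(pts, scale="log2", n_grid=10)
        assert np.isfinite(out["fitted_sd"]).all()
        assert out["grid"].iloc[0] == pytest.approx(np.log2(0.1))
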