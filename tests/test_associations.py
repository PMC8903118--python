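"""Tertiles, category-table tests, OLS with state fixed effects, LR, mixed model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import overuse_index as oi
from overuse_index.associations import (
    category_row_percentages,
    category_table,
    fit_mixed_state_re,
    fit_ols_state_fe,
    lr_test,
    make_tertiles,
    mh_trend_test,
    unadjusted_chi2,
    upper_quartile_flag,
)
from overuse_index.index import build_index_table


class TestTertiles:
    def test_six_point_example(self):
        labels, cuts = make_tertiles([1, 2, 3, 4, 5, 6])
        assert list(labels) == [1, 1, 2, 2, 3, 3]
        assert cuts == (2.0, 4.0)

    def test_balanced_sizes_without_ties(self):
        rng = np.random.default_rng(1)
        v = rng.permutation(90).astype(float)
        labels, _ = make_tertiles(v)
        sizes = pd.Series(labels).value_counts()
        assert sizes.max() - sizes.min() <= 1

    def test_tied_vector_matches_enumeration_oracle(self):
        v = [1, 1, 1, 1, 2, 9]
        labels, _ = make_tertiles(v)
        # type-1 quantiles by direct order statistics: q1 = x_(ceil(n/3)), q2 = x_(ceil(2n/3))
        srt = sorted(v)
        q1 = srt[int(np.ceil(len(v) / 3)) - 1]
        q2 = srt[int(np.ceil(2 * len(v) / 3)) - 1]
        expect = [1 if x <= q1 else (2 if x <= q2 else 3) for x in v]
        assert list(labels) == expect

    def test_missing_labelled_zero(self):
        labels, _ = make_tertiles([1, 2, 3, None, 5, 6])
        assert labels[3] == 0

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            make_tertiles([4, 4, 4, 4])


class TestUpperQuartile:
    def test_four_point_example(self):
        assert list(upper_quartile_flag([1, 2, 3, 4])) == [False, False, False, True]

    def test_constant_all_false(self):
        assert not upper_quartile_flag([2, 2, 2, 2]).any()

    def test_skewed_matches_enumeration(self):
        v = [1, 1, 2, 2, 3, 50, 100, 4]
        srt = sorted(v)
        q3 = srt[int(np.ceil(0.75 * len(v))) - 1]
        assert list(upper_quartile_flag(v)) == [x > q3 for x in v]


class TestChi2:
    def test_identical_rows_statistic_zero(self):
        cats = [1, 2, 3, 4, 5] * 8
        groups = ["a"] * 20 + ["b"] * 20
        stat, df, p = unadjusted_chi2(cats, groups)
        assert stat == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_two_by_two_closed_form(self):
        # [[10,20],[20,10]]: all margins 30, E=15 -> chi2 = 4*25/15 = 20/3
        cats = [1] * 10 + [2] * 20 + [1] * 20 + [2] * 10
        groups = ["a"] * 30 + ["b"] * 30
        stat, df, _ = unadjusted_chi2(cats, groups)
        assert stat == pytest.approx(20 / 3)
        assert df == 1

    def test_df_for_three_by_five(self):
        rng = np.random.default_rng(2)
        cats = rng.integers(1, 6, 600)
        groups = rng.choice(["a", "b", "c"], 600)
        _, df, _ = unadjusted_chi2(cats, groups)
        assert df == 8

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        cats = rng.integers(1, 6, 200)
        flags = rng.integers(0, 2, 200)
        s1 = unadjusted_chi2(cats, flags)[0]
        perm = rng.permutation(200)
        s2 = unadjusted_chi2(cats[perm], flags[perm])[0]
        assert s1 == pytest.approx(s2)


class TestMHTrend:
    def test_flat_proportions_near_zero(self):
        cats = np.repeat([1, 2, 3, 4, 5], 40)
        flag = np.tile([0, 1], 100)
        stat, p = mh_trend_test(flag, cats)
        assert stat < 1e-10

    def test_monotone_proportions_significant(self):
        rng = np.random.default_rng(4)
        cats = np.repeat([1, 2, 3, 4, 5], 100)
        flag = rng.random(500) < (0.1 + 0.15 * (cats - 1))
        stat, p = mh_trend_test(flag, cats)
        assert p < 0.05

    def test_matches_score_correlation_formula(self):
        # fixture: per-category (n, n_flagged) = (10,1),(10,3),(10,5),(10,7)
        cats = np.repeat([1, 2, 3, 4], 10)
        flag = np.concatenate([np.r_[np.ones(k), np.zeros(10 - k)] for k in (1, 3, 5, 7)])
        n = len(flag)
        # raw-sum computation of (n-1) r^2, independent of np.corrcoef
        sx, sy = flag.sum(), cats.sum()
        sxx, syy, sxy = (flag**2).sum(), (cats**2).sum(), (flag * cats).sum()
        r2 = (n * sxy - sx * sy) ** 2 / ((n * sxx - sx**2) * (n * syy - sy**2))
        stat, _ = mh_trend_test(flag, cats)
        assert stat == pytest.approx((n - 1) * r2)

    def test_label_swap_preserves_statistic(self):
        rng = np.random.default_rng(5)
        cats = rng.integers(1, 6, 300)
        flag = (rng.random(300) < 0.2 + 0.1 * cats).astype(int)
        s1, _ = mh_trend_test(flag, cats)
        s2, _ = mh_trend_test(1 - flag, cats)
        assert s1 == pytest.approx(s2)

    def test_constant_flag_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            mh_trend_test(np.ones(20), np.repeat([1, 2], 10))


def _truth_index_table(structure):
    """Index table built from the generator's true tendencies (no model fit)."""
    phi = pd.Series(structure.truth.system_tendencies)
    return build_index_table(phi)


class TestOLS:
    def test_intercept_only_recovers_zero_mean(self):
        s = oi.generate_structure(n_systems=40, seed=6)
        idx = _truth_index_table(s)
        res = fit_ols_state_fe(idx, s.characteristics, covariates=[], state_col=None)
        assert res.table.estimate.iloc[0] == pytest.approx(0.0, abs=1e-10)
        assert res.n_systems == 40

    def test_recovers_planted_tertile_effect_on_raw_scale(self):
        s = oi.generate_structure(n_systems=200, seed=7)
        idx = _truth_index_table(s)
        chars = oi.prepare_association_features(s.characteristics)
        res = fit_ols_state_fe(
            idx, chars,
            covariates=["pcp_tertile", "investor_owned", "major_teaching"],
            response="raw_phi",
        )
        t3 = res.table.set_index("name").loc["pcp_tertile[3]"]
        assert abs(t3.estimate - (-0.6)) < 1.96 * t3.se

    def test_noise_flag_ci_covers_zero_in_most_replicates(self):
        cover = 0
        for rep in range(50):
            s = oi.generate_structure(n_systems=60, seed=100 + rep)
            idx = _truth_index_table(s)
            chars = s.characteristics.copy()
            rng = np.random.default_rng(500 + rep)
            chars["noise_flag"] = rng.random(len(chars)) < 0.5
            res = fit_ols_state_fe(idx, chars, covariates=["noise_flag"], state_col=None,
                                   response="raw_phi")
            row = res.table.set_index("name").loc["noise_flag"]
            if abs(row.estimate) <= 1.96 * row.se:
                cover += 1
        assert cover >= 45  # >= 90% of 50

    def test_rank_deficiency_drops_column_with_warning(self):
        s = oi.generate_structure(n_systems=30, seed=8)
        chars = s.characteristics.copy()
        chars["copy_flag"] = chars["investor_owned"]
        idx = _truth_index_table(s)
        with pytest.warns(UserWarning, match="rank-deficient"):
            res = fit_ols_state_fe(idx, chars, covariates=["investor_owned", "copy_flag"],
                                   state_col=None)
        assert "copy_flag" not in set(res.table.name)


class TestLRTest:
    def _fits(self, n=60, seed=9, extra_is_noise=True):
        rng = np.random.default_rng(seed)
        idx = pd.DataFrame(
            {"system_id": [f"S{i}" for i in range(n)], "raw_phi": rng.normal(0, 1, n)}
        )
        idx["oi"] = (idx.raw_phi - idx.raw_phi.mean()) / idx.raw_phi.std(ddof=1)
        chars = pd.DataFrame(
            {"system_id": idx.system_id, "flag": rng.random(n) < 0.5}
        )
        r = fit_ols_state_fe(idx, chars, covariates=[], state_col=None)
        f = fit_ols_state_fe(idx, chars, covariates=["flag"], state_col=None)
        return r, f

    def test_identical_specs_zero_statistic(self):
        r, _ = self._fits()
        stat, df, p = lr_test(r, r)
        assert stat == 0.0 and p == 1.0

    def test_closed_form_n_log_rss_ratio(self):
        r, f = self._fits()
        stat, df, _ = lr_test(r, f)
        n = r.n_systems
        expect = n * np.log(r.extra["rss"] / f.extra["rss"])
        assert stat == pytest.approx(expect, rel=1e-10)
        assert df == 1

    def test_null_distribution_is_chi2_one(self):
        stats_ = []
        for rep in range(200):
            r, f = self._fits(n=50, seed=1000 + rep)
            stats_.append(lr_test(r, f)[0])
        ks = stats.kstest(stats_, stats.chi2(1).cdf)
        assert ks.pvalue > 0.01

    def test_nonnested_rejected(self):
        r, f = self._fits()
        with pytest.raises(ValueError):
            lr_test(f, r)  # reversed: full has fewer params than "restricted"


class TestMixedState:
    def test_zero_state_variance_matches_ols(self):
        s = oi.generate_structure(n_systems=120, seed=10, state_effect_sd=0.0)
        idx = _truth_index_table(s)
        chars = oi.prepare_association_features(s.characteristics)
        covs = ["pcp_tertile", "investor_owned"]
        ols = fit_ols_state_fe(idx, chars, covariates=covs, state_col=None, response="raw_phi")
        mix = fit_mixed_state_re(idx, chars, covariates=covs, response="raw_phi")
        a = ols.table.set_index("name").estimate
        b = mix.table.set_index("name").estimate
        assert np.abs(a - b).max() < 0.05
        assert mix.extra["state_variance"] < 0.02

    def test_state_variance_recovered(self):
        s = oi.generate_structure(n_systems=300, seed=11, state_effect_sd=0.5)
        idx = _truth_index_table(s)
        chars = oi.prepare_association_features(s.characteristics)
        mix = fit_mixed_state_re(idx, chars, covariates=["pcp_tertile"], response="raw_phi")
        # truth 0.25; sampling SE with 12 states is roughly var*sqrt(2/12) ~ 0.10
        assert 0.25 - 3 * 0.10 < mix.extra["state_variance"] < 0.25 + 3 * 0.10

    def test_sign_concordance_with_ols(self):
        s = oi.generate_structure(n_systems=200, seed=12, state_effect_sd=0.3)
        idx = _truth_index_table(s)
        chars = oi.prepare_association_features(s.characteristics)
        covs = ["pcp_tertile", "major_teaching"]
        ols = fit_ols_state_fe(idx, chars, covariates=covs, response="raw_phi")
        mix = fit_mixed_state_re(idx, chars, covariates=covs, response="raw_phi")
        a = ols.table.set_index("name").estimate
        b = mix.table.set_index("name").estimate
        common = a.index.intersection(b.index).drop("intercept")
        a, b = a[common], b[common]
        big = common[np.abs(a) > 0.1]
        assert (np.sign(a[big]) == np.sign(b[big])).all()


class TestCategoryTable:
    def test_counts_and_percentages(self):
        cats = [1, 3, 3, 4, 4, 4, 5]
        flags = [True] * 7
        tab = category_table(cats, flags)
        assert tab.loc[True].tolist() == [1, 0, 2, 3, 1]
        pct = category_row_percentages(tab)
        assert pct.loc[True, 4] == pytest.approx(300 / 7)
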