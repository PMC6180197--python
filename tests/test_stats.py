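"""Nonparametric battery: rank tests vs exact enumeration, FDR, resampling,
and the full cohort analysis (planted effects, error control)."""

import numpy as np
import pytest

import fractalbold as fb
from fractalbold.errors import (
    AllTies,
    BadPValue,
    DegenerateGroups,
    EmptyGroup,
    EmptyInput,
    IncompleteCohort,
    LengthMismatch,
    NegativeCount,
    SingleClass,
    TooFewValues,
    ZeroVariance,
)
from fractalbold.stats import CohortTable
from conftest import flat_h_means, table_from_truth
from helpers import exact_mannwhitney_p, exact_wilcoxon_p


class TestPhenotypeClassification:
    @pytest.mark.parametrize("count,label", [(0, "lowImp"), (2, "lowImp"),
                                             (3, "highImp"), (6, "highImp")])
    def test_threshold_rule(self, count, label):
        assert fb.classify_phenotype(count) == label

    def test_negative_count(self):
        with pytest.raises(NegativeCount):
            fb.classify_phenotype(-1)

    @pytest.mark.parametrize("counts,expected", [
        ([0, 1, 3, 5], 2),       # median 2.0
        ([3, 3, 3], 3),
        ([0, 1, 2, 3], 2),       # median 1.5 -> ceil 2
    ])
    def test_median_threshold(self, counts, expected):
        assert fb.median_threshold(counts) == expected

    def test_median_threshold_empty(self):
        with pytest.raises(EmptyInput):
            fb.median_threshold([])


class TestWilcoxon:
    def test_symmetric_values_give_large_p(self):
        values = [1 + d for d in (-0.3, 0.3, -0.2, 0.2, -0.1, 0.1, -0.4, 0.4)]
        res = fb.wilcoxon_one_sample(values, 1.0)
        assert res.p >= 0.9
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_ties_raises(self):
        with pytest.raises(AllTies):
            fb.wilcoxon_one_sample([1.0] * 10, 1.0)

    def test_exact_p_matches_sign_enumeration(self):
        """n = 8 tie-free sample: p equals the 2^8 enumeration oracle."""
        d = np.array([0.5, -0.2, 0.9, 1.4, -0.7, 0.3, 1.1, -1.6])
        res = fb.wilcoxon_one_sample(1.0 + d, 1.0)
        assert res.p == pytest.approx(exact_wilcoxon_p(d), abs=1e-10)

    def test_large_sample_uses_normal_approximation(self, rng):
        values = 1.0 + 0.1 * rng.standard_normal(103)
        res = fb.wilcoxon_one_sample(values, 1.0)
        # approx path: p consistent with reported Z
        from scipy.stats import norm
        assert res.p == pytest.approx(2 * norm.sf(abs(res.statistic)), rel=1e-9)

    def test_paired_requires_equal_lengths(self):
        with pytest.raises(LengthMismatch):
            fb.wilcoxon_paired([1, 2, 3], [1, 2])

    def test_paired_identical_samples_raise(self):
        with pytest.raises(AllTies):
            fb.wilcoxon_paired([1.0, 2.0, 3.0] * 3, [1.0, 2.0, 3.0] * 3)

    def test_paired_constant_shift_is_detected(self, rng):
        a = rng.standard_normal(40)
        res = fb.wilcoxon_paired(a + 1.0, a)
        assert res.p < 1e-6

    def test_paired_exact_enumeration(self):
        a = np.array([0.1, 0.7, -0.3, 0.9, 0.4, -0.6, 1.2, 0.2])
        b = np.array([0.0, 0.25, 0.1, 0.35, -0.1, 0.13, 0.45, -0.48])
        res = fb.wilcoxon_paired(a, b)
        assert res.p == pytest.approx(exact_wilcoxon_p(a - b), abs=1e-10)


class TestMannWhitney:
    def test_identical_multisets_are_indistinguishable(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        res = fb.mannwhitney_u(a, list(a))
        assert res.extra["U"] == pytest.approx(len(a) ** 2 / 2)
        assert res.p > 0.9

    def test_complete_separation(self):
        res = fb.mannwhitney_u([1, 2, 3, 4, 5], [10, 11, 12, 13, 14])
        assert res.extra["U"] == 0.0
        # minimal two-sided exact p for 5 vs 5: 2 / C(10,5)
        assert res.p == pytest.approx(2 / 252, abs=1e-12)

    def test_exact_p_matches_labeling_enumeration(self):
        a = np.array([0.3, 1.9, -0.4, 2.2, 0.8])
        b = np.array([1.1, -0.9, 0.1, 2.7, -1.3])
        res = fb.mannwhitney_u(a, b)
        assert res.p == pytest.approx(exact_mannwhitney_p(a, b), abs=1e-10)

    def test_empty_group(self):
        with pytest.raises(EmptyGroup):
            fb.mannwhitney_u([], [1.0])


class TestCorrelationAnova:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        res = fb.pearson_corr(x, 2 * x + 3)
        assert res.statistic == pytest.approx(1.0)

    def test_orthogonal_centered_vectors(self):
        x = np.array([1.0, 1.0, -1.0, -1.0])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert abs(np.dot(x, y)) < 1e-12
        assert fb.pearson_corr(x, y).statistic == pytest.approx(0.0, abs=1e-12)

    def test_fixed_table_matches_covariance_formula(self, rng):
        x = rng.standard_normal(6)
        y = rng.standard_normal(6)
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert fb.pearson_corr(x, y).statistic == pytest.approx(expected,
                                                                abs=1e-12)

    def test_zero_variance(self):
        with pytest.raises(ZeroVariance):
            fb.pearson_corr([1.0] * 6, [1.0, 2, 3, 4, 5, 6])

    def test_identical_groups_give_f_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = fb.oneway_anova([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.standard_normal(8)
        b = rng.standard_normal(10) + 0.5
        from scipy.stats import ttest_ind
        t = ttest_ind(a, b).statistic
        assert fb.oneway_anova([a, b]).statistic == pytest.approx(t ** 2,
                                                                  rel=1e-10)

    def test_fixed_table_matches_hand_sums_of_squares(self):
        a = np.array([2.0, 3.0, 1.0, 4.0, 5.0])
        b = np.array([4.0, 6.0, 5.0, 7.0, 3.0])
        grand = np.concatenate([a, b]).mean()
        ss_between = 5 * (a.mean() - grand) ** 2 + 5 * (b.mean() - grand) ** 2
        ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
        f = (ss_between / 1) / (ss_within / 8)
        res = fb.oneway_anova([a, b])
        assert res.statistic == pytest.approx(f, rel=1e-12)
        assert res.extra == {"df1": 1.0, "df2": 8.0}

    def test_degenerate_groups(self):
        with pytest.raises(DegenerateGroups):
            fb.oneway_anova([[1.0, 1.0], [1.0, 1.0]])


class TestBhFdr:
    @pytest.mark.parametrize("m,q_star", [(4, 0.0125), (8, 0.00625)])
    def test_rank_one_critical_value(self, m, q_star):
        res = fb.bh_fdr([0.5] * m, alpha=0.05)
        assert res.q_star == pytest.approx(q_star, abs=1e-12)

    def test_q_star_for_eight_tests_prints_as_006(self):
        assert round(fb.bh_fdr([0.5] * 8).q_star, 3) == 0.006

    def test_all_p_one_rejects_nothing(self):
        assert not any(fb.bh_fdr([1.0] * 10).rejected)

    def test_step_up_rule_against_direct_computation(self):
        p = np.array([0.001, 0.013, 0.04, 0.2, 0.9])
        res = fb.bh_fdr(p, alpha=0.05)
        # direct step-up: largest k with p_(k) <= k * alpha / m
        order = np.sort(p)
        k = max((i + 1 for i in range(p.size)
                 if order[i] <= (i + 1) * 0.05 / p.size), default=0)
        expected = p <= (order[k - 1] if k else -1.0)
        assert res.rejected == tuple(expected)

    def test_monotone_in_alpha_and_never_rejects_above_alpha(self, rng):
        p = rng.uniform(size=20)
        small = fb.bh_fdr(p, alpha=0.01)
        large = fb.bh_fdr(p, alpha=0.10)
        assert all(l or not s for s, l in zip(small.rejected, large.rejected))
        assert not any(r and pv > 0.10 for r, pv in zip(large.rejected, p))

    def test_bad_pvalue(self):
        with pytest.raises(BadPValue):
            fb.bh_fdr([0.5, 1.2])


class TestPermutationBootstrap:
    def test_null_rejection_rate_is_nominal(self):
        """Labels independent of values: rejection at 0.05 in ~5% of
        replications (500 runs)."""
        rejections = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            values = rng.standard_normal(24)
            labels = np.array(["a"] * 12 + ["b"] * 12)
            res = fb.permutation_group_test(values, labels, n_perm=999,
                                            seed=seed)
            rejections += res.p <= 0.05
        assert 0.03 <= rejections / 500 <= 0.07

    def test_p_lower_bound(self, rng):
        values = np.concatenate([rng.standard_normal(10) + 50,
                                 rng.standard_normal(10)])
        labels = ["a"] * 10 + ["b"] * 10
        res = fb.permutation_group_test(values, labels, n_perm=200, seed=1)
        assert res.p >= 1 / 201

    def test_planted_shift_is_detected(self, rng):
        values = np.concatenate([rng.standard_normal(40) + 2.0,
                                 rng.standard_normal(40)])
        labels = ["hi"] * 40 + ["lo"] * 40
        res = fb.permutation_group_test(values, labels, seed=7)
        assert res.p < 0.001

    def test_single_class_raises(self):
        with pytest.raises(SingleClass):
            fb.permutation_group_test([1.0, 2.0, 3.0], ["a", "a", "a"])

    def test_bootstrap_constant_data(self):
        lo, hi = fb.bootstrap_ci([2.0] * 10, seed=0)
        assert lo == hi == 2.0

    def test_bootstrap_reproducible(self, rng):
        values = rng.standard_normal(50)
        assert fb.bootstrap_ci(values, seed=3) == fb.bootstrap_ci(values, seed=3)

    def test_bootstrap_coverage(self):
        """95% percentile interval covers the true mean in ~95% of
        replications (500 draws, n = 103, sigma = 0.12)."""
        covered = 0
        for seed in range(500):
            rng = np.random.default_rng(seed)
            values = 1.0 + 0.12 * rng.standard_normal(103)
            lo, hi = fb.bootstrap_ci(values, b=500, seed=seed)
            covered += lo <= 1.0 <= hi
        assert covered / 500 == pytest.approx(0.95, abs=0.03)

    def test_bootstrap_too_few(self):
        with pytest.raises(TooFewValues):
            fb.bootstrap_ci([1.0, 2.0])


class TestTypeIError:
    @pytest.mark.parametrize("test_name", ["wilcoxon", "paired", "mwu",
                                           "pearson", "anova"])
    def test_nominal_level_under_null(self, test_name):
        """Each test's type-I error at 0.05 lies in [0.03, 0.07]
        (2000 null draws)."""
        rejections = 0
        n_rep = 2000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            if test_name == "wilcoxon":
                p = fb.wilcoxon_one_sample(1 + rng.standard_normal(103), 1.0).p
            elif test_name == "paired":
                p = fb.wilcoxon_paired(rng.standard_normal(103),
                                       rng.standard_normal(103)).p
            elif test_name == "mwu":
                p = fb.mannwhitney_u(rng.standard_normal(66),
                                     rng.standard_normal(38)).p
            elif test_name == "pearson":
                p = fb.pearson_corr(rng.standard_normal(103),
                                    rng.standard_normal(103)).p
            else:
                p = fb.oneway_anova([rng.standard_normal(66),
                                     rng.standard_normal(38)]).p
            rejections += p <= 0.05
        assert 0.03 <= rejections / n_rep <= 0.07


class TestFullAnalysis:
    def test_report_tables_have_expected_shape(self, small_cohort):
        table, _ = fb.cohort_hurst_table(small_cohort)
        tables = fb.run_full_analysis(table)
        assert set(tables) == {"pink_noise", "task_vs_rest", "phenotype",
                               "correlations", "behavior_anova"}
        assert len(tables["pink_noise"]) == 8
        assert len(tables["task_vs_rest"]) == 8
        assert len(tables["phenotype"]) == 16
        assert len(tables["correlations"]) == 32
        assert len(tables["behavior_anova"]) == 4
        for t in tables.values():
            assert t.select_dtypes("number").notna().all().all()

    def test_incomplete_cohort_raises(self, small_cohort):
        table, _ = fb.cohort_hurst_table(small_cohort)
        broken = CohortTable(h=table.h.iloc[:-1], behavior=table.behavior)
        with pytest.raises(IncompleteCohort):
            fb.run_full_analysis(broken)

    def test_planted_task_deficit_is_recovered(self):
        """highImp task deficit planted only in ACC and rNAcc: both flagged
        at FDR 0.05 in >= 90% of 100 truth-model cohorts, and the rest
        (null) family stays clean in >= 90%."""
        means = flat_h_means(task=0.92, rest=1.0, overrides={
            ("ACC", "task", "highImp"): 0.72,
            ("rNAcc", "task", "highImp"): 0.72,
        })
        spec = fb.CohortSpec(h_means=means)
        both = rest_clean = 0
        for seed in range(100):
            tab = table_from_truth(spec, 10_000 + seed)
            ph = fb.run_full_analysis(tab)["phenotype"]
            task = ph[ph["condition"] == "task"]
            flagged = set(task.loc[task["significant"], "region"])
            both += {"ACC", "rNAcc"} <= flagged
            rest = ph[ph["condition"] == "rest"]
            rest_clean += not rest["significant"].any()
        assert both >= 90
        assert rest_clean >= 90

    def test_null_cohort_family_wise_error_control(self):
        """Fully null cohort: per-family probability of any flag stays at
        or below alpha (+2 Monte-Carlo SE) over 500 runs."""
        shared = {c: 1 / 7 for c in range(7)}
        spec = fb.CohortSpec(
            h_means=flat_h_means(task=1.0, rest=1.0),
            premature_model={"lowImp": shared, "highImp": shared},
            h_bounds=(0.6, 1.4),
        )
        n_rep = 500
        counts = {key: 0 for key in
                  ["pink_noise", "tvr_overall", "tvr_lowImp", "tvr_highImp",
                   "phen_task", "phen_rest", "correlations", "behavior_anova"]}
        for seed in range(n_rep):
            tables = fb.run_full_analysis(table_from_truth(spec, 50_000 + seed))
            counts["pink_noise"] += tables["pink_noise"]["significant"].any()
            tvr = tables["task_vs_rest"]
            for name in ("overall", "lowImp", "highImp"):
                counts[f"tvr_{name}"] += tvr[f"{name}_significant"].any()
            ph = tables["phenotype"]
            for cond in ("task", "rest"):
                counts[f"phen_{cond}"] += \
                    ph.loc[ph["condition"] == cond, "significant"].any()
            counts["correlations"] += \
                tables["correlations"]["significant"].any()
            counts["behavior_anova"] += \
                tables["behavior_anova"]["significant"].any()
        bound = 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)
        for family, count in counts.items():
            assert count / n_rep <= bound, (family, count / n_rep)

    def test_grouping_validated_by_permutation(self):
        """On the default cohort the premature-count grouping survives the
        permutation check (group mean difference, p < 0.001)."""
        _, behavior = fb.gen_cohort_h(fb.CohortSpec(), seed=4)
        res = fb.permutation_group_test(behavior["premature"].to_numpy(),
                                        behavior["phenotype"].to_numpy(),
                                        seed=4)
        assert res.p < 0.001
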