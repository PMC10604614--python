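"""Cohort statistics: descriptive, two-group tests, ROC, adjusted association."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ddcfdna import (
    adjusted_association,
    build_group_comparison,
    chi_square_2x2,
    mann_whitney,
    median_iqr,
    roc_auc_ci,
)
from ddcfdna.stats import DEFAULT_TABLE2_VARIABLES, VariableSpec


def enumerate_mw_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration (oracle)."""
    a, b = list(a), list(b)
    pooled = a + b
    n_a = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    mean_u = n_a * len(b) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for x in ga for y in gb if x > y) + 0.5 * sum(
            1 for x in ga for y in gb if x == y
        )
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMedianIqr:
    def test_hand_computed_quartiles(self):
        assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)

    def test_single_value(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0)

    def test_constant_list_zero_width(self):
        med, q1, q3 = median_iqr([4, 4, 4, 4])
        assert med == q1 == q3 == 4.0

    def test_tukey_hinges_option(self):
        med, q1, q3 = median_iqr([1, 2, 3, 4, 5, 6], method="tukey")
        assert (med, q1, q3) == (3.5, 2.0, 5.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_iqr([])


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "mann_whitney_exact"

    def test_identical_groups_centre_u(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)
        assert res.p_value > 0.95

    def test_strong_shift_is_significant(self):
        a = np.arange(20) + 100.0
        b = np.arange(20)
        assert mann_whitney(a, b).p_value < 1e-4

    def test_matches_enumeration_oracle_for_untied_small_samples(self):
        rng = np.random.default_rng(4)
        for n_a, n_b in [(2, 3), (3, 3), (4, 4), (5, 4)]:
            vals = rng.permutation(100)[: n_a + n_b].astype(float)
            a, b = vals[:n_a], vals[n_a:]
            assert mann_whitney(a, b).p_value == pytest.approx(
                enumerate_mw_p(a, b), abs=1e-12
            )

    def test_exact_close_to_asymptotic_without_ties(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            vals = rng.permutation(1000)[:16].astype(float)
            a, b = vals[:8], vals[8:]
            p_exact = mann_whitney(a, b, method="exact").p_value
            p_asym = mann_whitney(a, b, method="asymptotic").p_value
            # the continuity-corrected normal approximation tracks the exact
            # null to ~0.011 at n=8 vs 8 (its worst case near p ~ 0.5)
            assert abs(p_exact - p_asym) < 0.015

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestChiSquare:
    @pytest.mark.parametrize(
        "table,p_printed",
        [([[4, 7], [1, 30]], 0.004),
         ([[4, 7], [3, 28]], 0.041),
         ([[7, 4], [7, 24]], 0.013)],
    )
    def test_uncorrected_pearson_matches_printed_association(self, table, p_printed):
        assert round(chi_square_2x2(table).p_value, 3) == p_printed

    def test_balanced_table_is_null(self):
        res = chi_square_2x2([[5, 5], [5, 5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_agrees_with_library_contingency_test(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            t = rng.integers(1, 40, size=(2, 2))
            ours = chi_square_2x2(t)
            chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
            assert ours.statistic == pytest.approx(chi2)
            assert ours.p_value == pytest.approx(p)
            ours_y = chi_square_2x2(t, continuity_correction=True)
            chi2y, py, _, _ = sps.chi2_contingency(t, correction=True)
            assert ours_y.statistic == pytest.approx(chi2y)
            assert ours_y.p_value == pytest.approx(py)

    def test_equals_squared_two_proportion_z(self):
        t = np.array([[12, 18], [5, 25]], dtype=float)
        n1, n2 = t[0].sum(), t[1].sum()
        p1, p2 = t[0, 0] / n1, t[1, 0] / n2
        pp = (t[0, 0] + t[1, 0]) / (n1 + n2)
        z = (p1 - p2) / np.sqrt(pp * (1 - pp) * (1 / n1 + 1 / n2))
        assert chi_square_2x2(t).statistic == pytest.approx(z**2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestRoc:
    def test_perfect_separation(self):
        r = roc_auc_ci([3, 2.5, 1, 0.5], [1, 1, 0, 0])
        assert r.auc == 1.0
        assert r.curve_points[0] == (0.0, 0.0) and r.curve_points[-1] == (1.0, 1.0)

    def test_null_scores_give_half(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, size=2000)
        r = roc_auc_ci(scores, labels)
        assert 0.46 <= r.auc <= 0.54

    def test_auc_equals_u_statistic_identity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = rng.integers(12, 60)
            scores = rng.choice(np.linspace(0, 5, 12), size=n)  # with ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            r = roc_auc_ci(scores, labels)
            u = sps.mannwhitneyu(scores[labels == 1], scores[labels == 0],
                                 alternative="two-sided").statistic
            assert r.auc == pytest.approx(u / (r.n_pos * r.n_neg))

    def test_label_swap_mirrors_auc(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, size=80)
        a = roc_auc_ci(scores, labels)
        b = roc_auc_ci(scores, 1 - labels)
        assert a.auc == pytest.approx(1 - b.auc)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(10)
        scores = rng.lognormal(size=100)
        labels = (scores + rng.normal(0, 1, 100) > 1).astype(int)
        a = roc_auc_ci(scores, labels).auc
        b = roc_auc_ci(np.log(scores), labels).auc
        assert a == pytest.approx(b)

    def test_curve_monotone_nondecreasing(self):
        rng = np.random.default_rng(11)
        r = roc_auc_ci(rng.normal(size=60), rng.integers(0, 2, 60))
        fpr, tpr = zip(*r.curve_points)
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_hanley_option_and_ci_bracket(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=60)
        labels = (scores + rng.normal(0, 1.5, 60) > 0).astype(int)
        for method in ("delong", "hanley"):
            r = roc_auc_ci(scores, labels, ci_method=method)
            assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc_ci([1, 2, 3], [1, 1, 1])


class TestAdjustedAssociation:
    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            adjusted_association([1] * 20, [0, 1] * 10, np.arange(20))

    def test_null_exposure_ci_covers_one(self):
        rng = np.random.default_rng(14)
        covered = 0
        n_sim = 60
        for _ in range(n_sim):
            e = rng.integers(0, 2, 300)
            c = rng.normal(50, 15, 300)
            y = (rng.random(300) < 0.25).astype(int)
            eff = adjusted_association(y, e, c)
            covered += eff.ci_low <= 1.0 <= eff.ci_high
        assert covered >= 0.9 * n_sim

    def test_strong_effect_detected_in_small_cohorts(self):
        rng = np.random.default_rng(15)
        above = n_fit = 0
        for _ in range(60):
            e = (rng.random(42) < 0.26).astype(int)
            c = rng.normal(50, 15, 42)
            p = 1 / (1 + np.exp(-(-3.0 + np.log(20.0) * e)))
            y = (rng.random(42) < p).astype(int)
            if y.sum() in (0, 42):
                continue
            n_fit += 1
            above += adjusted_association(y, e, c).odds_ratio > 1.0
        assert n_fit >= 50
        assert above >= 0.95 * n_fit

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            adjusted_association([0, 1] * 4, [0, 1] * 4, np.arange(8))


class TestGroupComparison:
    def test_identical_groups_have_null_pvalues(self, joined_cohort_frame):
        df = joined_cohort_frame.copy()
        # make the two cutoff groups copies of the same records
        half = df.iloc[:30].copy()
        half["dd_fraction_percent"] = 2.0
        other = df.iloc[:30].copy()
        other["dd_fraction_percent"] = 0.5
        both = pd.concat([half, other], ignore_index=True)
        table = build_group_comparison(
            both,
            [VariableSpec("egfr", "eGFR", "continuous"),
             VariableSpec("abmr", "AbMR", "binary")],
        )
        assert (table.p_value.dropna() > 0.9).all()

    def test_row_count_matches_variables(self, joined_cohort_frame):
        table = build_group_comparison(joined_cohort_frame,
                                       [VariableSpec("egfr", "eGFR", "continuous"),
                                        VariableSpec("abmr", "AbMR", "binary"),
                                        VariableSpec("classII_eplet_load", "load", "continuous")])
        assert len(table) == 3
        assert {"variable", "overall", "elevated", "low", "p_value"} <= set(table.columns)

    def test_missing_variable_named_in_error(self, joined_cohort_frame):
        with pytest.raises(ValueError, match="nonexistent"):
            build_group_comparison(
                joined_cohort_frame,
                [VariableSpec("nonexistent", "x", "continuous")],
            )

    def test_default_hla_table_spec_shapes(self):
        labels = [v.label for v in DEFAULT_TABLE2_VARIABLES]
        assert "All HLA class II eplet mismatch load" in labels
        assert len(labels) == 6
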