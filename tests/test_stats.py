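"""AUROC, fold CIs, DeLong's paired test, and the chi-squared analysis.

The AUROC is held to exact agreement with brute-force pair enumeration;
DeLong's p-value to a resampling oracle of the AUROC difference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slideattn.stats import (auroc, auroc_ci, build_report, chi_squared_2x2,
                             delong_test)


def pair_enumeration_auroc(scores, labels):
    """Independent O(n^2) oracle: mean pairwise win/tie score."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuroc:
    def test_perfect_and_constant_scores(self):
        labels = np.array([0, 0, 1, 1])
        assert auroc([0.1, 0.2, 0.8, 0.9], labels) == 1.0
        assert auroc([0.5] * 4, labels) == 0.5

    def test_worked_example(self):
        assert auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_matches_pair_enumeration_with_ties(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 50))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(n), 1)  # coarse grid forces ties
            assert auroc(scores, labels) == pytest.approx(
                pair_enumeration_auroc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.9], [1, 1])

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_adding_concordant_pair_never_decreases(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        scores = rng.random(n)
        base = auroc(scores, labels)
        ext_scores = np.r_[scores, scores.min() - 1, scores.max() + 1]
        ext_labels = np.r_[labels, 0, 1]
        assert auroc(ext_scores, ext_labels) >= base - 1e-12


class TestAurocCI:
    def test_zero_variance_collapses(self):
        mean, lo, hi = auroc_ci([0.8, 0.8, 0.8])
        for v in (mean, lo, hi):
            assert v == pytest.approx(0.8, abs=1e-12)

    def test_matches_hand_computed_normal_approx(self):
        folds = np.array([0.8, 0.8, 0.8, 0.8, 0.9])
        mean, lo, hi = auroc_ci(folds)
        half = 1.959963984540054 * folds.std(ddof=1) / np.sqrt(5)
        assert mean == pytest.approx(0.82)
        assert lo == pytest.approx(0.82 - half)
        assert hi == pytest.approx(0.82 + half)

    def test_truncation_at_bounds(self):
        _, lo, hi = auroc_ci([0.95, 0.99, 0.6])
        assert 0.0 <= lo and hi == 1.0

    def test_requires_two_folds(self):
        with pytest.raises(ValueError):
            auroc_ci([0.8])


class TestDeLong:
    def test_identical_classifiers_degenerate(self, rng):
        labels = np.array([0, 1] * 20)
        scores = rng.standard_normal(40)
        a, b, z, p = delong_test(scores, scores, labels)
        assert a == b and z == 0.0 and p == 1.0

    def test_reflected_scores_mirror_auroc(self, rng):
        labels = np.array([0, 1] * 20)
        scores = rng.random(40)
        a, b, _, _ = delong_test(scores, 1 - scores, labels)
        assert a == pytest.approx(1 - b)

    def test_p_value_matches_bootstrap_oracle(self):
        rng = np.random.default_rng(42)
        n = 40
        labels = np.array([0, 1] * 20)
        latent = labels + rng.standard_normal(n)
        s_a = latent + 0.8 * rng.standard_normal(n)
        s_b = latent + 0.8 * rng.standard_normal(n)
        *_, p = delong_test(s_a, s_b, labels)
        # 20,000-resample bootstrap of the AUROC difference
        boot_rng = np.random.default_rng(7)
        diffs, i = np.empty(20_000), 0
        while i < diffs.size:
            idx = boot_rng.integers(0, n, n)
            if labels[idx].min() == labels[idx].max():
                continue
            diffs[i] = auroc(s_a[idx], labels[idx]) - auroc(s_b[idx], labels[idx])
            i += 1
        p_boot = min(1.0, 2 * min((diffs <= 0).mean(), (diffs >= 0).mean()))
        assert abs(p - p_boot) <= 0.02

    def test_detects_genuinely_better_classifier(self, rng):
        labels = np.array([0, 1] * 100)
        good = labels + 0.5 * rng.standard_normal(200)
        bad = rng.standard_normal(200)
        a, b, z, p = delong_test(good, bad, labels)
        assert a > b and p < 0.001


class TestChiSquared:
    def test_top_patch_contingency_tables_significant(self):
        # stroma vs non-stroma and tumor vs non-tumor top-patch counts
        for table in ([[336, 414], [16, 734]], [[45, 705], [654, 96]]):
            stat, df, p = chi_squared_2x2(table)
            assert df == 1 and p < 0.001

    def test_identical_rows_null(self):
        stat, _, p = chi_squared_2x2([[25, 75], [25, 75]])
        assert stat == 0.0 and p == 1.0

    def test_matches_hand_computed_statistic(self):
        stat_uniform, _, _ = chi_squared_2x2([[10, 10], [10, 10]])
        assert stat_uniform == 0.0
        stat_diag, _, _ = chi_squared_2x2([[20, 0], [0, 20]])
        # all expected counts are 10: sum (O-E)^2 / E = 4 * 100/10
        assert stat_diag == pytest.approx(40.0)
        assert stat_diag > stat_uniform

    def test_invariance_under_row_and_column_swaps(self, rng):
        table = rng.integers(5, 60, (2, 2))
        stat, _, p = chi_squared_2x2(table)
        for variant in (table[::-1], table[:, ::-1], table.T):
            v_stat, _, v_p = chi_squared_2x2(variant)
            assert v_stat == pytest.approx(stat) and v_p == pytest.approx(p)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_squared_2x2([[0, 0], [5, 7]])


def test_build_report_shapes(rng):
    labels = np.array([0, 1] * 30)
    folds = np.repeat(np.arange(5), 12)
    sets = {"a": labels + rng.standard_normal(60),
            "b": rng.standard_normal(60)}
    report = build_report(sets, labels, fold_ids=folds)
    assert set(report.aurocs["classifier"]) == {"a", "b"}
    assert len(report.delong) == 1
    assert (report.aurocs["ci_low"] <= report.aurocs["auroc"] + 1e-12).all()
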