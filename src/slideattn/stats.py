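"""Evaluation statistics: AUROC, fold-based confidence intervals, DeLong's
paired test for correlated ROC curves, and contingency-table chi-squared
analysis of top-attention patch classes.

AUROC is computed in its Mann–Whitney form (probability that a random
positive outscores a random negative, ties counting one half). DeLong's
test estimates the variance of an AUROC difference from per-sample
structural components, which accounts for the correlation induced by
scoring the same samples with both classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels.astype(int)


def auroc(scores, labels) -> float:
    """Area under the ROC curve, Mann–Whitney form.

    Equals the mean over all positive–negative pairs of 1 if the positive
    scores higher, 0.5 on a tie, 0 otherwise. Computed via midranks so ties
    are handled exactly in O(n log n).
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same shape")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    ranks = sps.rankdata(scores)  # midranks
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auroc_ci(fold_aurocs, confidence: float = 0.95) -> tuple[float, float, float]:
    """Normal-approximation CI from per-fold (or per-repeat) AUROCs.

    Returns (mean, lower, upper) with bounds mean ± z·sd/sqrt(k), truncated
    to [0, 1]. Requires at least two folds.
    """
    vals = np.asarray(fold_aurocs, dtype=float)
    if vals.ndim != 1 or vals.size < 2:
        raise ValueError("need at least 2 fold AUROCs")
    z = sps.norm.ppf(0.5 + confidence / 2)
    mean = float(vals.mean())
    half = z * vals.std(ddof=1) / np.sqrt(vals.size)
    return mean, float(max(0.0, mean - half)), float(min(1.0, mean + half))


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Per-sample placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    # kernel psi(x, y) = 1 if x > y, 0.5 if equal, 0 otherwise
    diff = pos[:, None] - neg[None, :]
    psi = (diff > 0).astype(float) + 0.5 * (diff == 0)
    v10 = psi.mean(axis=1)  # one per positive
    v01 = psi.mean(axis=0)  # one per negative
    return v10, v01


def delong_test(scores_a, scores_b, labels):
    """DeLong's paired two-sided test comparing two correlated AUROCs.

    Both score vectors must rank the same samples. Returns
    ``(auroc_a, auroc_b, z, p)``. If the estimated variance of the AUROC
    difference is zero (e.g. identical classifiers) the test is degenerate
    and ``(z, p) = (0, 1)`` is returned.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = _check_binary(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("scores_a, scores_b and labels must have the same shape")

    v10a, v01a = _structural_components(scores_a, labels)
    v10b, v01b = _structural_components(scores_b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size

    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)  # 2x2 over positives
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)  # 2x2 over negatives
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        return auc_a, auc_b, 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


def chi_squared_2x2(table, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test on a 2x2 count table.

    No continuity correction by default (appropriate for large cells);
    Yates correction available via ``correction=True``. Returns
    ``(statistic, df, p)``.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero marginal total")
    stat, p, df, expected = sps.chi2_contingency(table, correction=correction)
    if (expected <= 0).any():
        raise ValueError("expected counts must be positive")
    return float(stat), int(df), float(p)


@dataclass
class EvalReport:
    """AUROCs with CIs per classifier/cohort plus pairwise DeLong results."""

    aurocs: pd.DataFrame  # classifier, cohort, auroc, ci_low, ci_high, n
    delong: pd.DataFrame = field(default=None)  # classifier_a, classifier_b, cohort, z, p
    chi_squared: pd.DataFrame = field(default=None)  # comparison, statistic, df, p


def build_report(score_sets: dict, labels, fold_ids=None) -> EvalReport:
    """Assemble an evaluation report from pooled out-of-fold scores.

    ``score_sets`` maps classifier name -> score vector over the same
    samples. AUROC CIs come from per-fold AUROCs when ``fold_ids`` is
    given; pairwise comparisons use DeLong's test on the pooled scores.
    """
    labels = _check_binary(labels)
    rows = []
    for name, scores in score_sets.items():
        scores = np.asarray(scores, dtype=float)
        point = auroc(scores, labels)
        lo = hi = np.nan
        if fold_ids is not None:
            fold_ids_arr = np.asarray(fold_ids)
            per_fold = []
            for f in np.unique(fold_ids_arr):
                sel = fold_ids_arr == f
                if labels[sel].min() != labels[sel].max():
                    per_fold.append(auroc(scores[sel], labels[sel]))
            if len(per_fold) >= 2:
                _, lo, hi = auroc_ci(per_fold)
        rows.append({"classifier": name, "auroc": point, "ci_low": lo,
                     "ci_high": hi, "n": labels.size})
    names = list(score_sets)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a_auc, b_auc, z, p = delong_test(score_sets[names[i]],
                                             score_sets[names[j]], labels)
            pairs.append({"classifier_a": names[i], "classifier_b": names[j],
                          "auroc_a": a_auc, "auroc_b": b_auc, "z": z, "p": p})
    return EvalReport(aurocs=pd.DataFrame(rows), delong=pd.DataFrame(pairs))
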