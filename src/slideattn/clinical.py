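"""Clinical and combined logistic classifiers.

The clinical classifier is a plain logistic regression of lymph-node
metastasis status on age (years), gender (male = 1), pT stage (ordinal
2/3/4, one coefficient per unit step), lymphovascular invasion (0/1) and
histologic grade (high = 1). The combined classifier adds the MIL slide
score as one continuous covariate on its probability scale; in
cross-validation only out-of-fold scores enter, and the folds are shared
with the MIL model so both classifiers see identical splits.

Reports follow the usual odds-ratio layout: coefficient, Wald standard
error, two-sided p-value, and exp(coefficient) with a 95% Wald CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

DEFAULT_COVARIATES = ["age", "gender", "pT_stage", "LVI", "grade"]
SCORE_COLUMN = "sblnp_score"


class SeparationError(ValueError):
    """Perfect separation: the MLE does not exist."""


class CollinearityError(ValueError):
    """Constant or linearly dependent covariates."""


def complete_cases(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Drop patients with any missing value in the modeling columns."""
    return table.dropna(subset=list(columns)).reset_index(drop=True)


@dataclass
class LogisticReport:
    """Coefficient table plus a probability predictor."""

    table: pd.DataFrame  # variable, coefficient, std_error, p_value, OR, CI
    covariates: list
    params: np.ndarray  # intercept first

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        x = np.column_stack([np.ones(len(data))] +
                            [np.asarray(data[c], dtype=float) for c in self.covariates])
        return 1.0 / (1.0 + np.exp(-x @ self.params))


def _check_design(table: pd.DataFrame, covariates) -> np.ndarray:
    x = np.column_stack([np.asarray(table[c], dtype=float) for c in covariates])
    if not np.all(np.isfinite(x)):
        raise ValueError("covariates contain missing or non-finite values; "
                         "apply complete_cases first")
    constant = [c for c, col in zip(covariates, x.T) if np.ptp(col) == 0]
    if constant:
        raise CollinearityError(f"covariates with zero variance: {constant}")
    design = np.column_stack([np.ones(len(table)), x])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError(f"linearly dependent covariates among {list(covariates)}")
    return design


def fit_logistic(table: pd.DataFrame, covariates=None,
                 label_col: str = "label") -> LogisticReport:
    """Maximum-likelihood logistic regression with a Wald report.

    Newton-type IRLS to tight gradient tolerance; raises SeparationError
    when the likelihood has no finite maximizer and CollinearityError on
    degenerate designs.
    """
    covariates = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    y = np.asarray(table[label_col], dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("label must contain both classes")
    design = _check_design(table, covariates)

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, design).fit(method="newton", maxiter=200,
                                          tol=1e-10, disp=0)
        except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
            raise SeparationError(f"logistic fit failed: {exc}") from exc
    for warning in caught:
        if "separation" in str(warning.message).lower():
            raise SeparationError("perfect separation detected; "
                                  "coefficients diverge")
    # quasi-separation guard: fitted probabilities numerically 0/1 everywhere
    fitted = res.predict(design)
    if np.all((fitted > 1 - 1e-8) == (y == 1)) and np.all((fitted < 1e-8) == (y == 0)):
        raise SeparationError("perfect separation detected; "
                              "fitted probabilities are all 0 or 1")

    beta, se = res.params, res.bse
    z95 = 1.959963984540054
    rows = []
    for name, b, s, p in zip(["intercept"] + covariates, beta, se, res.pvalues):
        rows.append({
            "variable": name, "coefficient": b, "std_error": s, "p_value": p,
            "odds_ratio": np.exp(b), "or_ci_low": np.exp(b - z95 * s),
            "or_ci_high": np.exp(b + z95 * s),
        })
    return LogisticReport(table=pd.DataFrame(rows), covariates=covariates,
                          params=np.asarray(beta))


def fit_combined(table: pd.DataFrame, covariates=None,
                 score_col: str = SCORE_COLUMN,
                 label_col: str = "label") -> LogisticReport:
    """Clinical covariates plus the MIL slide score as one extra covariate."""
    covariates = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    if score_col not in table.columns or table[score_col].isna().any():
        raise ValueError(f"{score_col} must be present for every patient")
    scores = np.asarray(table[score_col], dtype=float)
    if (scores < 0).any() or (scores > 1).any():
        warnings.warn(f"{score_col} outside [0, 1]; accepted as-is", stacklevel=2)
    return fit_logistic(table, covariates + [score_col], label_col=label_col)


def crossvalidated_scores(table: pd.DataFrame, folds: dict, covariates=None,
                          score_col: str | None = None,
                          label_col: str = "label") -> pd.DataFrame:
    """Out-of-fold predicted probabilities with a shared fold assignment.

    ``folds`` maps patient_id -> fold (the same mapping the MIL
    cross-validation used, keeping both classifiers' splits consistent).
    When ``score_col`` is given the combined model is fitted per fold.
    """
    covariates = list(covariates) if covariates is not None else list(DEFAULT_COVARIATES)
    fold_series = table["patient_id"].map(folds)
    if fold_series.isna().any():
        missing = table.loc[fold_series.isna(), "patient_id"].tolist()
        raise ValueError(f"patients without fold assignment: {missing}")
    out = []
    for fold in sorted(fold_series.unique()):
        train = table[fold_series != fold]
        test = table[fold_series == fold]
        if score_col is not None:
            report = fit_combined(train, covariates, score_col=score_col,
                                  label_col=label_col)
        else:
            report = fit_logistic(train, covariates, label_col=label_col)
        chunk = test[["patient_id", label_col]].copy()
        chunk["fold"] = fold
        chunk["score"] = report.predict(test)
        out.append(chunk)
    return pd.concat(out, ignore_index=True).rename(columns={label_col: "label"})
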