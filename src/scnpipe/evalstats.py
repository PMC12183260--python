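"""Performance metrics, permutation significance, and model comparison.

Balanced accuracy (BAC) is the mean of sensitivity (true-positive rate on
patients) and specificity (true-negative rate on controls); AUC is the
rank-based probability that a random patient's decision score exceeds a
random control's (ties count one half).  Model significance uses random
label permutations with the add-one estimator
p = (1 + #{permuted BAC >= observed}) / (B + 1).  Model comparison across
CV blocks uses the Quade rank test with an F reference distribution,
followed by paired t-tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PerformanceReport",
    "classification_metrics",
    "permutation_significance",
    "quade_compare",
    "posthoc_pairwise",
    "cohort_effect_tests",
    "write_report_table",
]


@dataclass
class PerformanceReport:
    bac: float            # percent
    sensitivity: float    # percent
    specificity: float    # percent
    auc: float            # fraction in [0, 1]
    p_value: float | None = None
    per_fold_bac: pd.DataFrame | None = None

    def __post_init__(self):
        if abs(self.bac - (self.sensitivity + self.specificity) / 2) > 1e-6:
            raise ValueError("BAC must equal (sensitivity + specificity)/2")


def classification_metrics(scores, labels) -> PerformanceReport:
    """Metrics from decision scores and binary labels (patient = 1).

    Predicted label is the sign rule (score >= 0 -> patient).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    pred = (s >= 0).astype(int)
    pats, ctrl = y == 1, y == 0
    sens = 100.0 * (pred[pats] == 1).mean()
    spec = 100.0 * (pred[ctrl] == 0).mean()
    # rank-based AUC with tie correction (Mann-Whitney U / n1 n0)
    r = stats.rankdata(s)
    n1, n0 = pats.sum(), ctrl.sum()
    auc = (r[pats].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    return PerformanceReport(bac=(sens + spec) / 2.0, sensitivity=sens,
                             specificity=spec, auc=float(auc))


def permutation_significance(runner, labels, B: int = 100,
                             seed: int = 0) -> tuple:
    """Label-permutation significance of a model's BAC.

    ``runner(labels) -> BAC`` must re-run the full training procedure;
    labels are permuted once per replicate and the identical CV plan is
    reused.  Returns (p, observed BAC, permuted BACs).
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = float(runner(y))
    null = np.empty(B)
    for b in range(B):
        null[b] = runner(rng.permutation(y))
    p = (1.0 + np.sum(null >= observed)) / (B + 1.0)
    return float(p), observed, null


def quade_compare(per_fold_bac: np.ndarray) -> tuple:
    """Quade rank test on a blocks x models performance table.

    Blocks are CV cells (outer fold x permutation).  Returns
    (W statistic, p, df1, df2) with df1 = k-1 and df2 = (b-1)(k-1).
    Identical columns give statistic 0 and p = 1.
    """
    A_mat = np.asarray(per_fold_bac, dtype=float)
    b, k = A_mat.shape
    if b < 2 or k < 2:
        raise ValueError("need at least 2 blocks and 2 models")
    R = np.apply_along_axis(stats.rankdata, 1, A_mat)
    ranges = A_mat.max(axis=1) - A_mat.min(axis=1)
    Q = stats.rankdata(ranges)
    S = Q[:, None] * (R - (k + 1) / 2.0)
    Sj = S.sum(axis=0)
    A = float((S ** 2).sum())
    Bq = float((Sj ** 2).sum() / b)
    df1, df2 = k - 1, (b - 1) * (k - 1)
    if A - Bq <= 0:
        # zero within-block spread of the statistic: all models tie
        return 0.0, 1.0, df1, df2
    W = (b - 1) * Bq / (A - Bq)
    p = float(stats.f.sf(W, df1, df2))
    return float(W), p, df1, df2


def posthoc_pairwise(per_fold_bac: np.ndarray, model_names=None,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Paired t-tests on per-block BAC for every model pair, BH-corrected.

    Returns a long-form table (model_a, model_b, t, p, p_fdr, significant).
    Constant pair differences yield p = 1.
    """
    X = np.asarray(per_fold_bac, dtype=float)
    k = X.shape[1]
    names = model_names if model_names is not None \
        else [f"model_{j}" for j in range(k)]
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = X[:, i] - X[:, j]
            if np.allclose(diff.std(ddof=1), 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = stats.ttest_rel(X[:, i], X[:, j])
            rows.append((names[i], names[j], float(t), float(p)))
    out = pd.DataFrame(rows, columns=["model_a", "model_b", "t", "p"])
    rej, p_fdr, *_ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
    out["p_fdr"] = p_fdr
    out["significant"] = rej
    return out


def cohort_effect_tests(scores_train, scores_valid, covariates_train,
                        covariates_valid):
    """Cohort effect on decision scores: two-sample t-test plus OLS
    ``score ~ cohort + age + sex`` with the cohort-coefficient p-value.

    Returns a dict with t-test results and the regression coefficient
    table.  FDR across multiple models is the caller's responsibility
    (apply :func:`statsmodels.stats.multitest.multipletests` to the
    collected p-values).
    """
    import statsmodels.api as sm

    s_tr = np.asarray(scores_train, dtype=float)
    s_va = np.asarray(scores_valid, dtype=float)
    if s_tr.size == 0 or s_va.size == 0:
        raise ValueError("both cohorts must be non-empty")
    t, p_t = stats.ttest_ind(s_tr, s_va)
    cov_tr = np.asarray(covariates_train, dtype=float)
    cov_va = np.asarray(covariates_valid, dtype=float)
    cohort = np.concatenate([np.zeros(s_tr.size), np.ones(s_va.size)])
    X = np.column_stack([cohort, np.vstack([cov_tr, cov_va])])
    X = sm.add_constant(X)
    fit = sm.OLS(np.concatenate([s_tr, s_va]), X).fit()
    coefs = pd.DataFrame({
        "term": ["intercept", "cohort", "age", "sex"],
        "coef": fit.params,
        "p": fit.pvalues,
    })
    return {"t": float(t), "p_t": float(p_t), "ols": coefs,
            "p_cohort": float(fit.pvalues[1])}


def write_report_table(reports: dict, path) -> None:
    """Per-model TSV with train/validation BAC, sensitivity, specificity
    and AUC columns.  ``reports`` maps model name ->
    {"train": PerformanceReport, "validation": PerformanceReport|None}."""
    rows = []
    for name, rr in reports.items():
        row = {"model": name}
        for split in ("train", "validation"):
            rep = rr.get(split)
            if rep is None:
                continue
            row[f"{split}_bac"] = rep.bac
            row[f"{split}_sensitivity"] = rep.sensitivity
            row[f"{split}_specificity"] = rep.specificity
            row[f"{split}_auc"] = rep.auc
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
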