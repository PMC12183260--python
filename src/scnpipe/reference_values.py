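"""Published operating points used by the worked examples.

Reported classification performances (balanced accuracy, sensitivity,
specificity, AUC) of the schizophrenia case-control study the pipeline
re-implements, for the training sample (366 controls, 154 patients) and
the external validation sample (74 controls, 71 patients), plus the
demographic counts behind the printed percentages.  These numbers are
inputs to worked-example identity checks (for instance, that balanced
accuracy equals the mean of sensitivity and specificity as recomputed by
:func:`scnpipe.evalstats.classification_metrics` from a realized
confusion table); they are never targets the pipeline is fit to.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "TRAIN_N_HC", "TRAIN_N_PAT", "VALID_N_HC", "VALID_N_PAT",
    "MODEL_PERFORMANCE", "DEMOGRAPHICS",
    "confusion_from_rates", "scores_from_confusion",
]

TRAIN_N_HC = 366
TRAIN_N_PAT = 154
VALID_N_HC = 74
VALID_N_PAT = 71

#: model -> {"train": (bac, sens, spec, auc), "validation": (...)} in
#: percent (AUC as a fraction)
MODEL_PERFORMANCE = {
    "ROI-GMV 100 LASSO":      {"train": (64.50, 62.34, 66.67, 0.68), "validation": (65.92, 52.11, 79.73, 0.69)},
    "ROI-GMV 200 LASSO":      {"train": (65.54, 61.69, 69.40, 0.69), "validation": (61.61, 39.44, 83.78, 0.65)},
    "ROI-GMV stacker LASSO":  {"train": (63.82, 62.34, 65.30, 0.69), "validation": (64.54, 50.70, 78.38, 0.68)},
    "ROI-GMV 100 PCA":        {"train": (62.33, 59.09, 65.57, 0.68), "validation": (65.89, 50.70, 81.08, 0.71)},
    "ROI-GMV 200 PCA":        {"train": (64.67, 61.04, 68.31, 0.70), "validation": (65.19, 49.30, 81.08, 0.69)},
    "ROI-GMV stacker PCA":    {"train": (64.04, 61.70, 66.39, 0.70), "validation": (66.60, 52.11, 81.08, 0.71)},
    "REF-SCN-E 100 LASSO":    {"train": (61.51, 59.09, 63.93, 0.65), "validation": (53.72, 16.90, 90.54, 0.48)},
    "REF-SCN-E 200 LASSO":    {"train": (67.03, 59.74, 74.32, 0.72), "validation": (56.32, 45.07, 67.57, 0.57)},
    "REF-SCN-M 100 LASSO":    {"train": (60.73, 62.99, 58.47, 0.61), "validation": (52.09, 36.62, 67.57, 0.47)},
    "REF-SCN-M 200 LASSO":    {"train": (60.14, 48.70, 71.58, 0.64), "validation": (55.89, 23.94, 87.84, 0.59)},
    "REF-SCN stacker LASSO":  {"train": (68.11, 62.99, 73.22, 0.73), "validation": (50.60, 29.58, 71.62, 0.57)},
    "REF-SCN-E 100 PCA":      {"train": (53.69, 50.00, 57.38, 0.57), "validation": (47.84, 26.76, 68.92, 0.47)},
    "REF-SCN-E 200 PCA":      {"train": (64.74, 53.25, 76.23, 0.69), "validation": (57.38, 30.99, 83.78, 0.61)},
    "REF-SCN-M 100 PCA":      {"train": (51.93, 62.34, 41.53, 0.53), "validation": (44.07, 40.85, 47.30, 0.41)},
    "REF-SCN-M 200 PCA":      {"train": (63.17, 50.65, 75.68, 0.67), "validation": (61.55, 36.62, 86.49, 0.60)},
    "REF-SCN stacker PCA":    {"train": (63.78, 53.25, 74.32, 0.68), "validation": (56.74, 32.39, 81.08, 0.63)},
    "KLS-SCN-E 100 LASSO":    {"train": (56.88, 35.06, 78.69, 0.61), "validation": (52.87, 8.45, 97.30, 0.50)},
    "KLS-SCN-E 200 LASSO":    {"train": (64.34, 44.81, 83.88, 0.70), "validation": (55.66, 12.68, 98.65, 0.54)},
    "KLS-SCN-M 100 LASSO":    {"train": (56.44, 46.75, 66.12, 0.58), "validation": (49.16, 25.35, 72.97, 0.50)},
    "KLS-SCN-M 200 LASSO":    {"train": (60.55, 53.90, 67.21, 0.62), "validation": (60.26, 39.44, 81.08, 0.58)},
    "KLS-SCN stacker LASSO":  {"train": (61.70, 59.74, 63.66, 0.67), "validation": (47.95, 32.39, 63.51, 0.54)},
    "KLS-SCN-E 100 PCA":      {"train": (57.12, 57.14, 57.10, 0.59), "validation": (64.63, 54.93, 74.32, 0.46)},
    "KLS-SCN-E 200 PCA":      {"train": (60.01, 59.09, 60.93, 0.63), "validation": (50.89, 43.66, 58.11, 0.65)},
    "KLS-SCN-M 100 PCA":      {"train": (56.15, 55.19, 57.10, 0.58), "validation": (64.07, 60.56, 67.57, 0.49)},
    "KLS-SCN-M 200 PCA":      {"train": (54.63, 53.25, 56.01, 0.61), "validation": (63.28, 54.93, 71.62, 0.64)},
    "KLS-SCN stacker PCA":    {"train": (59.24, 59.74, 58.74, 0.61), "validation": (57.24, 23.94, 90.54, 0.64)},
    "ROI SCN stacker LASSO":  {"train": (69.97, 67.53, 72.40, 0.75), "validation": (59.30, 25.35, 93.24, 0.65)},
    "ROI SCN stacker PCA":    {"train": (64.43, 59.74, 69.13, 0.71), "validation": (67.10, 43.66, 90.54, 0.71)},
}

#: counts behind the printed demographic percentages
DEMOGRAPHICS = {
    "train_female_hc": (184, TRAIN_N_HC),        # printed 50.3 %
    "train_female_pat": (41, TRAIN_N_PAT),       # printed 26.6 %
    "train_female_all": (184 + 41, TRAIN_N_HC + TRAIN_N_PAT),  # 43.27 %
    "valid_female_hc": (23, VALID_N_HC),         # printed 31.1 %
    "valid_female_pat": (14, VALID_N_PAT),       # printed 19.7 %
    "valid_female_all": (23 + 14, VALID_N_HC + VALID_N_PAT),   # 25.52 %
    "train_first_episode": (66, TRAIN_N_PAT),    # printed 42.9 %
}


def confusion_from_rates(sens_pct: float, spec_pct: float, n_pat: int,
                         n_hc: int) -> tuple:
    """Integer confusion counts (TP, FN, TN, FP) realizing printed rates.

    Printed sensitivities/specificities are rounded percentages of integer
    counts, so rounding sens*N back to an integer recovers the exact
    count.
    """
    tp = int(round(sens_pct / 100.0 * n_pat))
    tn = int(round(spec_pct / 100.0 * n_hc))
    return tp, n_pat - tp, tn, n_hc - tn


def scores_from_confusion(tp: int, fn: int, tn: int, fp: int) -> tuple:
    """Decision scores and labels realizing a confusion table under the
    sign rule (score >= 0 predicts patient)."""
    scores = np.concatenate([
        np.full(tp, 1.0), np.full(fn, -1.0),    # patients
        np.full(tn, -1.0), np.full(fp, 1.0),    # controls
    ])
    labels = np.concatenate([np.ones(tp + fn, dtype=int),
                             np.zeros(tn + fp, dtype=int)])
    return scores, labels
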