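"""Predicting imaging decision scores from clinical features.

Linear epsilon-insensitive support vector regression (SVR) inside the same
repeated nested CV design as the classifiers: median imputation and
standardization are estimated on each training partition only, C and
epsilon are selected on inner folds by mean R^2, the winner is refit on
the outer training partition, and out-of-fold predictions are averaged
over permutations into grand-mean predictions.  R^2 is reported in percent
(1 - SSE/SST on the pooled grand-mean predictions) together with the MSE,
both on the standardized target scale.  Feature importance uses the
median-based cross-validation ratio and sign consistency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.svm import LinearSVR

from . import explain
from .mlcore import C_GRID, CVPlan, _Standardizer

__all__ = ["RegressionReport", "fit_clinical_svr", "importance_similarity",
           "EPSILON_GRID"]

EPSILON_GRID = (0.01, 0.1, 0.5)


@dataclass
class RegressionReport:
    r2: float                     # percent variance explained (can be < 0)
    mse: float                    # on standardized targets
    predictions: np.ndarray       # grand-mean out-of-fold predictions
    importance: pd.DataFrame      # per-feature attribution table
    chosen: list                  # (p, k, C, epsilon) per outer partition

    def __post_init__(self):
        if self.mse < 0:
            raise ValueError("MSE must be non-negative")
        if self.r2 > 100:
            raise ValueError("R^2 cannot exceed 100 percent")


class _Imputer:
    """Median imputation with training-estimated medians."""

    def fit(self, X):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            med = np.nanmedian(X, axis=0)
        if np.any(np.isnan(med)):
            raise ValueError(
                f"all-missing feature column(s): "
                f"{np.flatnonzero(np.isnan(med)).tolist()}")
        self.median_ = med
        return self

    def transform(self, X):
        out = np.asarray(X, dtype=float).copy()
        nan = np.isnan(out)
        out[nan] = np.broadcast_to(self.median_, out.shape)[nan]
        return out


class _SVRChain:
    def __init__(self, imputer, scaler, svr):
        self.imputer, self.scaler, self.svr = imputer, scaler, svr

    def predict(self, X):
        return self.svr.predict(
            self.scaler.transform(self.imputer.transform(X)))

    def input_space_weights(self):
        w = self.svr.coef_.ravel().copy()
        nz = self.scaler.sd_ > 0
        w[nz] /= self.scaler.sd_[nz]
        w[~nz] = 0.0
        return w


def _fit_svr(X, y, C, eps, seed) -> _SVRChain:
    imp = _Imputer().fit(X)
    Z = imp.transform(X)
    scaler = _Standardizer().fit(Z)
    Z = scaler.transform(Z)
    svr = LinearSVR(C=C, epsilon=eps, loss="epsilon_insensitive", dual=True,
                    max_iter=3000, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svr.fit(Z, y)
    return _SVRChain(imp, scaler, svr)


def _r2(y_true, y_pred) -> float:
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    sse = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - sse / sst if sst > 0 else 0.0


def fit_clinical_svr(clinical: pd.DataFrame, target, plan: CVPlan,
                     C_grid=C_GRID, epsilon_grid=EPSILON_GRID,
                     standardize_target: bool = True) -> RegressionReport:
    """Nested-CV linear SVR from clinical features to decision scores.

    ``clinical`` is the patients-only feature table (may contain NaNs);
    ``target`` the matching decision scores; ``plan`` a CV plan over the
    patient sample (labels may be any stratification variable).  The
    target is z-scored once so that R^2 percent and MSE are on a
    comparable scale across imaging models.
    """
    X = clinical.to_numpy(dtype=float) if isinstance(clinical, pd.DataFrame) \
        else np.asarray(clinical, dtype=float)
    y = np.asarray(target, dtype=float)
    if X.shape[0] < 30:
        raise ValueError("need at least 30 patients")
    if not np.all(np.isfinite(y)):
        raise ValueError("target scores must be finite")
    if X.shape[0] != plan.n:
        raise ValueError("plan does not cover the patient rows")
    if standardize_target:
        y = (y - y.mean()) / (y.std() if y.std() > 0 else 1.0)

    P2, K2, K1 = plan.P2, plan.K2, plan.K1
    grid = [(C, e) for C in sorted(C_grid) for e in sorted(epsilon_grid)]
    preds = np.full((P2, plan.n), np.nan)
    weights, chosen = [], []

    for p in range(P2):
        for k in range(K2):
            tr, te = plan.outer_split(p, k)
            inner_ids = plan.inner[p, k]
            best = None
            for C, eps in grid:
                r2s = []
                for f in range(K1):
                    itr = np.flatnonzero((inner_ids >= 0) & (inner_ids != f))
                    ite = np.flatnonzero(inner_ids == f)
                    ch = _fit_svr(X[itr], y[itr], C, eps, plan.seed)
                    r2s.append(_r2(y[ite], ch.predict(X[ite])))
                crit = float(np.mean(r2s))
                if best is None or crit > best[0]:
                    best = (crit, C, eps)
            _, C_star, eps_star = best
            ch = _fit_svr(X[tr], y[tr], C_star, eps_star, plan.seed)
            preds[p, te] = ch.predict(X[te])
            weights.append(ch.input_space_weights())
            chosen.append((p, k, C_star, eps_star))

    grand = preds.mean(axis=0)
    names = list(clinical.columns) if isinstance(clinical, pd.DataFrame) \
        else None
    importance = explain.build_importance_map(np.array(weights),
                                              feature_names=names)
    return RegressionReport(
        r2=100.0 * _r2(y, grand),
        mse=float(np.mean((y - grand) ** 2)),
        predictions=grand,
        importance=importance,
        chosen=chosen,
    )


def importance_similarity(map_a: pd.DataFrame, map_b: pd.DataFrame):
    """Pearson correlation of the median-based CV-ratio vectors of two
    importance maps (same feature set).  Returns (r, p)."""
    from scipy import stats

    a = map_a["cv_ratio_median"].to_numpy(dtype=float)
    b = map_b["cv_ratio_median"].to_numpy(dtype=float)
    if a.size != b.size:
        raise ValueError("importance maps cover different feature sets")
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)
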