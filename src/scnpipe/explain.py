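"""Feature attribution and cross-model information-overlap analyses.

Two stability measures are computed over the collection of weight vectors
produced across the nested CV structure:

* the cross-validation ratio, mean weight divided by its standard error
  (a median-based variant serves the clinical regression models), and
* sign-based consistency, an exact two-sided binomial test on the number
  of positive weights against chance 0.5, Benjamini-Hochberg corrected
  across features and thresholded at -log10(adjusted p) > 1.3.

For edge models, a per-region involvement degree counts how often a region
participates in a significantly contributing edge.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cv_ratio",
    "sign_consistency",
    "build_importance_map",
    "regional_involvement",
    "score_correlations",
    "edge_pc_correlation",
]

#: sentinel magnitude for ratios with zero standard error and nonzero mean
CVR_CAP = 1e6
#: significance threshold on -log10 of the FDR-adjusted p-value
LOG10P_THRESHOLD = 1.3


def cv_ratio(weight_vectors: np.ndarray, center: str = "mean"):
    """Per-feature cross-validation ratio over M weight vectors.

    ratio_j = center_j / SE_j with SE = SD/sqrt(M) (SD with ddof=1).
    Features with SE = 0 get ratio 0 when the center is also 0, otherwise
    a capped +/-``CVR_CAP`` sentinel; the returned flag array marks the
    capped entries.  ``center='median'`` gives the median-based variant.
    """
    W = np.asarray(weight_vectors, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need at least 2 weight vectors")
    M = W.shape[0]
    c = np.median(W, axis=0) if center == "median" else W.mean(axis=0)
    se = W.std(axis=0, ddof=1) / np.sqrt(M)
    ratio = np.zeros_like(c)
    ok = se > 0
    ratio[ok] = c[ok] / se[ok]
    degenerate = (~ok) & (c != 0)
    ratio[degenerate] = np.sign(c[degenerate]) * CVR_CAP
    return ratio, degenerate


def sign_consistency(weight_vectors: np.ndarray, alpha: float = 0.05,
                     zero_policy: str = "exclude"):
    """Sign-based consistency of feature weights across CV models.

    For feature j, the number of positive weights among the trials is
    tested against a fair coin with an exact two-sided binomial test.
    ``zero_policy='exclude'`` (default) counts only nonzero weights as
    trials -- with sparse L1 models a feature that is never selected must
    not look "consistent" -- and features with fewer than 2 nonzero
    weights get p = 1.  ``'count'`` uses all M weights as trials.

    Returns (p, log10p, mask, p_adjusted): raw two-sided p-values, the
    -log10 of the BH-adjusted p-values, and the significance mask
    (-log10 adjusted p > 1.3).
    """
    W = np.asarray(weight_vectors, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need at least 2 weight vectors")
    M = W.shape[0]
    k_pos = (W > 0).sum(axis=0)
    if zero_policy == "exclude":
        m_trials = (W != 0).sum(axis=0)
    elif zero_policy == "count":
        m_trials = np.full(W.shape[1], M)
    else:
        raise ValueError("zero_policy must be 'exclude' or 'count'")

    # exact two-sided binomial p at theta = 0.5: by symmetry
    # p = min(1, 2 P(X <= min(k, m-k)))
    kmin = np.minimum(k_pos, m_trials - k_pos)
    p = np.ones(W.shape[1])
    valid = m_trials >= 2
    two_tail = 2.0 * stats.binom.cdf(kmin[valid], m_trials[valid], 0.5)
    p[valid] = np.minimum(1.0, two_tail)
    p[valid & (2 * kmin == m_trials)] = 1.0  # central tie: both tails overlap

    _, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    log10p = -np.log10(np.maximum(p_adj, 1e-300))
    mask = log10p > LOG10P_THRESHOLD
    return p, log10p, mask, p_adj


def build_importance_map(weight_vectors: np.ndarray, feature_names=None,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Full per-feature attribution table.

    Columns: mean, se, cv_ratio (mean-based), cv_ratio_median, n_positive,
    p_sign, log10p (adjusted), significant, cvr_capped.
    """
    W = np.asarray(weight_vectors, dtype=float)
    M, F = W.shape
    names = feature_names if feature_names is not None \
        else [f"f{j}" for j in range(F)]
    ratio, capped = cv_ratio(W, center="mean")
    ratio_med, _ = cv_ratio(W, center="median")
    p, log10p, mask, p_adj = sign_consistency(W, alpha=alpha)
    return pd.DataFrame({
        "feature": names,
        "mean": W.mean(axis=0),
        "se": W.std(axis=0, ddof=1) / np.sqrt(M),
        "cv_ratio": ratio,
        "cv_ratio_median": ratio_med,
        "n_positive": (W > 0).sum(axis=0),
        "p_sign": p,
        "p_sign_fdr": p_adj,
        "log10p": log10p,
        "significant": mask,
        "cvr_capped": capped,
    })


def regional_involvement(edge_mask: np.ndarray, d: int) -> np.ndarray:
    """Degree of each region in the significant-edge network.

    ``edge_mask`` is a boolean vector over the canonical upper-triangle
    edge ordering; the result counts, per region, the flagged edges
    incident to it (so the degrees sum to twice the number of flags).
    """
    mask = np.asarray(edge_mask, dtype=bool).ravel()
    if mask.size != d * (d - 1) // 2:
        raise ValueError(
            f"edge mask length {mask.size} != d(d-1)/2 = {d * (d - 1) // 2}")
    iu, ju = np.triu_indices(d, k=1)
    deg = np.zeros(d, dtype=int)
    np.add.at(deg, iu[mask], 1)
    np.add.at(deg, ju[mask], 1)
    return deg


def score_correlations(score_table: np.ndarray, model_names=None,
                       alpha: float = 0.05):
    """Pairwise Pearson correlations among model decision scores.

    Returns (r matrix, p matrix, FDR significance mask over off-diagonal
    pairs).  Raises on constant score columns.
    """
    S = np.asarray(score_table, dtype=float)
    if S.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    k = S.shape[1]
    if np.any(np.ptp(S, axis=0) == 0):
        raise ValueError("constant decision-score column")
    r = np.eye(k)
    p = np.zeros((k, k))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            ri, pi = stats.pearsonr(S[:, i], S[:, j])
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
            pairs.append(pi)
    mask = np.zeros((k, k), dtype=bool)
    if pairs:
        rej, *_ = multipletests(pairs, alpha=alpha, method="fdr_bh")
        idx = 0
        for i in range(k):
            for j in range(i + 1, k):
                mask[i, j] = mask[j, i] = rej[idx]
                idx += 1
    return r, p, mask


def edge_pc_correlation(edge_features: np.ndarray, roi_features: np.ndarray,
                        covariates: np.ndarray):
    """Correlate each processed edge feature with PC1 of the processed
    regional features.

    Regional features are covariate-adjusted and standardized before PCA
    (performed on the full sample, outside any CV); each edge column is
    Pearson-correlated with the first component score.  Returns
    (per-edge r, mean r, (min r, max r)).
    """
    from sklearn.decomposition import PCA

    from .mlcore import Residualizer, _Standardizer

    E = np.asarray(edge_features, dtype=float)
    R = np.asarray(roi_features, dtype=float)
    if E.shape[0] != R.shape[0]:
        raise ValueError("edge and regional tables must share subjects")
    if E.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    res = Residualizer().fit(R, covariates)
    Z = res.transform(R, covariates)
    Z = _Standardizer().fit(Z).transform(Z)
    pc1 = PCA(n_components=1).fit_transform(Z).ravel()

    Ec = E - E.mean(axis=0)
    pc = pc1 - pc1.mean()
    denom = np.sqrt((Ec ** 2).sum(axis=0) * (pc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Ec.T @ pc / denom, 0.0)
    return r, float(np.mean(r)), (float(np.min(r)), float(np.max(r)))
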