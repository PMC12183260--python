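"""Nested pooled cross-validation, linear SVC branches, and stacking.

The design is a repeated nested CV: P2 outer permutations of K2 stratified
outer folds, with K1 inner folds nested in each outer training partition.
Hyperparameters are selected on inner folds by mean balanced accuracy
(BAC); the winning configuration is refit on the full outer training
partition and scored on the outer test fold.  Per-subject grand-mean
decision scores average the out-of-fold scores over permutations; class
membership uses the sign of the grand mean (patients positive).

Two preprocessing/model branches exist:

* LASSO -- covariate residualization, feature-wise standardization, then a
  LIBLINEAR L1-penalized squared-hinge SVC (sparse weights acting as
  embedded feature selection);
* PCA -- residualization, PCA with the number of components on a small
  grid, standardization of the component scores, then an L2-penalized
  hinge SVC.

Stacked generalization trains a meta L2-SVC on the base models'
out-of-fold decision scores inside the identical CV structure; scores a
base model produced for a subject while that subject was in an inner test
fold are the only ones ever used as meta training input (the out-of-fold
contract), which is audited via provenance records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from . import evalstats

__all__ = [
    "C_GRID",
    "NPC_GRID",
    "CVPlan",
    "build_cv_plan",
    "Residualizer",
    "residualize_covariates",
    "FitResult",
    "fit_unimodal",
    "stack",
    "LeakageError",
]

#: slack-parameter grid shared by all linear models: C = 2^x, x = -6..4
C_GRID = tuple(2.0 ** x for x in range(-6, 5))
#: principal-component grid for the PCA branch
NPC_GRID = (5, 10, 15, 20, 25)


class LeakageError(RuntimeError):
    """Raised when a stacking input violates the out-of-fold contract."""


# ---------------------------------------------------------------------------
# cross-validation plan

@dataclass
class CVPlan:
    """Subject assignments for the repeated nested CV.

    ``outer[p, s]`` is the outer test-fold id of subject s in permutation
    p; ``inner[p, k, s]`` is the inner fold id of s within outer training
    partition (p, k), or -1 when s is in the outer test fold.
    """

    outer: np.ndarray
    inner: np.ndarray
    labels: np.ndarray
    K2: int
    P2: int
    K1: int
    seed: int

    @property
    def n(self) -> int:
        return self.labels.size

    def outer_split(self, p: int, k: int):
        te = np.flatnonzero(self.outer[p] == k)
        tr = np.flatnonzero(self.outer[p] != k)
        return tr, te


def build_cv_plan(labels, K2: int = 10, P2: int = 10, K1: int = 10,
                  seed: int = 0) -> CVPlan:
    """Stratified repeated nested CV assignments, deterministic in seed."""
    y = np.asarray(labels).astype(int)
    n = y.size
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < K2:
        raise ValueError(
            f"smallest class ({counts.min()}) is below the outer fold "
            f"count K2={K2}")
    if (counts.min() * (K2 - 1)) // K2 < K1:
        raise ValueError(
            f"smallest class cannot populate K1={K1} inner folds")
    rng = np.random.default_rng(seed)
    outer = np.empty((P2, n), dtype=int)
    inner = np.full((P2, K2, n), -1, dtype=int)
    for p in range(P2):
        skf = StratifiedKFold(n_splits=K2, shuffle=True,
                              random_state=int(rng.integers(2 ** 31)))
        for k, (_, te) in enumerate(skf.split(np.zeros(n), y)):
            outer[p, te] = k
        for k in range(K2):
            tr = np.flatnonzero(outer[p] != k)
            skf1 = StratifiedKFold(n_splits=K1, shuffle=True,
                                   random_state=int(rng.integers(2 ** 31)))
            for f, (_, te1) in enumerate(skf1.split(np.zeros(tr.size), y[tr])):
                inner[p, k, tr[te1]] = f
    return CVPlan(outer=outer, inner=inner, labels=y, K2=K2, P2=P2, K1=K1,
                  seed=seed)


# ---------------------------------------------------------------------------
# preprocessing blocks

class Residualizer:
    """OLS removal of covariate effects, frozen on training subjects.

    Fits, per feature, least squares on [intercept, covariates] and
    returns residuals; the frozen coefficients are applied unchanged to
    test subjects (no refitting, no leakage).
    """

    def fit(self, X: np.ndarray, covariates: np.ndarray) -> "Residualizer":
        D = self._design(covariates)
        rank = np.linalg.matrix_rank(D)
        if rank < D.shape[1]:
            raise ValueError("covariate design matrix is rank-deficient")
        self.beta_, *_ = np.linalg.lstsq(D, X, rcond=None)
        return self

    def transform(self, X: np.ndarray, covariates: np.ndarray) -> np.ndarray:
        return X - self._design(covariates) @ self.beta_

    @staticmethod
    def _design(covariates: np.ndarray) -> np.ndarray:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        return np.column_stack([np.ones(C.shape[0]), C])


def residualize_covariates(features: np.ndarray, covariates: np.ndarray,
                           fit_on: np.ndarray):
    """Residualize all rows using coefficients fit on ``fit_on`` rows only.

    Returns (adjusted features, frozen Residualizer).
    """
    X = np.asarray(features, dtype=float)
    res = Residualizer().fit(X[fit_on], np.asarray(covariates)[fit_on])
    return res.transform(X, covariates), res


class _Standardizer:
    def fit(self, X):
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0)
        return self

    def transform(self, X):
        out = X - self.mean_
        nz = self.sd_ > 0
        out[:, nz] /= self.sd_[nz]
        out[:, ~nz] = 0.0  # zero-SD features pass through as zeros
        return out


@dataclass
class FittedChain:
    """Frozen preprocessing + linear model for one training partition."""

    branch: str
    C: float
    n_pc: int | None
    resid: Residualizer
    pca: object
    scaler: _Standardizer
    svc: LinearSVC

    def decision_function(self, X: np.ndarray,
                          covariates: np.ndarray) -> np.ndarray:
        Z = self.resid.transform(np.asarray(X, dtype=float), covariates)
        if self.pca is not None:
            Z = self.pca.transform(Z)
        Z = self.scaler.transform(Z)
        return self.svc.decision_function(Z)

    def input_space_weights(self) -> np.ndarray:
        """Model weights mapped back to input-feature space.

        Standardization and PCA are linear, so the hyperplane normal can be
        expressed on the (residualized) input features; PCA-branch weights
        are back-projected through the component basis, making attribution
        maps comparable across branches.
        """
        w = self.svc.coef_.ravel().copy()
        nz = self.scaler.sd_ > 0
        w[nz] /= self.scaler.sd_[nz]
        w[~nz] = 0.0
        if self.pca is not None:
            w = self.pca.components_.T @ w
        return w


def _fit_chain(X, cov, y, branch, C, n_pc, seed=0) -> FittedChain:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("degenerate single-class training fold")
    resid = Residualizer().fit(X, cov)
    Z = resid.transform(X, cov)
    pca = None
    if branch == "pca":
        pca = PCA(n_components=min(n_pc, Z.shape[0] - 1, Z.shape[1]),
                  random_state=seed)
        Z = pca.fit_transform(Z)
    scaler = _Standardizer().fit(Z)
    Z = scaler.transform(Z)
    # class weights: inverse class frequency of the training partition
    if branch == "lasso":
        svc = LinearSVC(penalty="l1", loss="squared_hinge", dual=False,
                        C=C, class_weight="balanced", max_iter=2000,
                        tol=1e-3, random_state=seed)
    else:
        svc = LinearSVC(penalty="l2", loss="hinge", dual=True, C=C,
                        class_weight="balanced", max_iter=20000,
                        random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(Z, y)
    return FittedChain(branch=branch, C=C, n_pc=n_pc, resid=resid, pca=pca,
                       scaler=scaler, svc=svc)


def _bac_from_scores(scores: np.ndarray, y: np.ndarray) -> float:
    pred = (scores >= 0).astype(int)
    pats, ctrl = y == 1, y == 0
    sens = (pred[pats] == 1).mean() if pats.any() else 0.0
    spec = (pred[ctrl] == 0).mean() if ctrl.any() else 0.0
    return 100.0 * (sens + spec) / 2.0


# ---------------------------------------------------------------------------
# results containers

@dataclass
class OOFRecord:
    """Provenance-tagged out-of-fold scores for one outer partition."""

    indices: np.ndarray          # training-subject indices (global)
    scores: np.ndarray           # out-of-fold decision scores, same order
    fold_ids: np.ndarray         # inner fold in which each score was made
    tag: str = "inner_oof"


@dataclass
class PartitionModel:
    p: int
    k: int
    chain: FittedChain
    C: float
    n_pc: int | None
    test_idx: np.ndarray
    inner_oof: OOFRecord | None = None


@dataclass
class DecisionScores:
    per_permutation: np.ndarray   # (P2, n)
    grand_mean: np.ndarray        # (n,)
    predicted: np.ndarray         # (n,) in {0, 1}


@dataclass
class FitResult:
    """Output of :func:`fit_unimodal` or :func:`stack`."""

    partitions: list
    scores: DecisionScores
    report: "evalstats.PerformanceReport"
    per_fold_bac: pd.DataFrame    # columns: permutation, fold, bac
    weights: np.ndarray           # (P2*K2, n_features) input-space weights
    plan: CVPlan
    branch: str

    @property
    def bac(self) -> float:
        return self.report.bac

    def manifest(self) -> dict:
        """Run manifest: grids, seeds, and chosen hyperparameters."""
        return {
            "branch": self.branch,
            "plan": {"K2": self.plan.K2, "P2": self.plan.P2,
                     "K1": self.plan.K1, "seed": self.plan.seed},
            "chosen": [{"p": m.p, "k": m.k, "C": m.C, "n_pc": m.n_pc}
                       for m in self.partitions],
        }


# ---------------------------------------------------------------------------
# unimodal fitting

def _hyper_grid(branch, C_grid, npc_grid):
    if branch == "lasso":
        return [(C, None) for C in sorted(C_grid)]
    return [(C, npc) for C in sorted(C_grid) for npc in sorted(npc_grid)]


def fit_unimodal(features, labels, covariates, plan: CVPlan,
                 branch: str = "lasso", C_grid=C_GRID, npc_grid=NPC_GRID,
                 collect_inner_oof: bool = True,
                 pooled_predictions: bool = False) -> FitResult:
    """Run the full nested-CV pipeline for one feature modality.

    Inner folds score every hyperparameter setting by BAC (averaged per
    inner fold by default; ``pooled_predictions=True`` pools inner test
    predictions before one BAC); the argmax setting (ties: smaller C, then
    smaller component count) is refit on the outer training partition and
    applied to the outer test fold.
    """
    if branch not in ("lasso", "pca"):
        raise ValueError("branch must be 'lasso' or 'pca'")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    cov = np.asarray(covariates, dtype=float)
    if X.shape[0] != plan.n:
        raise ValueError("plan does not cover the feature rows")
    grid = _hyper_grid(branch, C_grid, npc_grid)

    P2, K2, K1 = plan.P2, plan.K2, plan.K1
    scores = np.full((P2, plan.n), np.nan)
    partitions, weights, fold_rows = [], [], []

    for p in range(P2):
        for k in range(K2):
            tr, te = plan.outer_split(p, k)
            inner_ids = plan.inner[p, k]
            best = None
            for C, n_pc in grid:
                fold_bacs, pooled_s, pooled_y = [], [], []
                for f in range(K1):
                    itr = np.flatnonzero((inner_ids >= 0) & (inner_ids != f))
                    ite = np.flatnonzero(inner_ids == f)
                    chain = _fit_chain(X[itr], cov[itr], y[itr], branch, C,
                                       n_pc, seed=plan.seed)
                    s = chain.decision_function(X[ite], cov[ite])
                    fold_bacs.append(_bac_from_scores(s, y[ite]))
                    pooled_s.append(s)
                    pooled_y.append(y[ite])
                if pooled_predictions:
                    crit = _bac_from_scores(np.concatenate(pooled_s),
                                            np.concatenate(pooled_y))
                else:
                    crit = float(np.mean(fold_bacs))
                if best is None or crit > best[0]:
                    best = (crit, C, n_pc)
            _, C_star, npc_star = best
            chain = _fit_chain(X[tr], cov[tr], y[tr], branch, C_star,
                               npc_star, seed=plan.seed)
            s_te = chain.decision_function(X[te], cov[te])
            scores[p, te] = s_te
            weights.append(chain.input_space_weights())
            fold_rows.append((p, k, _bac_from_scores(s_te, y[te])))

            oof = None
            if collect_inner_oof:
                oof_scores = np.full(tr.size, np.nan)
                oof_folds = np.full(tr.size, -1)
                pos = {s_: i for i, s_ in enumerate(tr)}
                for f in range(K1):
                    itr = np.flatnonzero((inner_ids >= 0) & (inner_ids != f))
                    ite = np.flatnonzero(inner_ids == f)
                    ch = _fit_chain(X[itr], cov[itr], y[itr], branch, C_star,
                                    npc_star, seed=plan.seed)
                    s_in = ch.decision_function(X[ite], cov[ite])
                    for s_, v in zip(ite, s_in):
                        oof_scores[pos[s_]] = v
                        oof_folds[pos[s_]] = f
                oof = OOFRecord(indices=tr, scores=oof_scores,
                                fold_ids=oof_folds)
            partitions.append(PartitionModel(
                p=p, k=k, chain=chain, C=C_star, n_pc=npc_star,
                test_idx=te, inner_oof=oof))

    grand = scores.mean(axis=0)
    ds = DecisionScores(per_permutation=scores, grand_mean=grand,
                        predicted=(grand >= 0).astype(int))
    report = evalstats.classification_metrics(grand, y)
    per_fold = pd.DataFrame(fold_rows, columns=["permutation", "fold", "bac"])
    return FitResult(partitions=partitions, scores=ds, report=report,
                     per_fold_bac=per_fold, weights=np.array(weights),
                     plan=plan, branch=branch)


# ---------------------------------------------------------------------------
# stacked generalization

def _audit_oof(base: FitResult, plan: CVPlan) -> None:
    """Verify the out-of-fold contract on a base model's provenance."""
    for m in base.partitions:
        if m.inner_oof is None:
            raise LeakageError(
                "base model carries no inner out-of-fold scores; refit with "
                "collect_inner_oof=True")
        rec = m.inner_oof
        if rec.tag != "inner_oof":
            raise LeakageError(
                f"partition ({m.p},{m.k}): score provenance tag "
                f"'{rec.tag}' is not out-of-fold")
        expected = plan.inner[m.p, m.k, rec.indices]
        if not np.array_equal(expected, rec.fold_ids):
            raise LeakageError(
                f"partition ({m.p},{m.k}): recorded score folds do not "
                "match the CV plan (possible in-fold score substitution)")
        if np.any(rec.fold_ids < 0) or np.any(np.isnan(rec.scores)):
            raise LeakageError(
                f"partition ({m.p},{m.k}): incomplete out-of-fold coverage")


def stack(base_results, labels, plan: CVPlan, C_grid=C_GRID,
          collect_inner_oof: bool = True) -> FitResult:
    """Meta L2-SVC on the base models' out-of-fold decision scores.

    For each outer partition the meta training feature of subject s is the
    score base model b produced while s sat in an inner test fold; meta
    features are standardized with training-partition statistics; the meta
    test feature is the base model's outer-test score.  C is selected on
    the plan's inner folds with the usual rule.  The returned result again
    carries inner out-of-fold provenance, so stackers can be stacked.
    """
    y = np.asarray(labels).astype(int)
    if len(base_results) < 1:
        raise ValueError("need at least one base model")
    for b in base_results:
        if b.plan is not plan and not (
                np.array_equal(b.plan.outer, plan.outer)
                and np.array_equal(b.plan.inner, plan.inner)):
            raise LeakageError("base model was fit under a different CV plan")
        _audit_oof(b, plan)

    B = len(base_results)
    P2, K2, K1 = plan.P2, plan.K2, plan.K1
    scores = np.full((P2, plan.n), np.nan)
    partitions, weights, fold_rows = [], [], []

    for p in range(P2):
        for k in range(K2):
            tr, te = plan.outer_split(p, k)
            idx = p * K2 + k
            Xtr = np.column_stack([
                b.partitions[idx].inner_oof.scores for b in base_results])
            Xte = np.column_stack([
                b.scores.per_permutation[p, te] for b in base_results])
            inner_ids = plan.inner[p, k, tr]

            best = None
            for C in sorted(C_grid):
                fold_bacs = []
                for f in range(K1):
                    itr = np.flatnonzero((inner_ids >= 0) & (inner_ids != f))
                    ite = np.flatnonzero(inner_ids == f)
                    ch = _fit_meta(Xtr[itr], y[tr][itr], C, plan.seed)
                    s = ch.decision_function(Xtr[ite])
                    fold_bacs.append(_bac_from_scores(s, y[tr][ite]))
                crit = float(np.mean(fold_bacs))
                if best is None or crit > best[0]:
                    best = (crit, C)
            C_star = best[1]
            meta = _fit_meta(Xtr, y[tr], C_star, plan.seed)
            s_te = meta.decision_function(Xte)
            scores[p, te] = s_te
            weights.append(meta.coef_scaled())
            fold_rows.append((p, k, _bac_from_scores(s_te, y[te])))

            oof = None
            if collect_inner_oof:
                oof_scores = np.full(tr.size, np.nan)
                oof_folds = np.full(tr.size, -1)
                for f in range(K1):
                    itr = np.flatnonzero((inner_ids >= 0) & (inner_ids != f))
                    ite = np.flatnonzero(inner_ids == f)
                    ch = _fit_meta(Xtr[itr], y[tr][itr], C_star, plan.seed)
                    oof_scores[ite] = ch.decision_function(Xtr[ite])
                    oof_folds[ite] = f
                oof = OOFRecord(indices=tr, scores=oof_scores,
                                fold_ids=oof_folds)
            partitions.append(PartitionModel(
                p=p, k=k, chain=meta, C=C_star, n_pc=None, test_idx=te,
                inner_oof=oof))

    grand = scores.mean(axis=0)
    ds = DecisionScores(per_permutation=scores, grand_mean=grand,
                        predicted=(grand >= 0).astype(int))
    report = evalstats.classification_metrics(grand, y)
    per_fold = pd.DataFrame(fold_rows, columns=["permutation", "fold", "bac"])
    return FitResult(partitions=partitions, scores=ds, report=report,
                     per_fold_bac=per_fold, weights=np.array(weights),
                     plan=plan, branch="stack")


class _MetaChain:
    """Standardize-then-L2-SVC chain used by the stacker."""

    def __init__(self, scaler, svc):
        self.scaler, self.svc = scaler, svc

    def decision_function(self, X):
        return self.svc.decision_function(self.scaler.transform(
            np.asarray(X, dtype=float).copy()))

    def coef_scaled(self):
        w = self.svc.coef_.ravel().copy()
        nz = self.scaler.sd_ > 0
        w[nz] /= self.scaler.sd_[nz]
        w[~nz] = 0.0
        return w


def _fit_meta(X, y, C, seed) -> _MetaChain:
    if np.unique(y).size < 2:
        raise ValueError("degenerate single-class training fold")
    scaler = _Standardizer().fit(np.asarray(X, dtype=float))
    Z = scaler.transform(np.asarray(X, dtype=float).copy())
    svc = LinearSVC(penalty="l2", loss="hinge", dual=True, C=C,
                    class_weight="balanced", max_iter=20000,
                    random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        svc.fit(Z, y)
    return _MetaChain(scaler, svc)
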