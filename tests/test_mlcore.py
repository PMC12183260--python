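"""Nested CV machinery: plan structure, residualization contracts,
hyperparameter grids, decision scores, and the stacking out-of-fold audit."""

import numpy as np
import pytest

from scnpipe.mlcore import (C_GRID, NPC_GRID, LeakageError, Residualizer,
                            build_cv_plan, fit_unimodal,
                            residualize_covariates, stack)


def _toy_problem(n_per_class=60, d=20, effect=1.2, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([0] * n_per_class + [1] * n_per_class)
    X = rng.normal(size=(n, d))
    X[y == 1, :5] += effect
    cov = np.column_stack([rng.normal(35, 10, n), rng.integers(0, 2, n)])
    return X, y, cov


class TestCVPlan:
    def test_each_subject_tested_once_per_permutation(self):
        y = np.array([0] * 40 + [1] * 30)
        plan = build_cv_plan(y, K2=5, P2=3, K1=4, seed=0)
        for p in range(3):
            counts = np.bincount(plan.outer[p], minlength=5)
            assert counts.sum() == 70
            for k in range(5):
                tr, te = plan.outer_split(p, k)
                assert np.intersect1d(tr, te).size == 0
                assert tr.size + te.size == 70

    def test_stratification_within_one_subject(self):
        y = np.array([0] * 44 + [1] * 26)
        plan = build_cv_plan(y, K2=5, P2=2, K1=3, seed=1)
        for p in range(2):
            for k in range(5):
                te = np.flatnonzero(plan.outer[p] == k)
                n_pat = y[te].sum()
                assert abs(n_pat - 26 / 5) <= 1

    def test_inner_folds_partition_training_set(self):
        y = np.array([0] * 30 + [1] * 30)
        plan = build_cv_plan(y, K2=5, P2=1, K1=4, seed=2)
        for k in range(5):
            tr, te = plan.outer_split(0, k)
            inner = plan.inner[0, k]
            assert (inner[te] == -1).all()
            assert (inner[tr] >= 0).all()
            assert set(np.unique(inner[tr])) == set(range(4))

    def test_different_seeds_differ(self):
        y = np.array([0] * 30 + [1] * 30)
        a = build_cv_plan(y, K2=5, P2=1, K1=3, seed=3)
        b = build_cv_plan(y, K2=5, P2=1, K1=3, seed=4)
        assert not np.array_equal(a.outer, b.outer)

    def test_class_smaller_than_folds_rejected(self):
        y = np.array([0] * 30 + [1] * 4)
        with pytest.raises(ValueError, match="K2"):
            build_cv_plan(y, K2=5, P2=1, K1=3, seed=0)


class TestResidualization:
    def test_planted_age_effect_removed(self):
        rng = np.random.default_rng(5)
        n = 500
        age = rng.normal(40, 12, n)
        cov = np.column_stack([age, rng.integers(0, 2, n)])
        X = (3.0 * age + rng.normal(0, 1, n))[:, None]
        adj, _ = residualize_covariates(X, cov, np.arange(n))
        r = np.corrcoef(adj[:, 0], age)[0, 1]
        assert abs(r) < 0.05

    def test_orthogonal_covariates_only_demean(self):
        rng = np.random.default_rng(6)
        n = 2000
        cov = np.column_stack([rng.normal(size=n), rng.integers(0, 2, n)])
        X = rng.normal(5.0, 1.0, size=(n, 3))
        adj, _ = residualize_covariates(X, cov, np.arange(n))
        np.testing.assert_allclose(adj, X - X.mean(0), atol=0.25)

    def test_frozen_coefficients_ignore_test_data(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 4))
        cov = rng.normal(size=(30, 2))
        res = Residualizer().fit(X[:20], cov[:20])
        beta_before = res.beta_.copy()
        res.transform(rng.normal(size=(10, 4)) * 100, cov[20:])
        np.testing.assert_array_equal(res.beta_, beta_before)

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(20, 3))
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank"):
            Residualizer().fit(X, np.column_stack([c, 2 * c]))


class TestGrids:
    def test_c_grid_has_eleven_powers_of_two(self):
        assert len(C_GRID) == 11
        assert C_GRID[0] == 2.0 ** -6 and C_GRID[-1] == 2.0 ** 4
        ratios = np.diff(np.log2(np.array(C_GRID)))
        np.testing.assert_allclose(ratios, 1.0)

    def test_npc_grid(self):
        assert NPC_GRID == (5, 10, 15, 20, 25)


class TestFitUnimodal:
    def test_separable_data_high_training_bac(self):
        X, y, cov = _toy_problem(effect=1.5, seed=10)
        plan = build_cv_plan(y, K2=5, P2=1, K1=3, seed=10)
        res = fit_unimodal(X, y, cov, plan, branch="lasso",
                           collect_inner_oof=False)
        assert res.report.bac > 90

    def test_label_permutation_near_chance(self):
        X, y, cov = _toy_problem(effect=0.0, n_per_class=100, seed=11)
        plan = build_cv_plan(y, K2=5, P2=1, K1=3, seed=11)
        res = fit_unimodal(X, np.random.default_rng(0).permutation(y), cov,
                           plan, branch="lasso", collect_inner_oof=False)
        # binomial band around 50 % for n=200
        assert 40 < res.report.bac < 60

    def test_scores_cover_every_subject_every_permutation(self):
        X, y, cov = _toy_problem(n_per_class=30, seed=12)
        plan = build_cv_plan(y, K2=5, P2=2, K1=3, seed=12)
        res = fit_unimodal(X, y, cov, plan, branch="lasso")
        assert not np.isnan(res.scores.per_permutation).any()
        np.testing.assert_allclose(
            res.scores.grand_mean,
            res.scores.per_permutation.mean(axis=0))

    def test_pca_branch_runs_and_backprojects_weights(self):
        X, y, cov = _toy_problem(n_per_class=40, d=12, seed=13)
        plan = build_cv_plan(y, K2=5, P2=1, K1=3, seed=13)
        res = fit_unimodal(X, y, cov, plan, branch="pca",
                           npc_grid=(2, 4), collect_inner_oof=False)
        assert res.weights.shape == (5, 12)
        assert res.report.bac > 70

    def test_manifest_records_choices(self):
        X, y, cov = _toy_problem(n_per_class=30, seed=14)
        plan = build_cv_plan(y, K2=5, P2=1, K1=3, seed=14)
        res = fit_unimodal(X, y, cov, plan, branch="lasso",
                           collect_inner_oof=False)
        man = res.manifest()
        assert len(man["chosen"]) == 5
        assert all(c["C"] in C_GRID for c in man["chosen"])

    def test_deterministic_given_plan(self):
        X, y, cov = _toy_problem(n_per_class=30, seed=15)
        plan = build_cv_plan(y, K2=5, P2=1, K1=3, seed=15)
        a = fit_unimodal(X, y, cov, plan, branch="lasso",
                         collect_inner_oof=False)
        b = fit_unimodal(X, y, cov, plan, branch="lasso",
                         collect_inner_oof=False)
        np.testing.assert_array_equal(a.scores.grand_mean,
                                      b.scores.grand_mean)


class TestStacking:
    def _bases(self, seed=20):
        X, y, cov = _toy_problem(n_per_class=50, d=15, effect=1.5, seed=seed)
        plan = build_cv_plan(y, K2=5, P2=1, K1=3, seed=seed)
        good = fit_unimodal(X, y, cov, plan, branch="lasso")
        rng = np.random.default_rng(seed + 1)
        noise = fit_unimodal(rng.normal(size=X.shape), y, cov, plan,
                             branch="lasso")
        return y, plan, good, noise

    def test_stacker_tracks_best_base(self):
        y, plan, good, noise = self._bases()
        st = stack([good, noise], y, plan, collect_inner_oof=False)
        assert st.report.bac >= good.report.bac - 2.0

    def test_input_dimensionality_is_number_of_bases(self):
        y, plan, good, noise = self._bases(seed=21)
        st = stack([good, noise], y, plan, collect_inner_oof=False)
        assert st.weights.shape[1] == 2

    def test_leakage_tripwire_on_tampered_provenance(self):
        y, plan, good, noise = self._bases(seed=22)
        rec = good.partitions[0].inner_oof
        rec.fold_ids = rec.fold_ids.copy()
        rec.fold_ids[0] = (rec.fold_ids[0] + 1) % plan.K1  # in-fold swap
        with pytest.raises(LeakageError, match="plan"):
            stack([good, noise], y, plan)

    def test_missing_oof_scores_rejected(self):
        X, y, cov = _toy_problem(n_per_class=40, seed=23)
        plan = build_cv_plan(y, K2=5, P2=1, K1=3, seed=23)
        base = fit_unimodal(X, y, cov, plan, branch="lasso",
                            collect_inner_oof=False)
        with pytest.raises(LeakageError, match="out-of-fold"):
            stack([base], y, plan)

    def test_foreign_plan_rejected(self):
        y, plan, good, _ = self._bases(seed=24)
        other = build_cv_plan(y, K2=5, P2=1, K1=3, seed=99)
        with pytest.raises(LeakageError, match="different"):
            stack([good], y, other)

    def test_stackers_can_be_stacked(self):
        y, plan, good, noise = self._bases(seed=25)
        level2 = stack([good, noise], y, plan, collect_inner_oof=True)
        level3 = stack([level2, good], y, plan, collect_inner_oof=False)
        assert level3.report.bac >= good.report.bac - 5.0
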