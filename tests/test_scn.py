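"""SCN construction: harmonization, group/REF/KLS networks, densities,
divergences and edge vectorization, each against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scnpipe.gmv import RegionalGMVTable, extract_regional_gmv
from scnpipe.scn import (DensityEstimate, devectorize, estimate_pdf,
                         group_scn, harmonize_sites, kls_divergence,
                         kls_scn_individual, ref_scn_individual,
                         silverman_bandwidth, vectorize_edges)
from scnpipe.synthgen import CohortConfig, ParcellatedSubject, generate_cohort


def _table(values, sites=None):
    n, d = values.shape
    idx = pd.Index([f"s{i}" for i in range(n)], name="subject_id")
    data = pd.DataFrame(values, index=idx,
                        columns=[f"P{j}" for j in range(d)])
    meta = pd.DataFrame({
        "age": 30.0, "sex": 0,
        "site": sites if sites is not None else 0,
        "label": "HC"}, index=idx)
    return RegionalGMVTable(data, meta)


class TestHarmonization:
    def test_single_site_identity(self, rng):
        t = _table(rng.random((6, 4)))
        out = harmonize_sites(t)
        np.testing.assert_allclose(out.values, t.values, atol=1e-12)

    def test_two_sites_align_and_preserve_grand_mean(self, rng):
        X = rng.random((10, 3))
        sites = np.array([0] * 5 + [1] * 5)
        X[sites == 1] += 2.5
        t = _table(X, sites)
        out = harmonize_sites(t)
        m0 = out.values[sites == 0].mean(0)
        m1 = out.values[sites == 1].mean(0)
        np.testing.assert_allclose(m0, m1, atol=1e-9)
        np.testing.assert_allclose(out.values.mean(0), X.mean(0), atol=1e-9)

    def test_matches_groupwise_mean_oracle(self, rng):
        X = rng.random((9, 4))
        sites = np.array([0, 0, 0, 1, 1, 2, 2, 2, 2])
        out = harmonize_sites(_table(X, sites)).values
        grand = X.mean(0)
        for s in (0, 1, 2):
            m = sites == s
            np.testing.assert_allclose(
                out[m], X[m] - X[m].mean(0) + grand, atol=1e-12)

    def test_small_site_rejected(self, rng):
        t = _table(rng.random((4, 3)), sites=np.array([0, 0, 0, 1]))
        with pytest.raises(ValueError, match="fewer than 2"):
            harmonize_sites(t)


class TestGroupSCN:
    def test_perfect_linear_relation(self, rng):
        x = rng.random(8)
        X = np.column_stack([x, 2 * x + 5, -x + 1])
        W = group_scn(_table(X)).matrix
        assert W[0, 1] == pytest.approx(1.0)
        assert W[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(W), 0)

    def test_matches_pairwise_correlation_oracle(self, rng):
        X = rng.random((10, 6))
        W = group_scn(_table(X)).matrix
        for i in range(6):
            for j in range(i + 1, 6):
                r, _ = stats.pearsonr(X[:, i], X[:, j])
                assert W[i, j] == pytest.approx(r, abs=1e-12)

    def test_zero_variance_parcel_named(self, rng):
        X = rng.random((5, 3))
        X[:, 1] = 7.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            group_scn(_table(X))


class TestRefSCN:
    def test_individual_on_regression_line_of_perfect_pair(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        ref = np.column_stack([x, 3 * x + 2])
        W = ref_scn_individual(np.array([5.0, 17.0]), ref).matrix
        assert W[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_parcel_oracle(self):
        ref = np.array([[1.0, 2.0, 5.0],
                        [2.0, 1.0, 4.0],
                        [4.0, 6.0, 1.0]])
        ind = np.array([3.0, 3.0, 3.0])
        R_ref = np.corrcoef(ref, rowvar=False)
        R_aug = np.corrcoef(np.vstack([ref, ind]), rowvar=False)
        expected = R_aug - R_ref
        np.fill_diagonal(expected, 0.0)
        W = ref_scn_individual(ind, ref).matrix
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_duplicated_reference_subject(self, rng):
        ref = rng.random((7, 4))
        ind = ref[2]
        W = ref_scn_individual(ind, ref).matrix
        R_aug = np.corrcoef(np.vstack([ref, ind]), rowvar=False)
        R_ref = np.corrcoef(ref, rowvar=False)
        expected = R_aug - R_ref
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_random_instances_match_two_correlation_oracle(self, rng):
        for _ in range(25):
            n, d = int(rng.integers(4, 12)), int(rng.integers(2, 6))
            ref = rng.random((n, d))
            ind = rng.random(d)
            W = ref_scn_individual(ind, ref).matrix
            expected = (np.corrcoef(np.vstack([ref, ind]), rowvar=False)
                        - np.corrcoef(ref, rowvar=False))
            np.fill_diagonal(expected, 0.0)
            np.testing.assert_allclose(W, expected, atol=1e-12)

    def test_average_individual_edges_shrink_with_reference_size(self, rng):
        """The reference-mean individual perturbs a large reference less
        than a small one."""
        d = 6
        cov = 0.5 * np.ones((d, d)) + 0.5 * np.eye(d)
        big = rng.multivariate_normal(np.zeros(d), cov, size=500)
        small = big[:50]
        ind = big.mean(axis=0)
        w_small = np.abs(ref_scn_individual(ind, small).matrix).max()
        w_big = np.abs(ref_scn_individual(ind, big).matrix).max()
        assert w_big < w_small


class TestDensity:
    def test_symmetry_about_center(self):
        x = np.concatenate([np.linspace(-1, 1, 50)]) + 5.0
        grid = np.linspace(3.0, 7.0, 201)
        est = estimate_pdf(x, grid)
        np.testing.assert_allclose(est.mass, est.mass[::-1], rtol=1e-8)

    def test_mass_normalized(self, rng):
        for _ in range(10):
            x = rng.normal(size=30)
            est = estimate_pdf(x, np.linspace(-5, 5, 128))
            assert abs(est.mass.sum() - 1.0) < 1e-9
            assert (est.mass > 0).all()

    def test_close_to_true_gaussian_in_total_variation(self, rng):
        x = rng.normal(size=4000)
        grid = np.linspace(-6, 6, 512)
        est = estimate_pdf(x, grid)
        true = np.exp(-0.5 * grid ** 2)
        true /= true.sum()
        tv = 0.5 * np.abs(est.mass - true).sum()
        assert tv < 0.05

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            estimate_pdf(np.ones(10), np.linspace(0, 2, 16))

    def test_bandwidth_positive_and_shrinks_with_n(self, rng):
        x = rng.normal(size=100)
        h1 = silverman_bandwidth(x)
        h2 = silverman_bandwidth(np.tile(x, 10))
        assert 0 < h2 < h1


class TestKLSDivergence:
    def _discrete_gaussian(self, mu, grid):
        m = np.exp(-0.5 * (grid - mu) ** 2)
        return DensityEstimate(grid, m / m.sum())

    def test_identical_densities_zero(self):
        g = np.linspace(-5, 5, 128)
        p = self._discrete_gaussian(0.0, g)
        assert kls_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric(self, rng):
        g = np.linspace(-4, 4, 64)
        for _ in range(5):
            m1 = np.maximum(rng.random(64), 1e-9)
            m2 = np.maximum(rng.random(64), 1e-9)
            p = DensityEstimate(g, m1 / m1.sum())
            q = DensityEstimate(g, m2 / m2.sum())
            assert kls_divergence(p, q) == pytest.approx(
                kls_divergence(q, p), rel=1e-10)

    def test_unit_shift_gaussians_close_to_one(self):
        """KL(N(0,1)||N(1,1)) = 0.5 each way, so the symmetric divergence
        of finely discretized versions is 1."""
        g = np.linspace(-6, 7, 4096)
        p = self._discrete_gaussian(0.0, g)
        q = self._discrete_gaussian(1.0, g)
        assert kls_divergence(p, q) == pytest.approx(1.0, abs=0.02)

    def test_grid_mismatch_rejected(self):
        p = self._discrete_gaussian(0.0, np.linspace(-5, 5, 64))
        q = self._discrete_gaussian(0.0, np.linspace(-4, 6, 64))
        with pytest.raises(ValueError, match="grid"):
            kls_divergence(p, q)


class TestKLSSCN:
    def _subject(self, values_by_parcel):
        return ParcellatedSubject("s0", values_by_parcel, age=30, sex=0,
                                  site=0, label="HC")

    def test_identical_parcels_give_near_zero_edges(self, rng):
        base = rng.normal(5.0, 0.5, size=40)
        sub = self._subject({1: base.copy(), 2: base.copy(), 3: base.copy()})
        W = kls_scn_individual(sub).matrix
        assert np.abs(W).max() == pytest.approx(0.0, abs=1e-9)

    def test_invariants_on_random_subject(self, small_cohort):
        W = kls_scn_individual(small_cohort[0])
        assert np.allclose(W.matrix, W.matrix.T)
        assert np.allclose(np.diag(W.matrix), 0)
        assert (W.matrix >= 0).all()

    def test_voxel_order_invariance(self, small_cohort):
        sub = small_cohort[1]
        shuffled = ParcellatedSubject(
            sub.subject_id,
            {k: v[::-1].copy() for k, v in sub.voxels.items()},
            age=sub.age, sex=sub.sex, site=sub.site, label=sub.label)
        W1 = kls_scn_individual(sub).matrix
        W2 = kls_scn_individual(shuffled).matrix
        np.testing.assert_allclose(W1, W2, rtol=1e-10)

    def test_voxel_duplication_approximately_invariant(self, rng):
        """Duplicating every voxel only changes the Silverman bandwidth
        factor n^(-1/5), so edges shift slightly but stay proportional."""
        vox = {1: rng.normal(5, 0.5, 30), 2: rng.normal(6, 0.7, 25),
               3: rng.normal(4, 0.3, 35)}
        sub = self._subject(vox)
        dup = self._subject({k: np.tile(v, 2) for k, v in vox.items()})
        e1 = vectorize_edges(kls_scn_individual(sub))
        e2 = vectorize_edges(kls_scn_individual(dup))
        r = np.corrcoef(e1, e2)[0, 1]
        assert r > 0.99
        np.testing.assert_allclose(e2, e1, rtol=0.35)

    def test_three_parcel_brute_force_oracle(self, rng):
        vox = {1: rng.normal(5, 0.5, 20), 2: rng.normal(6, 0.8, 25),
               3: rng.normal(4.5, 0.4, 30)}
        sub = self._subject(vox)
        W = kls_scn_individual(sub).matrix
        pids = [1, 2, 3]
        for a in range(3):
            for b in range(a + 1, 3):
                xi, xj = vox[pids[a]], vox[pids[b]]
                pooled = np.concatenate([xi, xj])
                h = silverman_bandwidth(pooled)
                grid = np.linspace(pooled.min() - 3 * h,
                                   pooled.max() + 3 * h, 128)
                p = estimate_pdf(xi, grid)
                q = estimate_pdf(xj, grid)
                assert W[a, b] == pytest.approx(kls_divergence(p, q),
                                                rel=1e-10)

    def test_degenerate_parcel_named(self):
        sub = self._subject({1: np.ones(10), 2: np.random.default_rng(0)
                             .normal(size=10)})
        with pytest.raises(ValueError, match="parcel 1"):
            kls_scn_individual(sub)


class TestVectorization:
    @pytest.mark.parametrize("d,expected", [(100, 4950), (200, 19900)])
    def test_edge_count(self, d, expected):
        assert d * (d - 1) // 2 == expected
        W = np.zeros((d, d))
        assert vectorize_edges(W).size == expected

    def test_round_trip(self, rng):
        for d in (3, 5, 8):
            W = rng.random((d, d))
            W = (W + W.T) / 2
            np.fill_diagonal(W, 0.0)
            v = vectorize_edges(W)
            back = devectorize(v, d).matrix
            np.testing.assert_allclose(back, W, atol=1e-12)

    def test_ordering_is_row_major_upper_triangle(self):
        W = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
        np.testing.assert_allclose(vectorize_edges(W), [1.0, 2.0, 3.0])

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            vectorize_edges(np.array([[0.0, 1.0], [2.0, 0.0]]))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            devectorize(np.zeros(5), 4)
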