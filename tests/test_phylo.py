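"""Trees, Mantel tests, K_mult, covariates, PCA."""

import itertools

import numpy as np
import pandas as pd
import pytest

import mutspectra as ms


def random_distance(n, rng, labels=None):
    M = rng.random((n, n))
    D = (M + M.T) / 2
    np.fill_diagonal(D, 0)
    labels = labels or [f"s{i}" for i in range(n)]
    return ms.PhyloDistances(labels, D)


class TestCophenetic:
    def test_two_leaf_distance(self):
        D = ms.cophenetic_matrix("(A:1,B:2);")
        assert D.values[0, 1] == pytest.approx(3.0)

    def test_four_leaf_matches_path_oracle(self):
        nwk = "((A:1,B:2):3,(C:4,D:5):6);"
        D = ms.cophenetic_matrix(nwk)
        # brute-force path lengths through the single internal split
        expect = {("A", "B"): 3, ("A", "C"): 14, ("A", "D"): 15,
                  ("B", "C"): 15, ("B", "D"): 16, ("C", "D"): 9}
        for (a, b), d in expect.items():
            i, j = D.labels.index(a), D.labels.index(b)
            assert D.values[i, j] == pytest.approx(d)

    def test_ultrametric_root_to_leaf_equal(self):
        nwk = "((A:1,B:1):2,(C:2,D:2):1);"
        labels, C = ms.brownian_covariance(nwk)
        assert np.allclose(np.diag(C), 3.0)

    def test_sqrt_option(self):
        D = ms.cophenetic_matrix("(A:1,B:3);", sqrt=True)
        assert D.values[0, 1] == pytest.approx(2.0)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            ms.cophenetic_matrix("(A:1,B:-2);")


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        D = random_distance(6, rng)
        res = ms.mantel_test(D, D, n_perm=99, seed=1)
        assert res.r == pytest.approx(1.0)

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(1)
        D1, D2 = random_distance(4, rng), random_distance(4, rng)
        res = ms.mantel_exact(D1, D2)
        # oracle: recompute over all 24 permutations from first principles
        A, B = D1.values, D2.values
        iu = np.triu_indices(4, 1)
        r_obs = np.corrcoef(A[iu], B[iu])[0, 1]
        count = 0
        for perm in itertools.permutations(range(4)):
            Bp = B[np.ix_(perm, perm)]
            if np.corrcoef(A[iu], Bp[iu])[0, 1] >= r_obs - 1e-12:
                count += 1
        assert res.p == pytest.approx(count / 24)
        assert res.r == pytest.approx(r_obs)

    def test_sampled_p_converges_to_exact(self):
        rng = np.random.default_rng(2)
        D1, D2 = random_distance(5, rng), random_distance(5, rng)
        exact = ms.mantel_exact(D1, D2).p
        sampled = ms.mantel_test(D1, D2, n_perm=20000, seed=3).p
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_p_floor_estimator(self):
        res = ms.mantel_test(random_distance(5, np.random.default_rng(0)),
                             random_distance(5, np.random.default_rng(1)),
                             n_perm=9, seed=0)
        assert res.p >= res.p_floor == 0.1

    def test_constant_matrix_rejected(self):
        labels = list("abcd")
        ones = np.ones((4, 4)) - np.eye(4)
        D1 = ms.PhyloDistances(labels, ones)
        D2 = random_distance(4, np.random.default_rng(0), labels)
        with pytest.raises(ValueError, match="constant"):
            ms.mantel_test(D2, D1, n_perm=9, seed=0)

    def test_r_matches_skbio(self):
        from skbio.stats.distance import DistanceMatrix, mantel as sk_mantel
        rng = np.random.default_rng(4)
        D1, D2 = random_distance(7, rng), random_distance(7, rng)
        r_sk, _, _ = sk_mantel(DistanceMatrix(D1.values, D1.labels),
                               DistanceMatrix(D2.values, D2.labels),
                               permutations=0)
        res = ms.mantel_test(D1, D2, n_perm=9, seed=0)
        assert res.r == pytest.approx(float(r_sk), abs=1e-12)


class TestPartialMantel:
    def test_covariate_fully_explained_by_phylogeny(self):
        # covariate is (almost exactly) an affine function of phylogeny:
        # after regressing the phylogeny out, no association remains
        rng = np.random.default_rng(5)
        D_phy = random_distance(8, rng)
        noise = rng.normal(0, 1e-3, D_phy.values.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        D_cov = ms.PhyloDistances(D_phy.labels, 2.0 * D_phy.values
                                  + np.abs(noise))
        D_spec = random_distance(8, rng, D_phy.labels)
        res = ms.partial_mantel(D_spec, D_cov, D_phy, n_perm=199, seed=0)
        assert abs(res.r) < 0.5
        assert res.p > 0.05

    def test_spectrum_equals_covariate(self):
        rng = np.random.default_rng(6)
        D_phy = random_distance(8, rng)
        D_spec = random_distance(8, rng, D_phy.labels)
        res = ms.partial_mantel(D_spec, D_spec, D_phy, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_partial_correlation_formula(self):
        rng = np.random.default_rng(7)
        D_x = random_distance(6, rng)
        D_y = random_distance(6, rng, D_x.labels)
        D_z = random_distance(6, rng, D_x.labels)
        res = ms.partial_mantel(D_x, D_y, D_z, n_perm=9, seed=0)
        iu = np.triu_indices(6, 1)
        x, y, z = D_x.values[iu], D_y.values[iu], D_z.values[iu]
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        oracle = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        assert res.r == pytest.approx(oracle, abs=1e-10)


class TestKmult:
    def test_single_trait_reduces_to_univariate_blomberg(self, tree13):
        labels, C = ms.brownian_covariance(tree13)
        rng = np.random.default_rng(8)
        y = np.linalg.cholesky(C) @ rng.normal(size=len(labels))
        res = ms.k_mult(tree13, pd.DataFrame({"t": y}, index=labels), n_perm=0)
        # independent univariate implementation of Blomberg's K
        n = len(labels)
        Cinv = np.linalg.inv(C)
        ones = np.ones(n)
        a = (ones @ Cinv @ y) / (ones @ Cinv @ ones)
        e = y - a
        mse0 = (e @ e) / (n - 1)
        mse = (e @ Cinv @ e) / (n - 1)
        expected = (np.trace(C) - n / (ones @ Cinv @ ones)) / (n - 1)
        oracle = (mse0 / mse) / expected
        assert res.k_mult == pytest.approx(oracle, rel=1e-10)

    def test_tip_shuffle_calibration(self, tree13):
        # under exchangeable traits the permutation p rejects near alpha
        labels, C = ms.brownian_covariance(tree13)
        rng = np.random.default_rng(9)
        hits = 0
        reps = 150
        for i in range(reps):
            Y = rng.normal(size=(len(labels), 3))
            res = ms.k_mult(tree13, pd.DataFrame(Y, index=labels),
                            n_perm=99, seed=i)
            hits += res.p <= 0.05
        assert 0.005 < hits / reps < 0.12

    def test_signal_detected_under_brownian(self, tree13):
        labels, C = ms.brownian_covariance(tree13)
        rng = np.random.default_rng(10)
        Y = np.linalg.cholesky(C) @ rng.normal(size=(len(labels), 6))
        res = ms.k_mult(tree13, pd.DataFrame(Y, index=labels), n_perm=199,
                        seed=0)
        assert res.p < 0.05


class TestCovariatesAndPCA:
    def test_scalar_distance_examples(self):
        D = ms.scalar_distance_matrix({"a": 1.0, "b": 4.0, "c": 6.0})
        got = {frozenset((i, j)): D.values[D.labels.index(i),
                                           D.labels.index(j)]
               for i, j in itertools.combinations("abc", 2)}
        assert got == {frozenset("ab"): 3, frozenset("ac"): 5,
                       frozenset("bc"): 2}
        shifted = ms.scalar_distance_matrix({"a": 11.0, "b": 14.0, "c": 16.0})
        assert np.allclose(D.values, shifted.values)

    def test_watterson_examples(self):
        assert ms.watterson_theta(4, 0, 1000) == 0
        assert ms.watterson_theta(4, 5, 1000) == pytest.approx(0.0027273,
                                                               abs=1e-6)
        assert ms.watterson_theta(4, 10, 1000) == pytest.approx(
            2 * ms.watterson_theta(4, 5, 1000))
        with pytest.raises(ValueError):
            ms.watterson_theta(1, 5, 1000)

    def _clr_table(self, seed=0, n=8):
        rng = np.random.default_rng(seed)
        schema = ms.SpectrumSchema(1)
        data = pd.DataFrame(rng.integers(10, 300, (n, 6)).astype(float),
                            index=[f"s{i}" for i in range(n)],
                            columns=list(schema.labels))
        return ms.clr(ms.SpectrumTable(data, schema))

    def test_pca_identical_rows_zero_variance(self):
        schema = ms.SpectrumSchema(1)
        data = pd.DataFrame([[1, 2, 3, 4, 5, 6]] * 3,
                            index=list("abc"), columns=list(schema.labels),
                            dtype=float)
        res = ms.clr_pca(ms.clr(ms.SpectrumTable(data, schema)))
        assert np.allclose(res.scores.values, 0)

    def test_pca_preserves_distances_and_variance(self):
        t = self._clr_table()
        res = ms.clr_pca(t)
        from scipy.spatial.distance import pdist
        X = t.data.to_numpy()
        assert np.allclose(pdist(X - X.mean(axis=0)),
                           pdist(res.scores.values), atol=1e-9)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_pca_sign_convention_deterministic(self):
        t = self._clr_table(seed=3)
        a = ms.clr_pca(t)
        b = ms.clr_pca(t)
        assert np.allclose(a.scores.values, b.scores.values)
        top = np.abs(a.loadings.values).argmax(axis=0)
        assert (a.loadings.values[top, range(a.loadings.shape[1])] >= 0).all()

    def test_bonferroni(self):
        assert round(ms.bonferroni_threshold(0.05, 7), 3) == 0.007
        assert round(ms.bonferroni_threshold(0.05, 42), 3) == 0.001
        assert ms.bonferroni_threshold(0.03, 1) == 0.03
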