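"""Aging signatures, exposure EM, novel-signature extraction."""

import numpy as np
import pandas as pd
import pytest

import mutspectra as ms
from mutspectra import simulate as sim
from mutspectra.signatures import Signature, SignatureSet


@pytest.fixture()
def labels96():
    return list(ms.SpectrumSchema(3).labels)


def random_sigset(labels, n=2, seed=0, conc=1.0):
    rng = np.random.default_rng(seed)
    return SignatureSet([
        Signature(f"sig{i}", pd.Series(rng.dirichlet(np.full(len(labels),
                                                             conc)),
                                       index=labels))
        for i in range(n)])


class TestAgingSignatures:
    def aging_df(self, m_mat, b_mat, m_pat, b_pat):
        labels = list(ms.SpectrumSchema(1, "excluded").labels)
        return pd.DataFrame({"maternal_slope": m_mat,
                             "maternal_intercept": b_mat,
                             "paternal_slope": m_pat,
                             "paternal_intercept": b_pat}, index=labels)

    def test_equal_slopes_uniform(self):
        df = self.aging_df([1] * 6, [0] * 6, [1] * 6, [0] * 6)
        sigs = ms.build_aging_signatures(df)
        for s in sigs:
            assert np.allclose(s.probs, 1 / 6)

    def test_paternal_normalization_example(self):
        df = self.aging_df([1] * 6, [0] * 6, [2, 1, 1, 1, 1, 0], [0] * 6)
        sigs = ms.build_aging_signatures(df)
        assert np.allclose(sigs["paternal_age"].probs,
                           [1 / 3, 1 / 6, 1 / 6, 1 / 6, 1 / 6, 0])

    def test_young_parent_uses_puberty_age(self):
        # zero slopes: young-parent signature driven by intercepts only
        df = self.aging_df([0.1] * 6, [2, 1, 1, 1, 1, 0],
                           [0.1] * 6, [0] * 6)
        sigs = ms.build_aging_signatures(df, puberty_age=0.0)
        # at age 0 the expected loads are just the intercepts
        assert np.allclose(sigs["young_parent"].probs,
                           np.array([2, 1, 1, 1, 1, 0]) / 6)

    def test_negative_slope_rejected(self):
        df = self.aging_df([1, 1, 1, 1, 1, -2], [0] * 6, [1] * 6, [0] * 6)
        with pytest.raises(ValueError, match="negative"):
            ms.build_aging_signatures(df)

    def test_table_round_trip(self, tmp_path):
        df = self.aging_df([0.3, 0.2, 0.1, 0.25, 0.4, 0.15], [1.0] * 6,
                           [1.1, 0.8, 0.9, 1.0, 1.2, 0.7], [2.0] * 6)
        path = tmp_path / "aging.tsv"
        df.to_csv(path, sep="\t", index_label="class")
        back = ms.read_aging_table(path)
        pd.testing.assert_frame_equal(back.sort_index(), df.sort_index())


class TestSignatureIO:
    def test_cosmic_style_labels_are_collapsed(self, tmp_path, labels96):
        # pyrimidine-centered COSMIC labels: T-centered map to A-centered
        rows = ["A[C>A]A\t0.5", "A[T>C]G\t0.3", "TCA>TAA\t0.2"]
        path = tmp_path / "sig.tsv"
        path.write_text("type\ts1\n" + "\n".join(rows) + "\n")
        sigs = ms.read_signatures_tsv(path)
        s = sigs["s1"].probs
        assert s["ACA>AAA"] == pytest.approx(0.5)
        # A[T>C]G == CAT>CGT after strand collapse
        assert s["CAT>CGT"] == pytest.approx(0.3)
        assert s["TCA>TAA"] == pytest.approx(0.2)
        assert s.sum() == pytest.approx(1.0)


class TestExposureFit:
    def test_single_signature_recovered(self, labels96):
        sigs = random_sigset(labels96, n=2, seed=1)
        expo = pd.DataFrame([[1.0, 0.0]], index=["sp"],
                            columns=sigs.names)
        data = sim.simulate_signature_mixture(sigs, expo, 10 ** 6, seed=2)
        res = ms.SignatureModel(data, sigs).fit()
        assert res.exposures.loc["sp", "sig0"] == pytest.approx(1.0,
                                                                abs=1e-3)

    def test_mixture_recovered_within_001(self, labels96):
        sigs = random_sigset(labels96, n=2, seed=3)
        expo = pd.DataFrame([[0.3, 0.7]], index=["sp"], columns=sigs.names)
        data = sim.simulate_signature_mixture(sigs, expo, 10 ** 6, seed=4)
        res = ms.SignatureModel(data, sigs).fit()
        assert np.allclose(res.exposures.values, [[0.3, 0.7]], atol=0.01)

    def test_loglik_matches_direct_evaluation(self, labels96):
        sigs = random_sigset(labels96, n=3, seed=5)
        rng = np.random.default_rng(6)
        expo = pd.DataFrame(rng.dirichlet(np.ones(3), 2),
                            index=["a", "b"], columns=sigs.names)
        data = sim.simulate_signature_mixture(sigs, expo, 50_000, seed=7)
        res = ms.SignatureModel(data, sigs).fit()
        # oracle: evaluate the multinomial log-likelihood at the fitted point
        P = res.exposures.values @ sigs.matrix()
        oracle = float(np.sum(data.data.values * np.log(P)))
        assert res.llf == pytest.approx(oracle, rel=1e-10)

    def test_loglik_monotone(self, labels96):
        sigs = random_sigset(labels96, n=2, seed=8)
        rng = np.random.default_rng(9)
        expo = pd.DataFrame(rng.dirichlet(np.ones(2), 4),
                            index=list("abcd"), columns=sigs.names)
        data = sim.simulate_signature_mixture(sigs, expo, 20_000, seed=10)
        res = ms.SignatureModel(data, sigs).fit()
        assert np.all(np.diff(res.llf_history) >= -1e-8)

    def test_exposures_on_simplex(self, labels96):
        sigs = random_sigset(labels96, n=3, seed=11)
        rng = np.random.default_rng(12)
        expo = pd.DataFrame(rng.dirichlet(np.ones(3), 5),
                            index=[f"s{i}" for i in range(5)],
                            columns=sigs.names)
        data = sim.simulate_signature_mixture(sigs, expo, 30_000, seed=13)
        res = ms.SignatureModel(data, sigs).fit()
        assert (res.exposures.values >= 0).all()
        assert np.allclose(res.exposures.sum(axis=1), 1.0)


class TestNovelExtraction:
    def _planted(self, labels96, frac=0.3, n=10 ** 6):
        fixed = random_sigset(labels96, n=2, seed=20)
        rng = np.random.default_rng(21)
        hidden = Signature("hidden",
                           pd.Series(rng.dirichlet(np.full(96, 0.3)),
                                     index=labels96))
        all3 = SignatureSet(list(fixed) + [hidden])
        E = np.array([[0.5 - frac / 2, 0.5 - frac / 2, frac]
                      if i % 2 == 0 else [0.5, 0.5, 0.0] for i in range(13)])
        expo = pd.DataFrame(E, index=[f"s{i}" for i in range(13)],
                            columns=all3.names)
        data = sim.simulate_signature_mixture(all3, expo, n, seed=22)
        return fixed, hidden, data

    def test_null_novel_component_is_redundant(self, labels96):
        # data generated from the fixed signatures only: the extra component
        # cannot add real structure — it either keeps near-zero exposure or
        # degenerates onto a fixed signature (flagged by a warning), and the
        # likelihood gain over the fixed-only model is negligible per count
        fixed = random_sigset(labels96, n=2, seed=30)
        rng = np.random.default_rng(31)
        expo = pd.DataFrame(rng.dirichlet(np.ones(2), 6),
                            index=[f"s{i}" for i in range(6)],
                            columns=fixed.names)
        data = sim.simulate_signature_mixture(fixed, expo, 200_000, seed=32)
        base = ms.SignatureModel(data, fixed).fit()
        with pytest.warns(UserWarning, match="degenerated"):
            res = ms.SignatureModel(data, fixed).fit(extract_novel=True,
                                                     n_restarts=3, seed=33,
                                                     max_iter=2000)
        gain_per_count = (res.llf - base.llf) / data.data.values.sum()
        assert gain_per_count < 1e-3
        assert (res.novel_similarity.max() > 0.99
                or res.exposures["novel"].max() < 0.05)

    def test_planted_signature_recovered(self, labels96):
        fixed, hidden, data = self._planted(labels96)
        res = ms.SignatureModel(data, fixed).fit(extract_novel=True,
                                                 n_restarts=5, seed=40,
                                                 max_iter=3000)
        cos = ms.cosine_similarity(res.novel_signature.probs, hidden.probs)
        assert cos >= 0.95

    def test_novel_model_dominates_fixed_model(self, labels96):
        fixed, hidden, data = self._planted(labels96, n=100_000)
        base = ms.SignatureModel(data, fixed).fit()
        full = ms.SignatureModel(data, fixed).fit(extract_novel=True,
                                                  n_restarts=3, seed=41,
                                                  max_iter=2000)
        assert full.llf >= base.llf


class TestReconstruction:
    def test_perfect_reconstruction(self, labels96):
        sigs = random_sigset(labels96, n=1, seed=50)
        # counts exactly proportional to the signature
        counts = (sigs["sig0"].probs * 10 ** 7).round()
        schema = ms.SpectrumSchema(3)
        data = ms.SpectrumTable(counts.to_frame("sp").T, schema)
        res = ms.SignatureModel(data, sigs).fit()
        cos, resid = ms.reconstruction_metrics(res)
        assert cos["sp"] == pytest.approx(1.0, abs=1e-6)
        assert np.abs(resid.values).max() < 1e-4

    def test_residual_rows_sum_to_zero(self, labels96):
        sigs = random_sigset(labels96, n=2, seed=51)
        rng = np.random.default_rng(52)
        expo = pd.DataFrame(rng.dirichlet(np.ones(2), 3),
                            index=list("abc"), columns=sigs.names)
        data = sim.simulate_signature_mixture(sigs, expo, 40_000, seed=53)
        res = ms.SignatureModel(data, sigs).fit()
        assert np.abs(res.residuals().sum(axis=1)).max() < 1e-12

    def test_cosine_consistent_with_normalize_module(self, labels96):
        sigs = random_sigset(labels96, n=2, seed=54)
        rng = np.random.default_rng(55)
        expo = pd.DataFrame(rng.dirichlet(np.ones(2), 2),
                            index=list("ab"), columns=sigs.names)
        data = sim.simulate_signature_mixture(sigs, expo, 40_000, seed=56)
        res = ms.SignatureModel(data, sigs).fit()
        obs = res.observed_proportions()
        rec = res.reconstructed.data
        for sp in obs.index:
            assert res.cosine_similarities()[sp] == pytest.approx(
                ms.cosine_similarity(obs.loc[sp], rec.loc[sp]))

    def test_identical_reconstructions_yield_constant_matrix_error(
            self, labels96, sqrt_cophenetic, tree13):
        sigs = random_sigset(labels96, n=2, seed=57)
        leaves = sqrt_cophenetic.labels
        # identical counts in every species -> identical fitted exposures ->
        # reconstructed distance matrix is exactly constant (all zero)
        one = sim.simulate_signature_mixture(
            sigs, pd.DataFrame([[0.4, 0.6]], index=[leaves[0]],
                               columns=sigs.names), 10 ** 5, seed=58)
        data = ms.SpectrumTable(
            pd.DataFrame(np.tile(one.data.values, (len(leaves), 1)),
                         index=leaves, columns=one.data.columns),
            one.schema)
        res = ms.SignatureModel(data, sigs).fit()
        with pytest.raises(ValueError, match="constant"):
            res.reconstructed_signal_test(sqrt_cophenetic, n_perm=19, seed=0)

    def test_reconstructed_signal_test_composes_existing_ops(
            self, labels96, sqrt_cophenetic):
        fixed = random_sigset(labels96, n=2, seed=59)
        rng = np.random.default_rng(60)
        leaves = sqrt_cophenetic.labels
        expo = pd.DataFrame(rng.dirichlet(np.ones(2), len(leaves)),
                            index=leaves, columns=fixed.names)
        data = sim.simulate_signature_mixture(fixed, expo, 100_000, seed=61)
        res = ms.SignatureModel(data, fixed).fit()
        got = res.reconstructed_signal_test(sqrt_cophenetic, n_perm=99,
                                            seed=5)
        D = ms.aitchison_distance_matrix(res.reconstructed)
        ref = ms.mantel_test(D, sqrt_cophenetic, n_perm=99, seed=5)
        assert got.r == pytest.approx(ref.r)
        assert got.p == ref.p


class TestStripCpG:
    def test_seven_to_six_classes(self):
        schema = ms.SpectrumSchema(1, "separate")
        data = pd.DataFrame([[5, 4, 3, 2, 1, 6, 9]], index=["sp"],
                            columns=list(schema.labels))
        t = ms.SpectrumTable(data, schema)
        sigs = SignatureSet([Signature(
            "s", pd.Series(np.full(7, 1 / 7), index=list(schema.labels)))])
        t2, sigs2 = ms.strip_cpg(t, sigs)
        assert t2.data.shape[1] == 6
        assert ms.CPG_LABEL not in t2.data.columns
        assert sigs2["s"].probs.sum() == pytest.approx(1.0)

    def test_idempotent(self):
        schema = ms.SpectrumSchema(1, "separate")
        data = pd.DataFrame([[5, 4, 3, 2, 1, 6, 9]], index=["sp"],
                            columns=list(schema.labels))
        t = ms.SpectrumTable(data, schema)
        sigs = SignatureSet([Signature(
            "s", pd.Series(np.full(7, 1 / 7), index=list(schema.labels)))])
        t2, sigs2 = ms.strip_cpg(t, sigs)
        t3, sigs3 = ms.strip_cpg(t2, sigs2)
        pd.testing.assert_frame_equal(t2.data, t3.data)

    def test_3mer_spectrum_loses_cpg_types(self, labels96):
        schema = ms.SpectrumSchema(3)
        data = pd.DataFrame([np.arange(96)], index=["sp"], columns=labels96)
        t = ms.SpectrumTable(data, schema)
        sigs = random_sigset(labels96, n=1, seed=70)
        t2, sigs2 = ms.strip_cpg(t, sigs)
        assert t2.data.shape[1] == 92
        assert sigs2["sig0"].probs.sum() == pytest.approx(1.0)
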