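"""Kinship, PCA, exact mixed-model scan, and the Bonferroni transform."""

import numpy as np
import pandas as pd
import pytest

from plastiqtl import association as assoc
from plastiqtl import synthetic_data as sd
from plastiqtl.exceptions import DataError, ParameterError


class TestKinship:
    def test_matches_double_loop_oracle(self, toy_geno_factory):
        G = toy_geno_factory([[0, 1, 2], [2, 1, 0], [1, 0, 2], [0, 2, 1]])
        K = assoc.compute_kinship(G).K
        d = G.dosage.astype(float)
        W = d - d.mean(axis=0)
        oracle = np.zeros((4, 4))
        for i in range(4):
            for j in range(4):
                for k in range(3):
                    oracle[i, j] += W[i, k] * W[j, k] / 3
        np.testing.assert_allclose(K, oracle, atol=1e-12)

    def test_duplicate_samples_share_entries(self, toy_geno_factory):
        G = toy_geno_factory([[0, 2, 1], [0, 2, 1], [2, 0, 1]])
        K = assoc.compute_kinship(G).K
        assert K[0, 1] == pytest.approx(K[0, 0], abs=1e-12)
        assert K[0, 1] == pytest.approx(K[1, 1], abs=1e-12)

    def test_row_sums_zero(self, small_parents):
        K = assoc.compute_kinship(small_parents).K
        np.testing.assert_allclose(K.sum(axis=1), 0.0, atol=1e-9)

    def test_monomorphic_panel_rejected(self, toy_geno_factory):
        G = toy_geno_factory([[2, 2], [2, 2], [2, 2]])
        with pytest.raises(DataError):
            assoc.compute_kinship(G)


class TestPCA:
    def test_two_subpopulations_separate_on_pc1(self, toy_geno_factory):
        rng = np.random.default_rng(0)
        m = 150
        p1 = rng.uniform(0.1, 0.3, m)
        p2 = rng.uniform(0.6, 0.9, m)
        d = np.vstack([
            np.where(rng.random((15, m)) < p1, 2, 0),
            np.where(rng.random((15, m)) < p2, 2, 0)]).astype(np.int8)
        G = toy_geno_factory(d)
        pc1 = assoc.compute_pcs(G, 2).coords["PC1"]
        a, b = pc1[:15], pc1[15:]
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_duplicate_samples_identical_coords(self, toy_geno_factory):
        G = toy_geno_factory([[0, 2, 1, 0], [0, 2, 1, 0], [2, 0, 0, 2],
                              [1, 1, 2, 0]])
        coords = assoc.compute_pcs(G, 2).coords
        np.testing.assert_allclose(coords.iloc[0], coords.iloc[1], atol=1e-10)

    def test_components_orthonormal(self, small_parents):
        comp = assoc.compute_pcs(small_parents, 3).components
        np.testing.assert_allclose(comp @ comp.T, np.eye(3), atol=1e-10)

    def test_sign_convention_deterministic(self, small_parents):
        a = assoc.compute_pcs(small_parents, 3)
        for row in a.components:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_many_pcs_rejected(self, toy_geno_factory):
        G = toy_geno_factory([[0, 2], [2, 0], [1, 1]])
        with pytest.raises(ParameterError):
            assoc.compute_pcs(G, 3)


class TestBonferroni:
    def test_genome_wide_threshold_scale(self):
        thr, neglog = assoc.bonferroni_threshold(939_850)
        assert thr == pytest.approx(5.32e-8, rel=1e-3)
        assert round(neglog, 2) == 7.27

    def test_single_test(self):
        thr, _ = assoc.bonferroni_threshold(1)
        assert thr == 0.05

    def test_zero_tests_rejected(self):
        with pytest.raises(ParameterError):
            assoc.bonferroni_threshold(0)


def _dense_grid_oracle(y, X, K, step=1e-4, lo=-5.0, hi=5.0):
    """Independent exact-MLM reference: dense log10-grid REML, then Wald."""
    from scipy import stats
    s, U = np.linalg.eigh(K)
    s = np.clip(s, 0, None)
    yt = U.T @ y
    Xt = U.T @ X
    n, c = X.shape
    nc = n - c
    grid = np.arange(lo, hi + step / 2, step)
    lam = s[None, :] + 10.0 ** grid[:, None]
    w = 1.0 / lam
    A = np.einsum("gi,ic,id->gcd", w, Xt, Xt)
    bv = np.einsum("gi,ic,i->gc", w, Xt, yt)
    beta = np.linalg.solve(A, bv[..., None])[..., 0]
    resid = yt[None, :] - beta @ Xt.T
    rss = np.einsum("gi,gi->g", w * resid, resid)
    _, logdetA = np.linalg.slogdet(A)
    ll = 0.5 * (nc * (np.log(nc) - np.log(2 * np.pi)) - nc
                - nc * np.log(rss) - np.log(lam).sum(axis=1) - logdetA)
    g = int(np.argmax(ll))
    Ainv = np.linalg.inv(A[g])
    sg2 = rss[g] / nc
    se = np.sqrt(sg2 * Ainv[-1, -1])
    t = beta[g, -1] / se
    p = 2 * stats.t.sf(abs(t), nc)
    return -np.log10(p)


class TestMLM:
    def test_identity_kinship_equals_ols(self, small_parents):
        import statsmodels.api as sm
        n = small_parents.n_samples
        rng = np.random.default_rng(1)
        y = pd.Series(rng.normal(0, 1, n), index=small_parents.sample_ids)
        K = assoc.KinshipMatrix(sample_ids=list(small_parents.sample_ids),
                                K=np.eye(n))
        res = assoc.mlm_gwas(y, small_parents, K, n_pc=3)
        pcs = assoc.compute_pcs(small_parents, 3).coords.to_numpy()
        X0 = np.column_stack([np.ones(n), pcs])
        for j in range(small_parents.n_snps):
            x = small_parents.dosage[:, j].astype(float)
            if np.all(x == x[0]):
                continue
            ols = sm.OLS(y.to_numpy(), np.column_stack([X0, x])).fit()
            assert res.p_wald[j] == pytest.approx(ols.pvalues[-1], abs=1e-8)

    def test_matches_dense_grid_oracle(self):
        G = sd.simulate_parents(50, 20, seed=5)
        K = assoc.compute_kinship(G)
        rng = np.random.default_rng(6)
        L = np.linalg.cholesky(K.K + 1e-6 * np.eye(50))
        y = pd.Series(L @ rng.normal(0, 1, 50)
                      + 0.5 * G.dosage[:, 3]
                      + rng.normal(0, 1, 50), index=G.sample_ids)
        res = assoc.mlm_gwas(y, G, K, n_pc=3)
        pcs = assoc.compute_pcs(G, 3).coords.to_numpy()
        X0 = np.column_stack([np.ones(50), pcs])
        for j in range(G.n_snps):
            x = G.dosage[:, j].astype(float)
            expect = _dense_grid_oracle(y.to_numpy(),
                                        np.column_stack([X0, x]), K.K)
            assert abs(res.neglog10p[j] - expect) < 0.01

    def test_affine_phenotype_invariance(self, small_parents):
        rng = np.random.default_rng(7)
        n = small_parents.n_samples
        y = pd.Series(rng.normal(0, 1, n), index=small_parents.sample_ids)
        K = assoc.compute_kinship(small_parents)
        r0 = assoc.mlm_gwas(y, small_parents, K, n_pc=2)
        r1 = assoc.mlm_gwas(3.0 * y + 10.0, small_parents, K, n_pc=2)
        np.testing.assert_allclose(r1.p_wald, r0.p_wald, atol=1e-8)
        np.testing.assert_allclose(r1.beta, 3.0 * r0.beta, rtol=1e-6)

    def test_large_effect_snp_is_study_minimum(self, full_hybrids):
        """A causal SNP explaining >= 25% of variance tops the scan."""
        causal_full = sd.pick_unlinked_loci(full_hybrids, ("Chr03",))[0]
        keep = sorted(set(range(0, full_hybrids.n_snps, 3)) | {causal_full})
        G = full_hybrids.take_snps(np.array(keep))
        causal = keep.index(causal_full)
        K = assoc.compute_kinship(G)
        x = G.dosage[:, causal].astype(float)
        beta = np.sqrt(0.25 / 0.75) / x.std()
        wins = 0
        n_rep = 100
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            y = pd.Series(beta * x + rng.normal(0, 1, len(x)),
                          index=G.sample_ids)
            res = assoc.mlm_gwas(y, G, K, n_pc=3)
            if int(res["p_wald"].idxmin()) == causal:
                wins += 1
        assert wins >= 0.95 * n_rep

    def test_scan_of_true_plasticity_ranks_causal_snps_on_top(
            self, full_hybrids, full_design):
        """Scanning the generative b values puts the programmed plasticity
        loci in the top percentile of the scan."""
        loci = sd.pick_unlinked_loci(full_hybrids, ("Chr02", "Chr07"))
        params = sd.PhenotypeParams(
            trait_names=("AC",), causal_plast_snps=tuple(loci),
            causal_plast_effects=(1.2, -1.2), sigma_b_noise=0.15, gca_sd=0.05)
        _, truth = sd.simulate_phenotypes(full_hybrids, full_design,
                                          {"HN-CS": 5}, params, seed=31)
        K = assoc.compute_kinship(full_hybrids)
        res = assoc.mlm_gwas(truth.b["AC"], full_hybrids, K, n_pc=3)
        order = res["neglog10p"].rank(ascending=False)
        top = max(1, int(np.ceil(0.01 * res["neglog10p"].notna().sum())))
        assert np.median([order[j] for j in loci]) <= top

    def test_null_ratio_approximation_tracks_exact_scan(self, small_parents):
        """EMMAX-style single-ratio approximation stays close to the exact
        per-SNP optimisation under a polygenic phenotype."""
        K = assoc.compute_kinship(small_parents)
        rng = np.random.default_rng(12)
        n = small_parents.n_samples
        L = np.linalg.cholesky(K.K + 1e-6 * np.eye(n))
        y = pd.Series(L @ rng.normal(0, 1, n) + rng.normal(0, 1, n),
                      index=small_parents.sample_ids)
        exact = assoc.mlm_gwas(y, small_parents, K, n_pc=2)
        fast = assoc.mlm_gwas(y, small_parents, K, n_pc=2,
                              approx_null_ratio=True)
        d = (exact["neglog10p"] - fast["neglog10p"]).abs().dropna()
        assert d.median() < 0.1

    def test_monomorphic_snp_sentinel(self, toy_geno_factory):
        d = np.array([[0, 2, 0], [2, 2, 1], [0, 2, 2], [2, 2, 1],
                      [1, 2, 0], [0, 2, 2], [2, 2, 1], [0, 2, 0]])
        G = toy_geno_factory(d)
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(0, 1, 8), index=G.sample_ids)
        K = assoc.KinshipMatrix(sample_ids=list(G.sample_ids), K=np.eye(8))
        res = assoc.mlm_gwas(y, G, K, n_pc=0)
        assert np.isnan(res.p_wald[1])
        assert np.isfinite(res.p_wald[0])

    def test_missing_dosage_drops_samples_per_snp(self, toy_geno_factory):
        d = np.array([[0, -1], [2, 0], [0, 2], [2, 0], [1, 2], [0, 0],
                      [2, 2], [0, 0], [1, 2], [2, 0]])
        G = toy_geno_factory(d)
        rng = np.random.default_rng(9)
        y = pd.Series(rng.normal(0, 1, 10), index=G.sample_ids)
        K = assoc.KinshipMatrix(sample_ids=list(G.sample_ids), K=np.eye(10))
        res = assoc.mlm_gwas(y, G, K, n_pc=0)
        import statsmodels.api as sm
        keep = d[:, 1] != -1
        ols = sm.OLS(y.to_numpy()[keep],
                     np.column_stack([np.ones(keep.sum()),
                                      d[keep, 1].astype(float)])).fit()
        assert res.p_wald[1] == pytest.approx(ols.pvalues[-1], abs=1e-8)
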