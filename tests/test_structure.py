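"""PCA, admixture EM, cluster discovery, DAPC, loading profiles."""

import numpy as np
import pytest

import radstruct as rs
from conftest import make_gm, random_gm


class TestPCA:
    def test_duplicated_samples_identical_scores(self, rng):
        g = rng.integers(0, 3, size=80).astype(np.int8)
        other = rng.integers(0, 3, size=(4, 80)).astype(np.int8)
        gm = make_gm(np.vstack([g, g, other]), pos=np.arange(1, 81) * 100)
        res = rs.pca_genotypes(gm, 3)
        assert np.allclose(res.scores[0], res.scores[1], atol=1e-10)

    def test_eigenvalue_sum_is_total_variance(self, rng):
        gm = random_gm(rng, n=25, L=60, missing=0.1)
        res = rs.pca_genotypes(gm, n_axes=24)
        G = gm.G.astype(float)
        G[gm.G == rs.MISSING] = np.nan
        X = G - np.nanmean(G, axis=0)
        X[np.isnan(X)] = 0.0
        total = (X**2).sum() / (gm.n_samples - 1)
        assert res.eigenvalues.sum() == pytest.approx(total, abs=1e-8)

    def test_matches_dense_eigendecomposition(self, rng):
        gm = random_gm(rng, n=30, L=300, missing=0.05)
        res = rs.pca_genotypes(gm, n_axes=5)
        G = gm.G.astype(float)
        G[gm.G == rs.MISSING] = np.nan
        X = G - np.nanmean(G, axis=0)
        X[np.isnan(X)] = 0.0
        C = X @ X.T / (gm.n_samples - 1)
        w, v = np.linalg.eigh(C)
        w, v = w[::-1][:5], v[:, ::-1][:, :5]
        assert np.allclose(res.eigenvalues, w, atol=1e-8)
        ref_scores = v * np.sqrt(w * (gm.n_samples - 1))
        for k in range(5):
            diff = min(
                np.abs(res.scores[:, k] - ref_scores[:, k]).max(),
                np.abs(res.scores[:, k] + ref_scores[:, k]).max(),
            )
            assert diff < 1e-8

    def test_unit_norm_loadings_and_order(self, rng):
        res = rs.pca_genotypes(random_gm(rng, n=20, L=100), n_axes=6)
        assert np.allclose(np.linalg.norm(res.loadings, axis=0), 1.0, atol=1e-10)
        assert (np.diff(res.eigenvalues) <= 1e-10).all()

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError):
            rs.pca_genotypes(make_gm(np.ones((5, 10))), 2)


class TestAdmixtureEM:
    def test_k1_closed_form(self, rng):
        gm = random_gm(rng, n=15, L=80, missing=0.1)
        res = rs.admixture_em(gm, K=1)
        assert np.all(res.Q == 1.0)
        stats = rs.site_allele_stats(gm)
        assert np.allclose(res.F[0], stats["p_alt"].to_numpy(), atol=1e-12)

    def test_loglik_monotone_and_simplex(self, rng):
        gm = random_gm(rng, n=25, L=150, missing=0.05)
        res = rs.admixture_em(gm, K=2, seed=1, n_restarts=2, max_iter=100)
        assert (np.diff(res.loglik_path) >= -1e-6).all()
        assert np.allclose(res.Q.sum(axis=1), 1.0, atol=1e-8)
        assert ((res.F >= 0) & (res.F <= 1)).all()

    def test_f1_minor_ancestry_half(self):
        cfg = rs.SimConfig(
            seed=9, n_loci=600, pop_sizes={"p1": 25}, n_pure_A=25,
            hybrid_spec=[rs.HybridSpec("F1", 6)], diagnostic_fraction=0.6,
        )
        gm, table, truth = rs.simulate_dataset(cfg)
        res = rs.admixture_em(gm, K=2, seed=0)
        minor = np.minimum(res.Q[:, 0], res.Q[:, 1])
        is_f1 = np.array(
            [truth["samples"][s]["species_class"] == "admixed" for s in gm.samples]
        )
        assert np.allclose(minor[is_f1], 0.5, atol=0.03)
        assert (minor[~is_f1] < 0.01).all()  # pure individuals >= 0.99 majority


class TestAdmixtureCV:
    def test_single_population_prefers_k1(self, rng):
        cfg = rs.SimConfig(seed=21, n_loci=300, pop_sizes={"p1": 40})
        gm, _, _ = rs.simulate_dataset(cfg)
        cv = rs.admixture_cv_error(gm, [1, 2], folds=3, seed=0,
                                   n_restarts=2, max_iter=150)
        assert cv[1] <= cv[2]

    def test_two_species_prefers_k2_and_deterministic(self):
        cfg = rs.SimConfig(seed=22, n_loci=300, pop_sizes={"p1": 20}, n_pure_A=20)
        gm, _, _ = rs.simulate_dataset(cfg)
        kwargs = dict(folds=3, seed=5, n_restarts=2, max_iter=150)
        cv = rs.admixture_cv_error(gm, [1, 2, 3], **kwargs)
        assert min(cv, key=cv.get) == 2
        cv2 = rs.admixture_cv_error(gm, [1, 2, 3], **kwargs)
        assert cv == cv2

    def test_k_above_n_rejected(self, rng):
        gm = random_gm(rng, n=5, L=60)
        with pytest.raises(ValueError):
            rs.admixture_cv_error(gm, [6])


class TestFindClusters:
    def test_three_separated_blobs(self, rng):
        centers = np.array([[0, 0], [30, 0], [0, 30]])
        X = np.vstack([rng.normal(c, 1.0, size=(20, 2)) for c in centers])
        best, labels, bic = rs.find_clusters(X, k_max=5, seed=0)
        assert best == 3
        assert len(np.unique(labels)) == 3

    def test_single_blob_prefers_k1(self, rng):
        X = rng.normal(0, 1, size=(40, 3))
        best, _, bic = rs.find_clusters(X, k_max=4, seed=0)
        assert best == 1

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(0, 1, size=(30, 4))
        r1 = rs.find_clusters(X, k_max=4, seed=7)
        r2 = rs.find_clusters(X, k_max=4, seed=7)
        assert r1[0] == r2[0] and np.array_equal(r1[1], r2[1])

    def test_k_max_validation(self, rng):
        with pytest.raises(ValueError):
            rs.find_clusters(rng.normal(size=(5, 2)), k_max=5)


class TestDAPC:
    def test_duplicated_clusters_perfectly_reassigned(self, rng):
        a = rng.integers(0, 3, size=100).astype(np.int8)
        b = rng.integers(0, 3, size=100).astype(np.int8)
        G = np.vstack([a, a, a, b, b, b])
        gm = make_gm(G, pos=np.arange(1, 101) * 50)
        res = rs.dapc(gm, np.array([0, 0, 0, 1, 1, 1]))
        assert res.reassignment_accuracy == 1.0

    def test_scores_invariant_to_locus_permutation(self, rng):
        gm = random_gm(rng, n=20, L=80, missing=0.0)
        y = np.repeat([0, 1], 10)
        res1 = rs.dapc(gm, y)
        perm = rng.permutation(80)
        order = np.lexsort((gm.loci["pos"].to_numpy()[perm],
                            gm.loci["chrom"].to_numpy()[perm]))
        idx = perm[order]
        gm2 = rs.GenotypeMatrix(
            samples=gm.samples,
            loci=gm.loci.iloc[idx].reset_index(drop=True),
            G=gm.G[:, idx].copy(),
        )
        res2 = rs.dapc(gm2, y)
        assert np.allclose(np.abs(res1.scores), np.abs(res2.scores), atol=1e-8)

    def test_deme_recovery_on_simulation(self):
        cfg = rs.SimConfig(seed=30, n_loci=1000,
                           pop_sizes={"a": 30, "b": 30, "c": 30}, fst=0.05)
        gm, table, _ = rs.simulate_dataset(cfg)
        pca = rs.pca_genotypes(gm, 10)
        _, labels, _ = rs.find_clusters(pca.scores, k_max=4, seed=0)
        res = rs.dapc(gm, labels)
        # majority ecoregion within each DAPC cluster agrees >= 90%
        eco = table["ecoregion"].reindex(gm.samples).to_numpy()
        agree = 0
        for c in np.unique(res.assignments):
            sub = eco[res.assignments == c]
            vals, counts = np.unique(sub, return_counts=True)
            agree += counts.max()
        assert agree / len(eco) >= 0.90


class TestLoadingProfile:
    def test_unit_mass_on_single_locus(self):
        gm = make_gm(np.zeros((2, 5)), pos=[1, 2, 3, 4, 5_000_001])
        load = np.array([0, 0, 0, 0, 1.0])
        prof = rs.loading_profile(load, gm.loci, window_bp=1e6)
        sums = rs.window_sums(prof)
        top = sums.loc[sums["stat"].idxmax()]
        assert top["stat"] == 1.0 and top["window"] == 5

    def test_window_sums_total_one_per_axis(self, rng):
        gm = random_gm(rng, n=10, L=200)
        res = rs.pca_genotypes(gm, 3)
        for ax in range(3):
            prof = rs.loading_profile(res.loadings[:, ax], gm.loci)
            assert rs.window_sums(prof)["stat"].sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_naive_window_loop(self, rng):
        gm = random_gm(rng, n=5, L=150, n_chrom=2)
        load = rng.normal(size=150)
        prof = rs.loading_profile(load, gm.loci, window_bp=1e6)
        sums = rs.window_sums(prof)
        for _, row in sums.sample(10, random_state=1).iterrows():
            mask = (
                (gm.loci["chrom"] == row["chrom"])
                & ((gm.loci["pos"] - 1) // 10**6 == row["window"])
            ).to_numpy()
            assert row["stat"] == pytest.approx((load[mask] ** 2).sum(), abs=1e-12)
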