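"""GRM/PCA, AMOVA, Weir-Cockerham FST and the admixture model."""

import numpy as np
import pytest

from capripop.structure import (
    admixture_cv,
    admixture_em,
    amova,
    fst_weir_cockerham,
    grm,
    pca,
)
from capripop.simulate import simulate_admixed, simulate_structured

from conftest import make_dataset


class TestGRM:
    def test_duplicate_samples_near_one(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.1, 0.5, size=5000)
        row = rng.binomial(2, p)
        others = rng.binomial(2, p, size=(20, 5000))
        ds = make_dataset(np.vstack([row, row, others]).astype(np.int8))
        G = grm(ds, freqs=p)  # generative frequencies: duplicates share ~1
        assert G[0, 1] == pytest.approx(1.0, abs=0.05)

    def test_random_mating_diagonal_one_offdiag_zero(self):
        ds, _ = simulate_structured(1, 0.5, 60, 4000, seed=2)
        G = grm(ds)
        off = G[~np.eye(len(G), dtype=bool)]
        assert abs(off.mean()) < 0.05
        assert np.diag(G).mean() == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_snps_excluded_with_warning(self):
        g = np.array([[0, 1], [0, 1], [0, 0], [0, 2]], dtype=np.int8)
        ds = make_dataset(g)
        with pytest.warns(UserWarning, match="monomorphic"):
            G = grm(ds)
        assert G.shape == (4, 4)


class TestPCA:
    def test_identity_matrix_equal_fractions(self):
        res = pca(np.eye(5), k=3)
        assert np.allclose(res.variance_fractions, 1 / 3)

    def test_rank_one_matrix(self):
        v = np.array([3.0, -1.0, 2.0, 0.5])
        res = pca(np.outer(v, v), k=2)
        direction = res.eigenvectors[:, 0]
        assert res.variance_fractions[0] == pytest.approx(1.0, abs=1e-9)
        cos = abs(direction @ v / np.linalg.norm(v))
        assert cos == pytest.approx(1.0, abs=1e-9)

    def test_k_exceeding_dimension_rejected(self):
        with pytest.raises(ValueError):
            pca(np.eye(3), k=4)

    def test_grm_pca_agrees_with_genotype_svd(self):
        ds, _ = simulate_structured(3, 0.12, 15, 400, seed=3)
        G = grm(ds)
        res = pca(G, k=3)
        p = ds.allele_freq_b()
        ok = (p > 0) & (p < 1)
        Z = (ds.genotypes[:, ok] - 2 * p[ok]) / np.sqrt(2 * p[ok] * (1 - p[ok]))
        U, s, _ = np.linalg.svd(Z - 0 * Z, full_matrices=False)
        # principal angles between top-3 subspaces
        M = res.eigenvectors.T @ U[:, :3]
        angles = np.arccos(np.clip(np.linalg.svd(M, compute_uv=False), -1, 1))
        assert np.max(np.abs(angles)) < 1e-6

    def test_separates_simulated_populations(self):
        from sklearn.linear_model import LogisticRegression
        ds, _ = simulate_structured(3, 0.12, 30, 2000, seed=4)
        res = pca(grm(ds), k=3)
        X = res.eigenvectors[:, :2]
        y = np.array(ds.populations)
        clf = LogisticRegression(max_iter=5000).fit(X, y)
        assert clf.score(X, y) == 1.0  # complete linear separability


class TestAMOVA:
    def test_percentages_sum_to_100(self, structured_dataset):
        ds, _ = structured_dataset
        res = amova(ds, n_permutations=20, seed=0)
        assert sum(res.percentages) == pytest.approx(100.0, abs=1e-6)
        assert res.fst == pytest.approx(res.percentages[0] / 100.0, abs=1e-12)

    def test_fixed_difference_gives_fst_one(self):
        g = np.zeros((8, 10), dtype=np.int8)
        g[4:, :] = 2
        ds = make_dataset(g, populations=["A"] * 4 + ["B"] * 4)
        res = amova(ds, n_permutations=30, seed=0)
        assert res.percentages[0] == pytest.approx(100.0, abs=1e-9)
        assert res.fst == pytest.approx(1.0, abs=1e-9)

    def test_null_labels_give_small_among_component(self):
        ds, _ = simulate_structured(1, 0.5, 45, 400, seed=5)
        labels = ["A"] * 15 + ["B"] * 15 + ["C"] * 15
        res = amova(ds, labels=labels, n_permutations=99, seed=1)
        assert abs(res.percentages[0]) < 2.0
        assert res.p_value > 0.05

    def test_population_of_one_rejected(self):
        ds, _ = simulate_structured(2, 0.1, 5, 50, seed=6)
        labels = ds.populations
        labels[0] = "LONER"
        with pytest.raises(ValueError):
            amova(ds, labels=labels, n_permutations=10)

    def test_balding_nichols_recovery(self):
        ds, truth = simulate_structured(3, 0.12, 30, 3000, seed=7)
        res = amova(ds, n_permutations=20, seed=0)
        assert res.fst == pytest.approx(0.12, abs=0.02)
        assert res.p_value <= 0.1


class TestWeirCockerham:
    def test_no_differentiation_near_zero(self):
        ds, _ = simulate_structured(1, 0.5, 60, 1000, seed=8)
        labels = ["A"] * 30 + ["B"] * 30
        _, global_fst = fst_weir_cockerham(ds, labels=labels)
        assert abs(global_fst) < 0.01

    def test_fixed_difference_per_snp_one(self):
        g = np.zeros((8, 3), dtype=np.int8)
        g[4:, :] = 2
        ds = make_dataset(g, populations=["A"] * 4 + ["B"] * 4)
        per_snp, global_fst = fst_weir_cockerham(ds)
        assert np.allclose(per_snp.fst.dropna(), 1.0)
        assert global_fst == pytest.approx(1.0)

    def test_balding_nichols_recovery(self):
        ds, _ = simulate_structured(3, 0.12, 30, 3000, seed=9)
        _, global_fst = fst_weir_cockerham(ds)
        assert global_fst == pytest.approx(0.12, abs=0.02)


class TestAdmixture:
    def test_k1_closed_form(self):
        ds, _ = simulate_structured(1, 0.5, 20, 100, seed=10)
        fit = admixture_em(ds, K=1)
        assert np.allclose(fit.Q, 1.0)
        assert np.allclose(fit.P[0], ds.allele_freq_b(), atol=1e-6)

    def test_q_rows_sum_to_one_and_bounds(self):
        ds, _ = simulate_structured(2, 0.2, 15, 200, seed=11)
        fit = admixture_em(ds, K=2, seed=0, n_restarts=2, max_iter=200)
        assert np.allclose(fit.Q.sum(axis=1), 1.0)
        assert (fit.Q >= 0).all() and (fit.P >= 0).all() and (fit.P <= 1).all()

    def test_unadmixed_recovery_at_high_fst(self):
        ds, _ = simulate_structured(2, 0.3, 30, 600, seed=12)
        fit = admixture_em(ds, K=2, seed=0, n_restarts=3)
        lab = np.array(ds.populations)
        m1 = fit.Q[lab == "pop1"].mean(axis=0)
        own = int(np.argmax(m1))
        assert fit.Q[lab == "pop1", own].mean() > 0.95
        assert fit.Q[lab == "pop2", 1 - own].mean() > 0.95

    def test_half_admixed_recovery(self):
        Q_true = np.vstack([np.tile([1.0, 0.0], (25, 1)),
                            np.tile([0.0, 1.0], (25, 1)),
                            np.tile([0.5, 0.5], (20, 1))])
        ds, _ = simulate_admixed(Q_true, 0.3, 1000, seed=13)
        fit = admixture_em(ds, K=2, seed=0, n_restarts=3)
        mixed = fit.Q[50:]
        assert np.allclose(mixed.mean(axis=0), 0.5, atol=0.05)

    def test_cv_deterministic_under_seed(self):
        ds, _ = simulate_structured(2, 0.2, 12, 150, seed=14)
        cv1 = admixture_cv(ds, [1, 2], seed=99, max_iter=100)
        cv2 = admixture_cv(ds, [1, 2], seed=99, max_iter=100)
        assert cv1 == cv2

    def test_panmictic_prefers_k1(self):
        ds, _ = simulate_structured(1, 0.5, 40, 400, seed=15)
        cv = admixture_cv(ds, [1, 2, 3], seed=0)
        assert min(cv, key=cv.get) == 1
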