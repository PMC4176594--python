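import numpy as np
import pytest

from soyblup import simulate_genotypes
from soyblup.kernels import (
    KernelMatrix,
    StandardizedMarkers,
    additive_kernel,
    hadamard_epistasis,
    standardize,
    xu_epistasis,
)
from conftest import make_matrix


class TestStandardize:
    def test_two_line_hand_algebra(self):
        std = standardize(make_matrix([[2], [0]]))
        np.testing.assert_allclose(std.W[:, 0], [np.sqrt(2), -np.sqrt(2)])
        assert std.theta[0] == pytest.approx(0.5)

    def test_supplied_theta_gives_zero_column_for_constant(self):
        std = standardize(make_matrix([[1], [1], [1]]), theta=np.array([0.5]))
        np.testing.assert_allclose(std.W[:, 0], 0.0)

    def test_internally_estimated_theta_centers_columns(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.integers(0, 3, (12, 8)).astype(float) / 1.0 + 0.0)
        # ensure polymorphic
        m.dosage[0] = 1.0
        std = standardize(m)
        np.testing.assert_allclose(std.W.mean(axis=0), 0.0, atol=1e-12)

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="MAF"):
            standardize(make_matrix([[2], [2], [2]]))

    def test_missing_rejected(self):
        with pytest.raises(ValueError, match="impute"):
            standardize(make_matrix([[2], [np.nan]]))


class TestAdditiveKernel:
    def test_two_line_single_marker(self):
        G = additive_kernel(standardize(make_matrix([[2], [0]])))
        np.testing.assert_allclose(G.K, [[2, -2], [-2, 2]])

    def test_duplicate_lines_exchangeable(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, (5, 30)).astype(float)
        d[3] = d[1]
        G = additive_kernel(standardize(make_matrix(d)))
        np.testing.assert_allclose(G.K[1], G.K[3])
        np.testing.assert_allclose(G.K[:, 1], G.K[:, 3])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, (6, 20)).astype(float)
        std = standardize(make_matrix(d))
        G = additive_kernel(std)
        W, p = std.W, std.n_markers
        oracle = np.empty((6, 6))
        for i in range(6):
            for k in range(6):
                oracle[i, k] = sum(W[i, j] * W[k, j] for j in range(p)) / p
        np.testing.assert_allclose(G.K, oracle, atol=1e-10)

    def test_marker_order_invariance(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, (8, 25)).astype(float)
        perm = rng.permutation(25)
        G1 = additive_kernel(standardize(make_matrix(d)))
        G2 = additive_kernel(standardize(make_matrix(d[:, perm])))
        np.testing.assert_allclose(G1.K, G2.K, atol=1e-12)

    def test_column_scaling_rescales_kernel(self):
        rng = np.random.default_rng(4)
        W = rng.standard_normal((6, 10))
        std = StandardizedMarkers(W=W, theta=np.full(10, 0.5), line_ids=[str(i) for i in range(6)])
        std_scaled = StandardizedMarkers(W=3.0 * W, theta=std.theta, line_ids=std.line_ids)
        np.testing.assert_allclose(additive_kernel(std_scaled).K,
                                   9.0 * additive_kernel(std).K, atol=1e-10)

    def test_inbred_diagonal_reflects_inbreeding(self, small_genome):
        matrix, _, _ = small_genome
        poly = matrix.dosage.std(axis=0) > 0
        G = additive_kernel(standardize(matrix.subset_markers(np.flatnonzero(poly))))
        # near-fully-inbred lines: mean diagonal well above the outbred value 1
        assert np.diag(G.K).mean() > 1.3


class TestHadamard:
    def test_identity_fixed_point(self):
        G = KernelMatrix(np.eye(3), "G", ["a", "b", "c"])
        np.testing.assert_allclose(hadamard_epistasis(G).K, np.eye(3))

    def test_entrywise_square(self):
        G = KernelMatrix(np.array([[2.0, -2.0], [-2.0, 2.0]]), "G", ["a", "b"])
        np.testing.assert_allclose(hadamard_epistasis(G).K, [[4, 4], [4, 4]])

    def test_requires_additive_kernel(self):
        K = KernelMatrix(np.eye(2), "GoG", ["a", "b"])
        with pytest.raises(ValueError):
            hadamard_epistasis(K)

    def test_psd_preserved_on_random_kernels(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            A = rng.standard_normal((10, 6))
            G = KernelMatrix(A @ A.T, "G", [str(i) for i in range(10)])
            GG = hadamard_epistasis(G)
            assert GG.min_eigenvalue() >= -1e-8 * max(np.abs(GG.K).max(), 1.0)


class TestXuEpistasis:
    def test_single_pair_matches_direct_construction(self):
        rng = np.random.default_rng(6)
        W = rng.standard_normal((5, 2))
        std = StandardizedMarkers(W=W, theta=np.full(2, 0.5),
                                  line_ids=[str(i) for i in range(5)])
        z = W[:, 0] * W[:, 1]
        np.testing.assert_allclose(xu_epistasis(std).K, np.outer(z, z), atol=1e-12)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(7)
        d = rng.integers(0, 3, (8, 12)).astype(float)
        std = standardize(make_matrix(d))
        Kaa = xu_epistasis(std)
        W, p = std.W, 12
        Z = np.column_stack([W[:, j] * W[:, k] for j in range(p) for k in range(j + 1, p)])
        np.testing.assert_allclose(Kaa.K, Z @ Z.T / Z.shape[1], atol=1e-10)

    def test_requires_two_markers(self):
        std = StandardizedMarkers(W=np.ones((3, 1)), theta=np.array([0.5]),
                                  line_ids=["a", "b", "c"])
        with pytest.raises(ValueError):
            xu_epistasis(std)

    def test_collinear_with_hadamard_on_family_data(self, small_genome):
        matrix, _, _ = small_genome
        poly = matrix.dosage.std(axis=0) > 0
        std = standardize(matrix.subset_markers(np.flatnonzero(poly)))
        G = additive_kernel(std)
        GG = hadamard_epistasis(G)
        Kaa = xu_epistasis(std)
        iu = np.triu_indices(G.n_lines, k=1)
        r = np.corrcoef(GG.K[iu], Kaa.K[iu])[0, 1]
        assert r > 0.9


class TestKernelMatrix:
    def test_symmetry_and_psd_of_pipeline_kernels(self, small_genome):
        matrix, _, _ = small_genome
        poly = matrix.dosage.std(axis=0) > 0
        std = standardize(matrix.subset_markers(np.flatnonzero(poly)))
        for K in (additive_kernel(std), hadamard_epistasis(additive_kernel(std)),
                  xu_epistasis(std)):
            np.testing.assert_allclose(K.K, K.K.T, atol=1e-10)
            assert K.min_eigenvalue() >= -1e-8 * max(np.abs(K.K).max(), 1.0)

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(8)
        A = rng.standard_normal((6, 4))
        G = KernelMatrix(A @ A.T, "G", [f"L{i}" for i in range(6)], {"p": 4})
        path = tmp_path / "G.tsv"
        G.save(path)
        back = KernelMatrix.load(path)
        assert back.kind == "G"
        assert back.line_ids == G.line_ids
        np.testing.assert_allclose(back.K, G.K, atol=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            KernelMatrix(np.array([[1.0, 0.5], [0.0, 1.0]]), "G", ["a", "b"])
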