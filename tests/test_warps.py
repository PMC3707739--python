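import numpy as np
import pytest

from morphuniq.procrustes import ProcrustesResult, gpa_align
from morphuniq.warps import (
    CoincidentLandmarksError,
    bending_energy_matrix,
    build_shape_basis,
    deformation_grid,
    relative_warps,
    rw_regression_direction,
    shape_variables,
    tps_interpolant,
)
from conftest import make_noisy_shapes


class TestShapeBasis:
    def test_k11_has_8_principal_warps_and_3_zero_eigenvalues(self, study_chain):
        basis = study_chain[3]
        assert basis.principal_warps.shape == (11, 8)
        assert basis.n_variables == 18
        vals = np.linalg.eigvalsh(basis.bending_energy)
        assert (np.abs(vals) < 1e-10).sum() == 3
        assert (basis.warp_eigenvalues > 0).all()

    def test_affine_field_has_zero_bending_energy(self, rng):
        base, _ = make_noisy_shapes(rng, n=1, noise=0.0)
        be = bending_energy_matrix(base)
        affine = 0.3 * base[:, 0] - 0.7 * base[:, 1] + 0.2  # any affine function
        assert abs(affine @ be @ affine) < 1e-10

    def test_k4_square_matches_dense_tps_oracle(self):
        """Single principal warp of a square equals the bending energy built
        from an explicit solve of the full bordered TPS system."""
        sq = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, -1.0], [-1.0, 1.0]]) / (2 * np.sqrt(2))
        basis = build_shape_basis(sq)
        assert basis.principal_warps.shape == (4, 1)
        # oracle: eigenvalue of quadratic form restricted to non-affine space
        from morphuniq.warps import tps_kernel

        k = 4
        d2 = ((sq[:, None] - sq[None, :]) ** 2).sum(-1)
        kmat = tps_kernel(d2)
        p = np.column_stack([np.ones(k), sq])
        l = np.zeros((k + 3, k + 3))
        l[:k, :k] = kmat
        l[:k, k:] = p
        l[k:, :k] = p.T
        be_oracle = np.linalg.inv(l)[:k, :k]
        q, _ = np.linalg.qr(p)
        proj = np.eye(k) - q @ q.T
        vals = np.linalg.eigvalsh(proj @ be_oracle @ proj)
        assert basis.warp_eigenvalues[0] == pytest.approx(vals[-1], rel=1e-10)

    def test_coincident_landmarks_rejected(self):
        bad = np.array([[0.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(CoincidentLandmarksError):
            build_shape_basis(bad)

    def test_basis_orthonormal_and_orthogonal_to_similarity(self, study_chain):
        basis = study_chain[3]
        b = basis.basis_matrix
        np.testing.assert_allclose(b.T @ b, np.eye(b.shape[1]), atol=1e-10)
        x = basis.consensus
        k = x.shape[0]
        sim = np.column_stack(
            [
                np.column_stack([np.ones(k), np.zeros(k)]).reshape(-1),
                np.column_stack([np.zeros(k), np.ones(k)]).reshape(-1),
                x.reshape(-1),
                np.column_stack([-x[:, 1], x[:, 0]]).reshape(-1),
            ]
        )
        np.testing.assert_allclose(b.T @ sim, 0, atol=1e-10)


class TestShapeVariables:
    def test_consensus_specimen_scores_zero(self, study_chain):
        _, _, gpa, basis, _, _ = study_chain
        res = ProcrustesResult(
            aligned=np.stack([gpa.consensus, gpa.consensus]),
            consensus=gpa.consensus,
            centroid_sizes=np.ones(2),
            iterations=1,
            converged=True,
        )
        sv = shape_variables(res, basis)
        np.testing.assert_allclose(sv.scores, 0, atol=1e-12)

    def test_dimension_is_2k_minus_4(self, study_chain):
        sv = study_chain[4]
        assert sv.m == 18

    def test_affine_deformation_has_zero_partial_warp_scores(self, study_chain):
        _, _, gpa, basis, _, _ = study_chain
        affine = gpa.consensus @ np.array([[0.02, 0.01], [0.015, -0.02]])
        res = ProcrustesResult(
            aligned=(gpa.consensus + affine)[None, :, :].repeat(2, 0),
            consensus=gpa.consensus,
            centroid_sizes=np.ones(2),
            iterations=1,
            converged=True,
        )
        sv = shape_variables(res, basis)
        assert np.abs(sv.scores[:, :-2]).max() < 1e-10  # partial warps silent
        assert np.abs(sv.scores[:, -2:]).max() > 0  # uniform terms carry it

    def test_score_roundtrip_reconstruction(self, study_chain):
        """Scores reproduce the tangent-space deviation through the basis."""
        _, _, gpa, basis, sv, _ = study_chain
        recon = sv.reconstruct().reshape(sv.n, -1)
        dev = (gpa.aligned - gpa.consensus).reshape(sv.n, -1)
        b = basis.basis_matrix
        proj = dev @ b @ b.T
        np.testing.assert_allclose(recon, proj, atol=1e-12)

    def test_variance_preserved_at_small_amplitude(self, rng):
        _, arr = make_noisy_shapes(rng, n=25, noise=0.0008)
        gpa = gpa_align(arr)
        basis = build_shape_basis(gpa.consensus)
        sv = shape_variables(gpa, basis)
        dev = (gpa.aligned - gpa.consensus).reshape(25, -1)
        assert abs((sv.scores**2).sum() - (dev**2).sum()) < 1e-8

    def test_consensus_mismatch_rejected(self, study_chain, rng):
        _, _, gpa, _, _, _ = study_chain
        other = build_shape_basis(rng.normal(size=(11, 2)))
        with pytest.raises(ValueError, match="consensus"):
            shape_variables(gpa, other)


class TestRelativeWarps:
    def test_percent_variance_sums_to_100(self, study_chain):
        rw = study_chain[5]
        assert rw.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_matches_covariance_eigendecomposition(self, study_chain):
        """RW eigenvalues/loadings equal a direct covariance eigensolve."""
        sv, rw = study_chain[4], study_chain[5]
        x = sv.scores - sv.scores.mean(0)
        cov = x.T @ x / (x.shape[0] - 1)
        vals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(rw.eigenvalues, np.clip(vals, 0, None), atol=1e-9)
        for j in range(3):
            v = rw.loadings[:, j]
            np.testing.assert_allclose(cov @ v, rw.eigenvalues[j] * v, atol=1e-9)

    def test_score_variance_equals_eigenvalue(self, study_chain):
        rw = study_chain[5]
        np.testing.assert_allclose(
            rw.scores.var(axis=0, ddof=1), rw.eigenvalues, atol=1e-9
        )

    def test_duplication_invariance(self, study_chain):
        sv = study_chain[4]
        doubled = relative_warps(np.vstack([sv.scores, sv.scores]))
        single = relative_warps(sv.scores)
        np.testing.assert_allclose(
            doubled.percent_variance, single.percent_variance, atol=1e-8
        )

    def test_specimen_permutation_invariance(self, study_chain, rng):
        sv = study_chain[4]
        perm = rng.permutation(sv.n)
        shuffled = relative_warps(sv.scores[perm])
        original = relative_warps(sv.scores)
        np.testing.assert_allclose(
            np.abs(shuffled.loadings), np.abs(original.loadings), atol=1e-8
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            relative_warps(np.ones((5, 4)))


class TestRegressionDirection:
    def test_parallel_to_rw1_loading(self, study_chain):
        sv, rw = study_chain[4], study_chain[5]
        d = rw_regression_direction(sv, rw.scores[:, 0])
        cos = abs(d @ rw.loadings[:, 0]) / np.linalg.norm(d)
        assert cos == pytest.approx(1.0, abs=1e-10)

    def test_two_specimens_give_difference_direction(self, rng):
        x = rng.normal(size=(2, 6))
        d = rw_regression_direction(x, np.array([-1.0, 1.0]))
        diff = x[1] - x[0]
        cos = abs(d @ diff) / (np.linalg.norm(d) * np.linalg.norm(diff))
        assert cos == pytest.approx(1.0, abs=1e-12)

    def test_independent_noise_scores_give_small_direction(self, rng):
        x = rng.normal(size=(4000, 6))
        noise_scores = rng.normal(size=4000)
        d = rw_regression_direction(x, noise_scores)
        assert np.linalg.norm(d) < 0.1

    def test_zero_variance_scores_rejected(self, rng):
        with pytest.raises(ValueError):
            rw_regression_direction(rng.normal(size=(5, 3)), np.ones(5))


class TestDeformationGrid:
    def test_zero_magnitude_identity(self, study_chain):
        basis = study_chain[3]
        d = np.zeros(18)
        d[0] = 1.0
        g0 = deformation_grid(basis, d, 0.0, grid_shape=(8, 8))
        g1 = deformation_grid(basis, d, 0.0, grid_shape=(8, 8))
        np.testing.assert_allclose(g0, g1)
        # matches the raw meshgrid (no warping applied)
        assert g0.shape == (8, 8, 2)

    def test_uniform_direction_gives_affine_grid(self, study_chain):
        """A pure uniform-component displacement keeps grid lines parallel."""
        basis = study_chain[3]
        d = np.zeros(18)
        d[-2] = 1.0
        g = deformation_grid(basis, d, 0.05, grid_shape=(6, 6))
        # affine map: second differences along rows/cols vanish
        row_dd = np.diff(g, n=2, axis=0)
        col_dd = np.diff(g, n=2, axis=1)
        assert np.abs(row_dd).max() < 1e-8
        assert np.abs(col_dd).max() < 1e-8

    def test_interpolant_hits_landmark_targets(self, study_chain):
        basis = study_chain[3]
        d = np.zeros(18)
        d[2] = 1.0
        mag = 0.04
        disp = (basis.basis_matrix @ d).reshape(11, 2) * mag
        f = tps_interpolant(basis.consensus, basis.consensus + disp)
        np.testing.assert_allclose(
            f(basis.consensus), basis.consensus + disp, atol=1e-8
        )

    def test_nonfinite_magnitude_rejected(self, study_chain):
        with pytest.raises(ValueError):
            deformation_grid(study_chain[3], np.zeros(18), np.nan)
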