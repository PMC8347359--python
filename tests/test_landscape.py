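"""Conformational landscape: RMSD matrices, classical MDS, GMM/BIC, PCA."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmdkit.core_model import TrajectoryEnsemble, kabsch_superpose
from tmdkit.landscape import (
    DistanceMatrix,
    bhattacharyya_distance,
    classical_mds,
    fit_gmm,
    fit_pca,
    gmm_n_params,
    project_onto,
    rmsd_matrix,
    select_k_bic,
)
from tmdkit.synthetic import BundleSpec, build_bundle, generate_basin_trajectory


def _procrustes_residual(a: np.ndarray, b: np.ndarray) -> float:
    """RMS residual after the best rigid+reflection alignment of two
    centred planar configurations (orthogonal Procrustes)."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(a.T @ b)
    R = u @ vt
    return float(np.sqrt(((a - b @ R.T) ** 2).sum(axis=1).mean()))


class TestRMSDMatrix:
    def test_identical_frames_all_zero(self, static_ensemble):
        D = rmsd_matrix(static_ensemble)
        assert np.allclose(D.values, 0.0, atol=1e-7)

    def test_rigid_transform_removed(self, small_bundle):
        _, top, ref = small_bundle
        R = Rotation.from_euler("z", 70, degrees=True).as_matrix()
        moved = ref @ R.T + np.array([3.0, -2.0, 8.0])
        ens = TrajectoryEnsemble(np.stack([ref, moved]), [0.0, 1.0], top)
        D = rmsd_matrix(ens)
        assert D.values[0, 1] < 1e-6

    def test_matches_per_pair_kabsch_oracle(self, small_bundle):
        _, top, ref = small_bundle
        rng = np.random.default_rng(12)
        coords = ref[None] + rng.normal(scale=0.8, size=(3, top.n_atoms, 3))
        ens = TrajectoryEnsemble(coords, np.arange(3.0), top)
        D = rmsd_matrix(ens)
        x = ens.ca_coords()
        for i in range(3):
            for j in range(3):
                expected = 0.0 if i == j else kabsch_superpose(x[i], x[j]).rmsd
                assert D.values[i, j] == pytest.approx(expected, abs=1e-9)

    def test_small_selection_rejected(self, static_ensemble):
        with pytest.raises(ValueError):
            rmsd_matrix(static_ensemble, selection=[1, 2])


class TestClassicalMDS:
    def test_equilateral_triangle_distances_preserved(self):
        d = 2.0
        D = np.full((3, 3), d) - d * np.eye(3)
        emb = classical_mds(DistanceMatrix(D), dims=2)
        for i in range(3):
            for j in range(i + 1, 3):
                dist = np.linalg.norm(emb.points[i] - emb.points[j])
                assert dist == pytest.approx(d, abs=1e-9)
        assert np.allclose(emb.points.mean(axis=0), 0.0, atol=1e-9)

    def test_collinear_points_one_dimensional(self):
        pos = np.array([0.0, 1.0, 2.0, 3.0])
        D = np.abs(pos[:, None] - pos[None, :])
        emb = classical_mds(DistanceMatrix(D), dims=2)
        # 1-D configuration: second eigenvalue vanishes, distances exact
        assert emb.eigenvalues[1] == pytest.approx(0.0, abs=1e-9)
        for i in range(4):
            for j in range(4):
                got = np.linalg.norm(emb.points[i] - emb.points[j])
                assert got == pytest.approx(D[i, j], abs=1e-9)

    def test_zero_matrix_embeds_to_origin(self):
        emb = classical_mds(DistanceMatrix(np.zeros((5, 5))), dims=2)
        assert np.allclose(emb.points, 0.0, atol=1e-12)

    def test_recovers_planar_configuration_up_to_rotation(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(30, 2)) * [4.0, 1.5]
        D = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
        emb = classical_mds(DistanceMatrix(D), dims=2)
        assert _procrustes_residual(pts, emb.points) < 1e-6

    def test_too_many_dims_rejected(self):
        with pytest.raises(ValueError):
            classical_mds(DistanceMatrix(np.zeros((3, 3))), dims=5)


class TestFitGMM:
    def test_single_component_closed_form(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(300, 2)) @ np.array([[1.0, 0.4], [0.0, 0.8]])
        model = fit_gmm(X, K=1, n_starts=1, seed=0)
        assert np.allclose(model.means[0], X.mean(axis=0), atol=1e-6)
        mle_cov = np.cov(X.T, bias=True)
        assert np.allclose(model.covariances[0], mle_cov, atol=1e-6)

    def test_two_planted_gaussians_recovered(self):
        rng = np.random.default_rng(4)
        X = np.vstack(
            [rng.normal(loc=(0, 0), size=(200, 2)),
             rng.normal(loc=(10, 0), size=(200, 2))]
        )
        truth = np.repeat([0, 1], 200)
        model = fit_gmm(X, K=2, n_starts=5, seed=0)
        labels = model.labels
        agree = max(
            (labels == truth).mean(), (labels == 1 - truth).mean()
        )
        assert agree >= 0.99

    def test_log_likelihood_monotone_over_em_iterations(self):
        rng = np.random.default_rng(9)
        X = np.vstack(
            [rng.normal(loc=(0, 0), size=(120, 2)),
             rng.normal(loc=(5, 3), size=(80, 2))]
        )
        for K in (1, 2, 3):
            model = fit_gmm(X, K=K, n_starts=3, seed=1)
            ll = np.asarray(model.ll_history)
            assert np.all(np.diff(ll) >= -1e-7 * np.abs(ll[:-1]))

    def test_bic_formula_audit(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(150, 2))
        model = fit_gmm(X, K=3, n_starts=2, seed=5)
        expected = gmm_n_params(3, 2) * np.log(150) - 2.0 * model.log_likelihood
        assert model.bic == pytest.approx(expected, rel=1e-12)
        assert gmm_n_params(3, 2) == (3 - 1) + 2 * 3 + 3 * 3

    def test_agrees_with_sklearn_mixture(self):
        # independent implementation cross-check on an easy problem
        from sklearn.mixture import GaussianMixture

        rng = np.random.default_rng(6)
        X = np.vstack(
            [rng.normal(loc=(0, 0), scale=0.7, size=(150, 2)),
             rng.normal(loc=(8, 8), scale=0.7, size=(150, 2))]
        )
        ours = fit_gmm(X, K=2, n_starts=5, seed=0)
        ref = GaussianMixture(2, covariance_type="full", n_init=5,
                              random_state=0).fit(X)
        # same optimum: mean log-likelihood and sorted means agree
        assert ours.log_likelihood / len(X) == pytest.approx(
            ref.score(X), abs=1e-3
        )
        a = ours.means[np.argsort(ours.means[:, 0])]
        b = ref.means_[np.argsort(ref.means_[:, 0])]
        assert np.allclose(a, b, atol=0.05)

    def test_more_components_than_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gmm(np.zeros((3, 2)), K=5)


class TestSelectKBIC:
    def test_single_gaussian_selects_one(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(300, 2))
        model = select_k_bic(X, k_range=range(1, 6), n_starts=3, seed=0)
        assert model.K == 1

    def test_three_separated_basins_select_three(self):
        rng = np.random.default_rng(8)
        centers = np.array([(0, 0), (12, 0), (0, 12)])
        X = np.vstack([rng.normal(loc=c, size=(120, 2)) for c in centers])
        model = select_k_bic(X, k_range=range(1, 9), n_starts=3, seed=0)
        assert model.K == 3

    def test_singleton_range_returns_that_k(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(100, 2))
        model = select_k_bic(X, k_range=[2], n_starts=2, seed=0)
        assert model.K == 2

    @pytest.mark.parametrize("k_true", [4, 7])
    def test_planted_k_recovered_at_large_separation(self, k_true):
        # spot checks; the 20-replicate recovery-rate suite lives in the
        # acceptance tests
        rng = np.random.default_rng(200 + k_true)
        centers = np.array(
            [(20 * np.cos(2 * np.pi * i / k_true),
              20 * np.sin(2 * np.pi * i / k_true)) for i in range(k_true)]
        )
        X = np.vstack(
            [rng.normal(loc=c, scale=1.0, size=(100, 2)) for c in centers]
        )
        model = select_k_bic(X, k_range=range(1, 11), n_starts=5, seed=1)
        assert model.K == k_true


class TestLandscapeEndToEnd:
    @pytest.mark.parametrize("n_basins", [4, 7])
    def test_planted_basin_count_recovered(self, n_basins):
        # multi-basin trajectory -> RMSD matrix -> MDS -> BIC cluster count
        spec = BundleSpec(n_helices=4, residues_per_helix=8)
        top, ref = build_bundle(spec, seed=5)
        rng = np.random.default_rng(100 + n_basins)
        offsets = [
            (7.0 * np.cos(2 * np.pi * b / n_basins),
             7.0 * np.sin(2 * np.pi * b / n_basins),
             4.0 * (b % 2))
            for b in range(n_basins)
        ]
        ens, truth = generate_basin_trajectory(
            top, ref, offsets, frames_per_basin=30, noise_sigma=0.15,
            seed=200 + n_basins, moving_residues=spec.helix_residues(1),
        )
        D = rmsd_matrix(ens)
        emb = classical_mds(D)
        model = select_k_bic(emb, k_range=range(1, 11), n_starts=5, seed=0)
        assert model.K == n_basins


class TestPCA:
    def test_planted_single_mode_dominates(self, small_bundle):
        spec, top, ref = small_bundle
        helix1 = top.ca_indices(spec.helix_residues(1))
        coords = np.repeat(ref[None], 60, axis=0)
        amp = np.sin(np.linspace(0, 6 * np.pi, 60)) * 3.0
        coords[:, helix1, 0] += amp[:, None]
        ens = TrajectoryEnsemble(coords, np.arange(60.0), top)
        model = fit_pca(ens)
        frac = model.eigenvalues[0] / model.eigenvalues.sum()
        assert frac > 0.999

    def test_static_ensemble_all_zero_eigenvalues(self, static_ensemble):
        model = fit_pca(static_ensemble)
        assert np.allclose(model.eigenvalues, 0.0, atol=1e-12)

    def test_eigenvalue_sum_equals_total_variance(self, small_bundle):
        _, top, ref = small_bundle
        rng = np.random.default_rng(44)
        coords = ref[None] + rng.normal(scale=0.4, size=(40, top.n_atoms, 3))
        ens = TrajectoryEnsemble(coords, np.arange(40.0), top)
        model = fit_pca(ens)
        from tmdkit.core_model import superpose_frames

        x = superpose_frames(ens.ca_coords(), model.mean_structure)
        total = ((x - model.mean_structure) ** 2).sum(axis=(1, 2)).mean()
        assert model.eigenvalues.sum() == pytest.approx(total, abs=1e-6)

    def test_eigenvectors_orthonormal(self, small_bundle):
        _, top, ref = small_bundle
        rng = np.random.default_rng(45)
        coords = ref[None] + rng.normal(scale=0.4, size=(30, top.n_atoms, 3))
        ens = TrajectoryEnsemble(coords, np.arange(30.0), top)
        model = fit_pca(ens)
        g = model.eigenvectors.T @ model.eigenvectors
        assert np.allclose(g, np.eye(g.shape[0]), atol=1e-8)


class TestProjection:
    def _noisy_ens(self, top, ref, seed, F=50):
        rng = np.random.default_rng(seed)
        coords = ref[None] + rng.normal(scale=0.4, size=(F, top.n_atoms, 3))
        return TrajectoryEnsemble(coords, np.arange(float(F)), top)

    def test_projecting_mean_structure_is_zero(self, small_bundle):
        # the bundles are Cα-only, so the PCA mean is a full coordinate set
        _, top, ref = small_bundle
        ens = self._noisy_ens(top, ref, 50)
        model = fit_pca(ens)
        mean_ens = TrajectoryEnsemble(model.mean_structure[None], [0.0], top)
        proj = project_onto(model, mean_ens, n_components=3)
        assert np.allclose(proj, 0.0, atol=1e-9)

    def test_training_projection_variance_equals_eigenvalues(self, small_bundle):
        _, top, ref = small_bundle
        ens = self._noisy_ens(top, ref, 51)
        model = fit_pca(ens)
        proj = project_onto(model, ens, n_components=5)
        var = (proj ** 2).mean(axis=0) - proj.mean(axis=0) ** 2
        # projections are centred by construction
        assert np.allclose((proj.mean(axis=0)), 0.0, atol=1e-9)
        assert np.allclose(var, model.eigenvalues[:5], atol=1e-6)

    def test_twin_ensemble_overlaps_training_cloud(self, small_bundle):
        # two ensembles from the same generator (planted breathing mode +
        # noise, different seeds/phases) must occupy the same region of the
        # essential subspace — the same-dynamics check used to compare
        # field-on and field-off simulations
        spec, top, ref = small_bundle
        helix1 = top.ca_indices(spec.helix_residues(1))

        def generated(seed, phase):
            rng = np.random.default_rng(seed)
            F = 120
            coords = ref[None] + rng.normal(scale=0.2, size=(F, top.n_atoms, 3))
            amp = 2.5 * np.sin(np.linspace(0, 8 * np.pi, F) + phase)
            coords[:, helix1, 0] += amp[:, None]
            return TrajectoryEnsemble(coords, np.arange(float(F)), top)

        train = generated(52, 0.0)
        twin = generated(53, 1.0)
        model = fit_pca(train)
        p1 = project_onto(model, train, n_components=2)
        p2 = project_onto(model, twin, n_components=2)
        assert bhattacharyya_distance(p1, p2) < 0.2

    def test_selection_mismatch_rejected(self, small_bundle):
        _, top, ref = small_bundle
        ens = self._noisy_ens(top, ref, 54)
        model = fit_pca(ens, selection=top.protein_residues[:20])
        model.selection = top.protein_residues[:10]  # corrupt the selection
        with pytest.raises(ValueError, match="does not match"):
            project_onto(model, ens)
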