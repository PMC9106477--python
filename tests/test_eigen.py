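import numpy as np
import pytest

from fdcnet.eigen import (
    EigenFeatureExtractor,
    EigenModel,
    center,
    eigen_decompose,
    match,
    mean_image,
    project,
    snapshot_covariance,
    total_scatter,
)


class TestMeanCenter:
    def test_identical_images(self):
        X = np.tile(np.arange(6.0), (2, 1))
        assert np.array_equal(mean_image(X), np.arange(6.0))
        assert np.all(center(X, mean_image(X)) == 0)

    def test_two_point_average(self):
        X = np.stack([np.zeros(4), np.full(4, 2.0)])
        assert np.array_equal(mean_image(X), np.ones(4))
        A = center(X, mean_image(X))
        assert np.array_equal(A[:, 0], -A[:, 1])

    def test_mean_matches_independent_summation(self, rng):
        X = rng.normal(size=(5, 12))
        acc = np.zeros(12)
        for row in X:
            acc += row
        assert np.allclose(mean_image(X), acc / 5)

    def test_centering_identity(self, rng):
        X = rng.normal(size=(7, 9))
        A = center(X, mean_image(X))
        assert np.allclose(A.sum(axis=1), 0, atol=1e-10)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_image(np.zeros((0, 4)))


class TestSnapshotCovariance:
    def test_zero_matrix(self):
        assert np.all(snapshot_covariance(np.zeros((8, 3))) == 0)

    def test_orthonormal_columns_give_identity(self):
        A = np.eye(5)[:, :3]
        assert np.allclose(snapshot_covariance(A), np.eye(3))

    def test_symmetric_psd(self, rng):
        A = rng.normal(size=(20, 6))
        C = snapshot_covariance(A)
        assert np.allclose(C, C.T)
        assert np.linalg.eigvalsh(C).min() >= -1e-10


class TestEigenDecompose:
    def test_rank_one(self):
        v = np.array([3.0, 4.0, 0.0, 0.0])
        A = np.zeros((4, 2))
        A[:, 0] = v
        model = eigen_decompose(snapshot_covariance(A), A, f=1)
        assert np.allclose(np.abs(model.components[0]), np.abs(v / 5.0))
        assert model.eigenvalues[0] == pytest.approx(25.0)

    def test_snapshot_equals_direct_route(self, rng):
        d, M = 16, 5
        X = rng.normal(size=(M, d))
        A = center(X, mean_image(X))
        model = eigen_decompose(snapshot_covariance(A), A, f=M - 1)
        direct_evals = np.sort(np.linalg.eigvalsh(A @ A.T))[::-1][:M - 1]
        assert np.allclose(model.eigenvalues, np.clip(direct_evals, 0, None),
                           atol=1e-8)
        # reconstructions are sign-invariant: W^T W Phi_i must agree
        W = model.components
        evals, V = np.linalg.eigh(A @ A.T)
        Wd = V[:, np.argsort(evals)[::-1][:M - 1]].T
        for i in range(M):
            phi = A[:, i]
            assert np.allclose(W.T @ (W @ phi), Wd.T @ (Wd @ phi), atol=1e-8)

    def test_full_rank_projection_reconstructs(self, rng):
        X = rng.normal(size=(5, 10))
        A = center(X, mean_image(X))
        model = eigen_decompose(snapshot_covariance(A), A, f=4)
        W = model.components
        for i in range(5):
            phi = A[:, i]
            assert np.allclose(W.T @ (W @ phi), phi, atol=1e-8)

    def test_rank_bound_enforced(self, rng):
        A = rng.normal(size=(8, 3))
        with pytest.raises(ValueError, match="rank"):
            eigen_decompose(snapshot_covariance(A), A, f=3)

    def test_components_orthonormal(self, rng):
        X = rng.normal(size=(6, 20))
        A = center(X, mean_image(X))
        model = eigen_decompose(snapshot_covariance(A), A, f=5)
        G = model.components @ model.components.T
        assert np.allclose(G, np.eye(5), atol=1e-8)

    def test_retained_eigenvalue_mass_bounded_by_trace(self, rng):
        X = rng.normal(size=(6, 9))
        A = center(X, mean_image(X))
        C = snapshot_covariance(A)
        for f in range(1, 6):
            model = eigen_decompose(C, A, f=f)
            assert model.eigenvalues.sum() <= np.trace(C) + 1e-8


class TestTotalScatter:
    def test_single_sample_zero(self):
        X = np.array([[1.0, 2.0, 3.0]])
        assert np.all(total_scatter(X, X[0]) == 0)

    def test_two_symmetric_samples(self):
        u = np.array([1.0, -2.0])
        S = total_scatter(np.stack([u, -u]), np.zeros(2))
        assert np.allclose(S, 2 * np.outer(u, u))

    def test_equals_AAt_at_the_mean(self, rng):
        X = rng.normal(size=(6, 5))
        mu = mean_image(X)
        A = center(X, mu)
        assert np.allclose(total_scatter(X, mu), A @ A.T)


class TestProjectMatch:
    @pytest.fixture
    def model(self, rng):
        X = rng.normal(size=(6, 12))
        A = center(X, mean_image(X))
        return eigen_decompose(snapshot_covariance(A), A, f=4,
                               mean=mean_image(X))

    def test_mean_maps_to_origin(self, model):
        assert np.allclose(project(model.mean, model), 0)

    def test_component_direction_gives_unit_coordinate(self, model):
        c = 2.5
        x = model.mean + c * model.components[2]
        y = project(x, model)
        expect = np.zeros(4)
        expect[2] = c
        assert np.allclose(y, expect, atol=1e-8)

    def test_projection_contracts_norm(self, model, rng):
        for _ in range(20):
            x = rng.normal(size=12)
            y = project(x, model)
            assert np.linalg.norm(y) <= np.linalg.norm(x - model.mean) + 1e-10

    def test_match_exact_member(self):
        g = [np.array([1.0, 2.0]), np.array([3.0, 4.0])]
        res = match(np.array([3.0, 4.0]), g, tau=0.5)
        assert res.distance == 0.0 and res.detected
        assert res.nearest_index == 1

    def test_match_threshold_is_strict(self):
        res = match(np.array([3.0, 4.0]), [np.zeros(2)], tau=5.0)
        assert res.distance == pytest.approx(5.0)
        assert not res.detected

    def test_match_equals_bruteforce_minimum(self, rng):
        g = [rng.normal(size=5) for _ in range(20)]
        y = rng.normal(size=5)
        res = match(y, g, tau=1.0)
        dists = [np.linalg.norm(y - v) for v in g]
        assert res.distance == pytest.approx(min(dists))
        assert res.nearest_index == int(np.argmin(dists))

    def test_match_gallery_permutation_invariant_distance(self, rng):
        g = [rng.normal(size=3) for _ in range(10)]
        y = rng.normal(size=3)
        d1 = match(y, g, tau=1.0).distance
        d2 = match(y, g[::-1], tau=1.0).distance
        assert d1 == pytest.approx(d2)

    def test_empty_gallery_rejected(self):
        with pytest.raises(ValueError):
            match(np.zeros(2), [], tau=1.0)


class TestExtractor:
    def test_fitted_attributes_and_shapes(self, rng):
        X = rng.normal(size=(10, 25))
        ex = EigenFeatureExtractor(n_components=4).fit(X)
        assert ex.components_.shape == (4, 25)
        assert ex.f_ == 4
        assert np.all(np.diff(ex.eigenvalues_) <= 1e-8)
        assert ex.transform(X).shape == (10, 4)
        assert ex.tau_ > 0

    def test_reconstruction_error_monotone_in_f(self, rng):
        X = rng.normal(size=(8, 30))
        errs = []
        for f in range(1, 8):
            ex = EigenFeatureExtractor(n_components=f).fit(X)
            Y = ex.transform(X)
            recon = Y @ ex.components_ + ex.mean_
            errs.append(np.linalg.norm(X - recon))
        assert all(e2 <= e1 + 1e-8 for e1, e2 in zip(errs, errs[1:]))

    def test_training_image_detected(self, rng):
        X = rng.normal(size=(6, 16))
        ex = EigenFeatureExtractor(n_components=3).fit(X)
        res = ex.detect(X[2])
        assert res.detected and res.distance < 1e-8

    def test_variance_threshold_selects_f(self, rng):
        X = rng.normal(size=(9, 40))
        ex = EigenFeatureExtractor(variance_threshold=0.95).fit(X)
        lam = np.clip(np.linalg.eigvalsh(
            snapshot_covariance(center(X, mean_image(X)))), 0, None)[::-1]
        frac = np.cumsum(lam) / lam.sum()
        assert ex.f_ == min(int(np.searchsorted(frac, 0.95)) + 1, 8)

    def test_model_roundtrip(self, tmp_path, rng):
        X = rng.normal(size=(5, 9))
        ex = EigenFeatureExtractor(n_components=2).fit(X)
        ex.model_.save(tmp_path / "m.npz", provenance={"seed": 0, "M": 5})
        back = EigenModel.load(tmp_path / "m.npz")
        assert np.allclose(back.components, ex.components_)
        assert back.tau == pytest.approx(ex.tau_)
        assert (tmp_path / "m.json").exists()
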