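"""PCA, KNN, confidence ellipses and non-negative curve resolution."""

import numpy as np
import pytest
from scipy import stats

from sorsid.chemometrics import (
    KNNModel,
    assign_container,
    confidence_ellipse,
    cosine_similarity,
    fit_mcr,
    fit_pca,
    knn_classify,
    match_components_to_materials,
    project,
    reconstruct,
)


class TestPCA:
    def test_rank_one_data(self):
        rng = np.random.default_rng(0)
        direction = rng.random(20)
        X = np.outer(rng.random(10), direction)
        model = fit_pca(X, 3)
        assert model.explained_variance[0] == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(1)
        model = fit_pca(rng.random((15, 30)), 8)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(8), atol=1e-8)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.random((10, 20))
        model = fit_pca(X, 9)
        cov = np.cov(X, rowvar=False, bias=True)
        w = np.sort(np.linalg.eigvalsh(cov))[::-1]
        total = w.sum()
        np.testing.assert_allclose(
            model.explained_variance, (w / total)[:9], atol=1e-8
        )

    def test_matches_sklearn_up_to_sign(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(3)
        X = rng.random((12, 25))
        model = fit_pca(X, 5)
        sk = sklearn.PCA(n_components=5).fit(X)
        for ours, theirs in zip(model.loadings, sk.components_):
            assert abs(cosine_similarity(ours, theirs)) == pytest.approx(1.0, abs=1e-8)

    def test_variance_fractions_sum_to_one_at_full_rank(self):
        rng = np.random.default_rng(4)
        model = fit_pca(rng.random((9, 12)), 8)
        assert model.explained_variance.sum() == pytest.approx(1.0, abs=1e-9)

    def test_component_limit_enforced(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((4, 10)), 4)


class TestProjection:
    def test_training_mean_projects_to_origin(self):
        rng = np.random.default_rng(5)
        X = rng.random((8, 14))
        model = fit_pca(X, 3)
        np.testing.assert_allclose(project(model, X.mean(axis=0)), 0.0, atol=1e-10)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(6)
        X = rng.random((8, 6))
        model = fit_pca(X, 6)
        back = reconstruct(model, project(model, X))
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_training_scores_centered(self):
        rng = np.random.default_rng(7)
        X = rng.random((10, 12))
        model = fit_pca(X, 4)
        np.testing.assert_allclose(project(model, X).mean(axis=0), 0.0, atol=1e-10)


class TestEllipse:
    def test_isotropic_cloud_axes_equal(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((4000, 2))
        ell = confidence_ellipse(pts)
        w = np.linalg.eigvalsh(ell.covariance)
        assert w[1] / w[0] == pytest.approx(1.0, rel=0.15)

    def test_95_percent_coverage(self):
        rng = np.random.default_rng(9)
        cov = np.array([[2.0, 0.7], [0.7, 1.0]])
        pts = rng.multivariate_normal([1.0, -2.0], cov, size=20000)
        ell = confidence_ellipse(pts, level=0.95)
        frac = ell.contains(pts).mean()
        assert 0.93 <= frac <= 0.97

    def test_radius_is_chi2_quantile(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        ell = confidence_ellipse(pts, level=0.95)
        assert ell.mahalanobis_radius2 == pytest.approx(stats.chi2.ppf(0.95, 2))

    def test_degenerate_cloud_guarded(self):
        pts = np.tile([2.0, 3.0], (5, 1))
        ell = confidence_ellipse(pts)
        w = np.linalg.eigvalsh(ell.covariance)
        assert np.all(w >= 0.0)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            confidence_ellipse(np.zeros((2, 2)))


def brute_force_knn(X, y, q, k=4):
    """Exhaustive oracle with the same tie-break contract: majority vote,
    then smallest mean neighbor distance, then lexicographic label."""
    d = np.sqrt(((X - q) ** 2).sum(axis=1))
    order = np.argsort(d, kind="stable")[:k]
    votes, dists = {}, {}
    for i in order:
        votes[y[i]] = votes.get(y[i], 0) + 1
        dists.setdefault(y[i], []).append(d[i])
    top = max(votes.values())
    tied = sorted(
        [lab for lab, v in votes.items() if v == top],
        key=lambda lab: (np.mean(dists[lab]), lab),
    )
    return tied[0]


class TestKNN:
    def test_interior_training_point(self):
        X = np.array([[0.0], [0.1], [0.2], [0.3], [5.0]])
        y = np.array(["a", "a", "a", "a", "b"])
        model = KNNModel(X, y, k=4)
        assert knn_classify(model, np.array([0.15])).label == "a"

    def test_tie_broken_by_mean_distance(self):
        X = np.array([[0.0], [0.4], [1.0], [1.2]])
        y = np.array(["near", "near", "far", "far"])
        model = KNNModel(X, y, k=4)
        # 2-2 vote; "near" pair has the smaller mean distance to the query
        assert knn_classify(model, np.array([0.3])).label == "near"

    def test_exact_tie_broken_lexicographically(self):
        X = np.array([[-1.0], [1.0]])
        y = np.array(["zeta", "alpha"])
        model = KNNModel(X, y, k=2)
        assert knn_classify(model, np.array([0.0])).label == "alpha"

    def test_agrees_with_exhaustive_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.integers(0, 4, size=(50, 3)).astype(float)  # ties guaranteed
        y = np.array([f"c{i}" for i in rng.integers(0, 5, size=50)])
        model = KNNModel(X, y, k=4)
        queries = rng.integers(0, 4, size=(20, 3)).astype(float)
        for q in queries:
            assert knn_classify(model, q).label == brute_force_knn(X, y, q)


class TestMCR:
    @staticmethod
    def _three_component_problem(n=30, p=500, seed=0):
        # a separable problem: components with near-exclusive spectral
        # support AND a few near-pure mixture rows — the regime in which a
        # non-negative factorization is essentially unique, so "recovery"
        # is well-posed
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 1, p)
        S = np.stack([
            np.exp(-0.5 * ((x - c) / 0.04) ** 2)
            + 0.3 * np.exp(-0.5 * ((x - c - 0.08) / 0.03) ** 2)
            for c in (0.2, 0.5, 0.8)
        ])
        C = rng.random((n, 3)) + 0.1
        C[:3] = 0.02
        C[[0, 1, 2], [0, 1, 2]] = 1.0  # near-pure rows anchor each component
        return C, S, C @ S

    def test_exact_factorization_recovered(self):
        C, S, X = self._three_component_problem()
        model = fit_mcr(X, n_components=3, seed=0)
        assert model.reconstruction_error < 1e-3
        # match recovered spectra to truth up to permutation/scale
        used = set()
        for comp in model.component_spectra:
            best = max(
                (i for i in range(3) if i not in used),
                key=lambda i: cosine_similarity(comp, S[i]),
            )
            assert cosine_similarity(comp, S[best]) >= 0.99
            used.add(best)

    def test_rank_one_exact(self):
        rng = np.random.default_rng(11)
        X = np.outer(rng.random(8) + 0.1, rng.random(40) + 0.1)
        model = fit_mcr(X, n_components=1, seed=0)
        assert model.reconstruction_error < 1e-6

    def test_objective_non_increasing(self):
        _, _, X = self._three_component_problem(seed=5)
        noisy = X + 0.01 * np.random.default_rng(5).random(X.shape)
        model = fit_mcr(noisy, n_components=3, seed=0)
        hist = np.array(model.error_history)
        assert np.all(np.diff(hist) <= 1e-10)

    def test_factors_non_negative(self):
        rng = np.random.default_rng(12)
        X = rng.random((10, 60))
        model = fit_mcr(X, n_components=4, seed=0)
        assert model.component_spectra.min() >= 0.0
        assert model.scores.min() >= 0.0

    def test_agrees_with_sklearn_nmf_components(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        _, S, X = self._three_component_problem(seed=3)
        ours = fit_mcr(X, n_components=3, seed=0)
        theirs = sklearn.NMF(
            n_components=3, init="nndsvda", max_iter=2000, tol=1e-10
        ).fit(X)
        for comp in ours.component_spectra:
            best = max(
                cosine_similarity(comp, h) for h in theirs.components_
            )
            assert best >= 0.99

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError):
            fit_mcr(np.ones((3, 10)), n_components=4)


class TestAssignment:
    def test_tie_is_indeterminate(self):
        from sorsid.chemometrics import MCRModel

        model = MCRModel(
            component_spectra=np.ones((2, 5)),
            scores=np.array([[0.5, 0.5]]),
            n_components=2, n_iterations=1, converged=True,
            final_change=0.0, reconstruction_error=0.0,
        )
        out = assign_container(model, 0, {0: "a", 1: "b"})
        assert out.material == "indeterminate"

    def test_zero_scores_indeterminate(self):
        from sorsid.chemometrics import MCRModel

        model = MCRModel(
            component_spectra=np.ones((2, 5)),
            scores=np.array([[0.0, 0.0]]),
            n_components=2, n_iterations=1, converged=True,
            final_change=0.0, reconstruction_error=0.0,
        )
        assert assign_container(model, 0, {0: "a", 1: "b"}).material == "indeterminate"

    def test_material_map_by_cosine(self):
        from sorsid.chemometrics import MCRModel

        s1 = np.array([1.0, 0.0, 0.0, 0.0])
        s2 = np.array([0.0, 0.0, 1.0, 1.0])
        model = MCRModel(
            component_spectra=np.stack([s1, s2]),
            scores=np.array([[1.0, 0.2], [0.1, 2.0]]),
            n_components=2, n_iterations=1, converged=True,
            final_change=0.0, reconstruction_error=0.0,
        )
        refs = {"glass": s2 * 3.0, "polymer": s1 * 0.5}
        mapping = match_components_to_materials(model, refs)
        assert mapping == {0: "polymer", 1: "glass"}
        assert assign_container(model, 0, mapping).material == "polymer"
        assert assign_container(model, 1, mapping).material == "glass"
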