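"""GPA, coordinate PCA, shape synthesis, covariate correlation."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import auriclass as ac
from auriclass.homofit import HomologousModel
from auriclass.meshkit import MeshValidationError, SubjectMeta
from auriclass.shapespace import (
    fit_shape_pca,
    generalized_procrustes,
    load_shape_model,
    project_scores,
    save_shape_model,
    score_covariate_correlation,
    synthesize,
)


def _hm(verts, faces, sid="s", age=40):
    return HomologousModel(SubjectMeta(sid, "left", age), verts, faces, None)


def _toy_models(n=5, n_vertices=4, seed=0, faces=None):
    rng = np.random.default_rng(seed)
    if faces is None:
        faces = np.array([[0, 1, 2], [1, 2, 3]])
    return [
        _hm(rng.normal(size=(n_vertices, 3)), faces, f"s{i}", 30 + i)
        for i in range(n)
    ]


class TestGPA:
    def test_fixed_point_on_identical_copies(self, template):
        models = [_hm(template.vertices.copy(), template.faces, f"s{i}")
                  for i in range(3)]
        aligned, mean = generalized_procrustes(models, allow_scaling=False)
        centered = template.vertices - template.vertices.mean(axis=0)
        for m in aligned:
            np.testing.assert_allclose(m.vertices, centered, atol=1e-6)

    def test_similarity_transforms_collapse(self, template):
        rng = np.random.default_rng(3)
        models = []
        for i in range(6):
            rot = Rotation.random(random_state=10 + i).as_matrix()
            s = rng.uniform(0.7, 1.4)
            t = rng.normal(scale=10, size=3)
            models.append(_hm(s * template.vertices @ rot.T + t, template.faces, f"s{i}"))
        aligned, _ = generalized_procrustes(models, allow_scaling=True)
        ref = aligned[0].vertices
        for m in aligned[1:]:
            np.testing.assert_allclose(m.vertices, ref, atol=1e-6)

    def test_converges_on_synthetic_cohort(self, models414):
        aligned, mean = generalized_procrustes(models414[:50])
        assert np.all(np.isfinite(mean))
        np.testing.assert_allclose(mean.mean(axis=0), 0.0, atol=1e-9)

    def test_needs_two_models(self, template):
        with pytest.raises(MeshValidationError):
            generalized_procrustes([_hm(template.vertices, template.faces)])


class TestPCA:
    def test_two_specimens_rank_one(self):
        models = _toy_models(n=2)
        model = fit_shape_pca(models)
        assert len(model.eigenvalues) == 1
        assert model.contribution_ratio[0] == pytest.approx(100.0)

    def test_matches_dense_covariance_eigendecomposition(self):
        models = _toy_models(n=5, n_vertices=4, seed=1)
        model = fit_shape_pca(models)
        x = np.stack([m.vertices.ravel() for m in models])
        xc = x - x.mean(axis=0)
        cov = xc.T @ xc / len(models)  # divisor n
        dense = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(
            model.eigenvalues, dense[: len(model.eigenvalues)], atol=1e-9
        )
        assert model.total_variance == pytest.approx(np.trace(cov), abs=1e-9)

    def test_scores_are_centered_projections(self):
        models = _toy_models(n=6, seed=2)
        model = fit_shape_pca(models)
        assert np.abs(model.scores.mean(axis=0)).max() < 1e-6 * model.scores.std()
        x0 = models[0].vertices.ravel() - model.mean_shape
        np.testing.assert_allclose(
            model.scores[0], model.eigenvectors @ x0, atol=1e-9
        )

    def test_display_threshold_filters_by_cr(self, upper_model):
        model, _ = upper_model
        displayed = model.displayed
        assert np.all(model.contribution_ratio[displayed] >= 1.0)
        hidden = np.setdiff1d(np.arange(len(model.eigenvalues)), displayed)
        assert np.all(model.contribution_ratio[hidden] < 1.0)

    def test_eigenvector_orthonormality(self, upper_model):
        model, _ = upper_model
        vt = model.eigenvectors
        np.testing.assert_allclose(vt @ vt.T, np.eye(len(vt)), atol=1e-8)

    def test_ccr_consistency(self, upper_model):
        model, _ = upper_model
        m = model.n_displayed
        expected = 100.0 * model.eigenvalues[:m].sum() / model.total_variance
        assert model.cumulative_cr[m - 1] == pytest.approx(expected, abs=1e-9)
        assert np.all(np.diff(model.cumulative_cr) >= -1e-12)
        assert model.cumulative_cr[-1] <= 100.0 + 1e-9

    def test_scale_invariance_of_cr(self):
        models = _toy_models(n=6, seed=4)
        c = 2.5
        scaled = [
            _hm(c * m.vertices, m.faces, m.meta.subject_id, m.meta.age)
            for m in models
        ]
        a = fit_shape_pca(models)
        b = fit_shape_pca(scaled)
        np.testing.assert_allclose(b.eigenvalues, c**2 * a.eigenvalues, rtol=1e-9)
        np.testing.assert_allclose(
            b.contribution_ratio, a.contribution_ratio, atol=1e-9
        )


class TestSynthesize:
    def test_zero_scores_give_mean(self, upper_model):
        model, _ = upper_model
        mesh = synthesize(model, {})
        np.testing.assert_array_equal(
            mesh.vertices.ravel(), model.mean_shape
        )

    def test_projection_roundtrip(self, upper_model):
        model, _ = upper_model
        amp = 3.0 * model.sd(0)
        mesh = synthesize(model, {0: amp})
        scores = project_scores(model, mesh.vertices)
        expected = np.zeros(len(model.eigenvalues))
        expected[0] = amp
        np.testing.assert_allclose(scores, expected, atol=1e-9)

    def test_linearity(self, upper_model):
        model, _ = upper_model
        a = synthesize(model, {0: 5.0}).vertices
        b = synthesize(model, {1: -2.0}).vertices
        ab = synthesize(model, {0: 5.0, 1: -2.0}).vertices
        np.testing.assert_allclose(
            a + b - model.mean_shape.reshape(-1, 3), ab, atol=1e-9
        )

    def test_reconstruction_of_specimen(self, upper_model):
        model, aligned = upper_model
        scores = dict(enumerate(model.scores[3]))
        mesh = synthesize(model, scores)
        np.testing.assert_allclose(mesh.vertices, aligned[3].vertices, atol=1e-6)

    def test_unknown_component_rejected(self, upper_model):
        model, _ = upper_model
        with pytest.raises(MeshValidationError):
            synthesize(model, {len(model.eigenvalues) + 5: 1.0})


class TestCovariateCorrelation:
    def test_degenerate_ages_not_available(self):
        models = _toy_models(n=6, seed=5)
        model = fit_shape_pca(models)
        r = score_covariate_correlation(model, np.full(6, 40.0))
        assert np.all(np.isnan(r))

    def test_recovers_injected_age_link(self, recovery_cohort):
        _, _, models = recovery_cohort
        aligned, _ = generalized_procrustes(models)
        model = fit_shape_pca(aligned)
        ages = np.array([m.meta.age for m in models])
        r = np.abs(score_covariate_correlation(model, ages)[:3])
        hits = np.nonzero((r >= 0.4) & (r <= 0.6))[0]
        assert len(hits) == 1
        others = np.delete(r, hits)
        assert np.all(others < 0.15)

    def test_permuted_ages_near_null(self, recovery_cohort):
        _, _, models = recovery_cohort
        model = fit_shape_pca(models)
        ages = np.array([m.meta.age for m in models])
        rng = np.random.default_rng(6)
        r = score_covariate_correlation(model, rng.permutation(ages))
        assert np.nanmax(np.abs(r[:3])) < 0.15


class TestPersistence:
    def test_roundtrip(self, tmp_path, upper_model):
        model, _ = upper_model
        save_shape_model(model, tmp_path / "m")
        back = load_shape_model(tmp_path / "m")
        np.testing.assert_allclose(back.eigenvalues, model.eigenvalues, rtol=1e-10)
        np.testing.assert_allclose(back.mean_shape, model.mean_shape, rtol=1e-10)
        np.testing.assert_allclose(
            back.eigenvectors, model.eigenvectors, rtol=1e-8, atol=1e-12
        )
        assert back.n_specimens == model.n_specimens
        np.testing.assert_array_equal(back.faces, model.faces)
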