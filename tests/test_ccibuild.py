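"""Composite images, second-stage PCA, and CCI derivation."""

import numpy as np
import pytest

import auriclass as ac
from auriclass.ccibuild import (
    cci_set_distance,
    derive_ccis,
    make_composite_images,
    roman,
    second_stage_pca,
)
from auriclass.meshkit import MeshValidationError
from auriclass.shapespace import fit_shape_pca, project_scores, synthesize


@pytest.fixture(scope="module")
def ci_model(upper_model):
    model, _ = upper_model
    cis = make_composite_images(model, 5, 100.0)
    return model, cis, second_stage_pca(cis)


class TestCompositeImages:
    @pytest.mark.parametrize("k", range(1, 9))
    def test_count_formula(self, upper_model, k):
        model, _ = upper_model
        if k > model.n_displayed:
            pytest.skip("needs more displayed components than available")
        cis = make_composite_images(model, k, 50.0)
        expected = 2 * k + 4 * (k * (k - 1) // 2)
        assert len(cis) == expected

    def test_k5_amp100_gives_fifty(self, ci_model):
        _, cis, _ = ci_model
        assert len(cis) == 50
        singles = [c for c in cis if len(c.provenance) == 1]
        pairs = [c for c in cis if len(c.provenance) == 2]
        assert len(singles) == 10 and len(pairs) == 40

    def test_k1_gives_plus_minus_syntheses(self, upper_model):
        model, _ = upper_model
        cis = make_composite_images(model, 1, 70.0)
        assert len(cis) == 2
        np.testing.assert_allclose(
            cis[0].mesh.vertices, synthesize(model, {0: -70.0}).vertices
        )
        np.testing.assert_allclose(
            cis[1].mesh.vertices, synthesize(model, {0: +70.0}).vertices
        )

    def test_cis_lie_in_model_span(self, ci_model):
        model, cis, _ = ci_model
        for ci in cis[:6]:
            scores = project_scores(model, ci.mesh.vertices)
            recon = model.mean_shape + scores @ model.eigenvectors
            resid = np.abs(recon - ci.mesh.vertices.ravel()).max()
            assert resid < 1e-9

    def test_invalid_requests_rejected(self, upper_model):
        model, _ = upper_model
        with pytest.raises(MeshValidationError):
            make_composite_images(model, model.n_displayed + 1, 100.0)
        with pytest.raises(MeshValidationError):
            make_composite_images(model, 2, 0.0)


class TestSecondStagePCA:
    def test_rank_one_source_gives_single_component(self, upper_model):
        model, _ = upper_model
        cis = make_composite_images(model, 1, 100.0)
        ci_pca = second_stage_pca(cis)
        assert len(ci_pca.eigenvalues) == 1

    def test_symmetric_grid_scores_have_zero_mean(self, ci_model):
        _, _, ci_pca = ci_model
        assert np.abs(ci_pca.scores.mean(axis=0)).max() < 1e-9

    def test_matches_dense_covariance_on_toy_set(self, upper_model):
        model, _ = upper_model
        cis = make_composite_images(model, 2, 40.0)  # 10 CIs
        ci_pca = second_stage_pca(cis)
        x = np.stack([c.mesh.vertices.ravel() for c in cis])
        xc = x - x.mean(axis=0)
        dense = np.sort(np.linalg.eigvalsh(xc.T @ xc / len(cis)))[::-1]
        np.testing.assert_allclose(
            ci_pca.eigenvalues, dense[: len(ci_pca.eigenvalues)], atol=1e-6
        )


class TestDeriveCCIs:
    def test_ten_ccis_from_five_pcs(self, ci_model):
        _, _, ci_pca = ci_model
        ccis = derive_ccis(ci_pca, 5, 100.0, "upper_auricle")
        assert len(ccis.ccis) == 10
        assert ccis.labels == [roman(i) for i in range(1, 11)]

    def test_twelve_ccis_from_six_pcs(self, uppers414, models414):
        from auriclass.homofit import split_regions

        lobules = [split_regions(m)[1] for m in models414]
        aligned, _ = ac.generalized_procrustes(lobules)
        model = fit_shape_pca(aligned)
        cis = make_composite_images(model, 6, 60.0)
        assert len(cis) == 72
        ci_pca = second_stage_pca(cis)
        ccis = derive_ccis(ci_pca, 6, 30.0, "lobule")
        assert len(ccis.ccis) == 12

    def test_cci_pair_reflects_through_mean(self, ci_model):
        _, _, ci_pca = ci_model
        ccis = derive_ccis(ci_pca, 3, 100.0, "upper_auricle")
        for j in range(3):
            lo = ccis.ccis[2 * j][1].vertices
            hi = ccis.ccis[2 * j + 1][1].vertices
            np.testing.assert_allclose(
                lo + hi, 2.0 * ci_pca.mean_shape.reshape(-1, 3), atol=1e-9
            )

    def test_nonpositive_amplitude_rejected(self, ci_model):
        _, _, ci_pca = ci_model
        with pytest.raises(MeshValidationError):
            derive_ccis(ci_pca, 2, -5.0, "upper_auricle")


class TestCCISetDistance:
    def test_identical_sets_distance_zero(self, ci_model):
        _, _, ci_pca = ci_model
        ccis = derive_ccis(ci_pca, 4, 100.0, "upper_auricle")
        d = cci_set_distance(ccis, ccis)
        assert d["max"] == pytest.approx(0.0, abs=1e-12)

    def test_sign_flip_absorbed_by_matching(self, ci_model):
        _, _, ci_pca = ci_model
        a = derive_ccis(ci_pca, 4, 100.0, "upper_auricle")
        flipped = derive_ccis(ci_pca, 4, 100.0, "upper_auricle")
        flipped.ccis = [
            (lab, mesh, prov)
            for (lab, _, prov), (_, mesh, _) in zip(
                flipped.ccis,
                [flipped.ccis[i ^ 1] for i in range(len(flipped.ccis))],
            )
        ]
        d = cci_set_distance(a, flipped)
        assert d["max"] == pytest.approx(0.0, abs=1e-12)

    def test_half_cohort_stability(self, uppers414):
        halves = (uppers414[:207], uppers414[207:])
        sets = []
        for half in halves:
            aligned, _ = ac.generalized_procrustes(half)
            model = fit_shape_pca(aligned)
            cis = make_composite_images(model, 5, 100.0)
            sets.append(
                derive_ccis(second_stage_pca(cis), 5, 100.0, "upper_auricle")
            )
        d = cci_set_distance(sets[0], sets[1])
        diag = np.linalg.norm(
            uppers414[0].vertices.max(axis=0) - uppers414[0].vertices.min(axis=0)
        )
        assert d["mean"] < 0.10 * diag

    def test_count_mismatch_rejected(self, ci_model):
        _, _, ci_pca = ci_model
        a = derive_ccis(ci_pca, 2, 100.0, "upper_auricle")
        b = derive_ccis(ci_pca, 3, 100.0, "upper_auricle")
        with pytest.raises(MeshValidationError):
            cci_set_distance(a, b)


def test_roman_labels():
    assert [roman(i) for i in (1, 4, 9, 12)] == ["I", "IV", "IX", "XII"]
    with pytest.raises(ValueError):
        roman(0)
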