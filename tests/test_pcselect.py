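"""DBV statistic and component-selection criteria."""

import numpy as np
import pytest

import auriclass as ac
from auriclass.meshkit import MeshValidationError
from auriclass.pcselect import (
    dbv,
    dbv_per_pc,
    ev_threshold_select,
    scree_elbow,
    shape_change_mask,
    shape_change_overlap,
    subset_sweep,
)
from auriclass.shapespace import ShapeModel

from reference_tables import LOBULE_EV, UPPER_AURICLE_EV


class TestDBV:
    def test_identical_meshes_zero(self, template):
        assert dbv(template, template) == 0.0

    def test_uniform_translation_exact(self, template):
        moved = template.with_vertices(template.vertices + [3.0, 0.0, 0.0])
        assert dbv(template, moved) == pytest.approx(3.0, abs=1e-12)
        assert dbv(template, moved, "max") == pytest.approx(3.0, abs=1e-12)

    def test_matches_bruteforce_loop(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3))
        expected = sum(
            float(np.sqrt(((a[i] - b[i]) ** 2).sum())) for i in range(50)
        ) / 50
        assert dbv(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry_and_nonnegativity(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=(2, 30, 3))
        assert dbv(a, b) == dbv(b, a) >= 0

    def test_triangle_inequality_mean_statistic(self):
        rng = np.random.default_rng(14)
        a, b, c = rng.normal(size=(3, 40, 3))
        assert dbv(a, c) <= dbv(a, b) + dbv(b, c) + 1e-12

    def test_mismatched_counts_rejected(self):
        with pytest.raises(MeshValidationError):
            dbv(np.zeros((4, 3)), np.zeros((5, 3)))


class TestEVThreshold:
    def test_reference_upper_spectrum_crosses_at_six(self):
        assert ev_threshold_select(UPPER_AURICLE_EV, 500.0) == 6

    def test_reference_lobule_spectrum_crosses_at_six(self):
        assert ev_threshold_select(LOBULE_EV, 100.0) == 6

    def test_threshold_above_largest_gives_zero(self):
        assert ev_threshold_select(UPPER_AURICLE_EV, 1e6) == 0

    def test_monotone_in_threshold(self):
        counts = [
            ev_threshold_select(UPPER_AURICLE_EV, thr)
            for thr in (50, 150, 300, 500, 800, 1200)
        ]
        assert counts == sorted(counts, reverse=True)


class TestScreeElbow:
    def test_elbow_before_big_drop(self):
        assert scree_elbow([100.0, 90.0, 10.0, 9.0, 8.0]) == 2

    def test_geometric_decay_still_defined(self):
        ev = [100.0 * 0.5**k for k in range(8)]
        m = scree_elbow(ev)
        assert 1 <= m <= 6

    def test_spiked_spectrum_recovers_k(self):
        # 4 strong components over a weak flat noise floor
        ev = [100.0, 64.0, 36.0, 25.0] + [0.4] * 20
        assert scree_elbow(ev) == 4

    def test_needs_three_values(self):
        with pytest.raises(MeshValidationError):
            scree_elbow([2.0, 1.0])


class TestDBVPerPC:
    def test_closed_form(self, upper_model):
        model, _ = upper_model
        report = dbv_per_pc(model, upto=4)
        for k in range(4):
            phi = model.eigenvectors[k].reshape(-1, 3)
            closed = 6.0 * model.sd(k) * np.linalg.norm(phi, axis=1).mean()
            assert report.values[k] == pytest.approx(closed, abs=1e-9)

    def test_scaling_eigenvalues_scales_dbv(self, upper_model):
        model, _ = upper_model
        doubled = ShapeModel(
            mean_shape=model.mean_shape,
            eigenvalues=4.0 * model.eigenvalues,
            eigenvectors=model.eigenvectors,
            contribution_ratio=model.contribution_ratio,
            cumulative_cr=model.cumulative_cr,
            scores=model.scores,
            total_variance=4.0 * model.total_variance,
            n_specimens=model.n_specimens,
            faces=model.faces,
        )
        a = dbv_per_pc(model, upto=3).values
        b = dbv_per_pc(doubled, upto=3).values
        np.testing.assert_allclose(b, 2.0 * a, rtol=1e-9)

    def test_zero_eigenvalue_gives_zero(self, upper_model):
        model, _ = upper_model
        zeroed = ShapeModel(
            mean_shape=model.mean_shape,
            eigenvalues=np.zeros_like(model.eigenvalues),
            eigenvectors=model.eigenvectors,
            contribution_ratio=model.contribution_ratio,
            cumulative_cr=model.cumulative_cr,
            scores=model.scores,
            total_variance=model.total_variance,
            n_specimens=model.n_specimens,
            faces=model.faces,
        )
        assert np.all(dbv_per_pc(zeroed, upto=2).values == 0.0)


class TestShapeChangeOverlap:
    def test_self_overlap_is_one(self, upper_model):
        model, _ = upper_model
        assert shape_change_overlap(model, model, 0) == 1.0

    def test_mask_respects_threshold(self, upper_model):
        model, _ = upper_model
        m = shape_change_mask(model, 0)
        assert np.all(m.displacement[m.mask] >= m.threshold)

    def test_disjoint_masks_give_zero_dice(self):
        # two rank-1 models whose components move disjoint vertices
        n = 6
        faces = np.array([[0, 1, 2]])
        mean = np.zeros(3 * n)
        va = np.zeros(3 * n)
        va[0] = 1.0
        vb = np.zeros(3 * n)
        vb[-1] = 1.0

        def rank1(vec):
            return ShapeModel(
                mean_shape=mean,
                eigenvalues=np.array([4.0]),
                eigenvectors=vec[None, :],
                contribution_ratio=np.array([100.0]),
                cumulative_cr=np.array([100.0]),
                scores=np.zeros((2, 1)),
                total_variance=4.0,
                n_specimens=2,
                faces=faces,
            )

        assert shape_change_overlap(rank1(va), rank1(vb), 0, 0.5) == 0.0

    def test_overlapping_subsets_stable_for_pc1(self, uppers414):
        res = subset_sweep(uppers414, sizes=[300, 363], seed=3)
        assert shape_change_overlap(res[0].model, res[1].model, 0) >= 0.8


class TestSubsetSweep:
    def test_default_sizes_follow_study_ladder(self, uppers414):
        res = subset_sweep(uppers414, sizes=[123, 242, 300, 363, 414], seed=3)
        assert [r.size for r in res] == [123, 242, 300, 363, 414]

    def test_subsets_are_nested(self, uppers414):
        res = subset_sweep(uppers414, sizes=[123, 242, 300], seed=3)
        for small, big in zip(res, res[1:]):
            assert np.all(np.isin(small.indices, big.indices))

    def test_full_size_equals_direct_pipeline(self, uppers414, upper_model):
        res = subset_sweep(uppers414, sizes=[len(uppers414)], seed=3)
        model, _ = upper_model
        np.testing.assert_allclose(
            res[0].model.eigenvalues, model.eigenvalues, rtol=1e-9
        )

    def test_oversized_subset_rejected(self, uppers414):
        with pytest.raises(MeshValidationError):
            subset_sweep(uppers414, sizes=[len(uppers414) + 1], seed=3)
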