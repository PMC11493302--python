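"""Shared fixtures: templates and synthetic cohorts reused across tests."""

import numpy as np
import pytest

import auriclass as ac
from auriclass.homofit import HomologousModel, split_regions
from auriclass.meshkit import mirror_mesh


@pytest.fixture(scope="session")
def template():
    return ac.make_template(0, seed=1)


def _as_homologous(subjects, template):
    """Un-mirror right sides and wrap as homologous models (generator
    output shares the template's vertex order when jitter is off)."""
    out = []
    for s in subjects:
        mesh = s.mesh if s.meta.side == "left" else mirror_mesh(s.mesh, "yz")
        out.append(
            HomologousModel(
                s.meta, mesh.vertices, template.faces, template.region_labels
            )
        )
    return out


@pytest.fixture(scope="session")
def cohort414(template):
    """Demo-scale analogue of the 218 left + 196 right study cohort."""
    spec = ac.default_cohort_spec(seed=1)
    return ac.sample_population(spec, template)


@pytest.fixture(scope="session")
def models414(cohort414, template):
    return _as_homologous(cohort414, template)


@pytest.fixture(scope="session")
def uppers414(models414):
    return [split_regions(m)[0] for m in models414]


@pytest.fixture(scope="session")
def upper_model(uppers414):
    aligned, _ = ac.generalized_procrustes(uppers414)
    return ac.fit_shape_pca(aligned), aligned


@pytest.fixture(scope="session")
def recovery_cohort(template):
    """n=500 single-side cohort with K=3 modes and an age-linked mode."""
    spec = ac.PopulationSpec(
        n_subjects=500,
        side_plan=["left"] * 500,
        n_modes=3,
        mode_sd=(6.0, 4.0, 3.0),
        vertex_noise_sd=0.1,
        age_linked_mode=(2, 0.5),
        seed=7,
    )
    subjects = ac.sample_population(spec, template)
    models = _as_homologous(subjects, template)
    return spec, subjects, models
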