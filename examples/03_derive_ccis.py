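"""Derive classification criterion images (CCIs) for both ear regions.

Synthesises the composite-image grid over the leading PCs (50 CIs for the
upper auricle at +/-100, 72 for the lobule at +/-60), reduces each set by
a second-stage PCA, and takes the +/-amplitude shapes of its leading
components as the CCI prototypes (10 and 12 respectively).
"""

import auriclass as ac
from auriclass.homofit import HomologousModel, split_regions
from auriclass.meshkit import mirror_mesh

template = ac.make_template(0, seed=1)
cohort = ac.sample_population(ac.default_cohort_spec(seed=1), template)
models = []
for s in cohort:
    mesh = s.mesh if s.meta.side == "left" else mirror_mesh(s.mesh, "yz")
    models.append(HomologousModel(s.meta, mesh.vertices, template.faces,
                                  template.region_labels))

for region_index, (region, k, ci_amp, cci_amp) in enumerate(
    [("upper_auricle", 5, 100.0, 100.0), ("lobule", 6, 60.0, 30.0)]
):
    subs = [split_regions(m)[region_index] for m in models]
    aligned, _ = ac.generalized_procrustes(subs)
    model = ac.fit_shape_pca(aligned)
    cis = ac.make_composite_images(model, k, ci_amp)
    ci_model = ac.second_stage_pca(cis)
    ccis = ac.derive_ccis(ci_model, k, cci_amp, region, ci_amplitude=ci_amp)
    print(f"{region}: k={k} -> {len(cis)} CIs -> {len(ccis.ccis)} CCIs "
          f"labelled {ccis.labels[0]}..{ccis.labels[-1]} at +/-{cci_amp:g}")
# Each CCI is a full prototype mesh; the pair of one second-stage PC are
# mirror images through the CI mean shape.
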