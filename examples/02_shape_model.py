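"""Build the upper-auricle shape model and choose how many PCs matter.

Runs generalized Procrustes alignment and coordinate PCA over the
upper-auricle sub-models of a synthetic cohort, then applies the three
component-selection criteria: the EV table, the scree elbow, and the DBV
of the -3 SD / +3 SD shape pair per component.
"""

import numpy as np

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
uppers = [split_regions(m)[0] for m in models]

aligned, mean = ac.generalized_procrustes(uppers)
model = ac.fit_shape_pca(aligned)

print(f"{model.n_specimens} specimens, {model.n_displayed} PCs displayed "
      f"(CR >= {model.display_cr_threshold}%)")
print("PC   EV      CR(%)  CCR(%)")
for k in range(min(8, model.n_displayed)):
    print(f"{k + 1:<4d}{model.eigenvalues[k]:<8.1f}"
          f"{model.contribution_ratio[k]:<7.1f}{model.cumulative_cr[k]:.1f}")

# the three selection criteria; a large DBV means the component visibly
# moves the surface between its -3 SD and +3 SD shapes
print("scree elbow:", ac.scree_elbow(model.eigenvalues))
report = ac.dbv_per_pc(model, upto=8)
print("DBV(-3SD,+3SD) per PC (mm):", np.round(report.values, 2))
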