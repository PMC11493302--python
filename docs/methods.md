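# Methods

## Data model and units

All geometry is in millimetres. A `TriangleMesh` carries vertices, faces,
optionally a registry of 18 named landmarks and per-vertex region labels
(`upper_auricle` / `lobule`). STL/PLY/OBJ carry no attributes, so
landmarks and labels travel in a JSON sidecar (`<mesh>.landmarks.json`),
0-based indices throughout. STL is an unindexed triangle soup: round-trips
through STL preserve the triangle set but not vertex indexing; PLY or OBJ
should be used when correspondence must survive file I/O.

Only three of the 18 landmark names are anatomically fixed by the
upper-auricle/lobule boundary definition (cauda helicis, incisura
intertragica, otobasion inferius); the remaining 15 follow standard
auricular anatomy but their exact placement is a package convention.

## Synthetic template and cohort

The template is a parametric sheet over (u, v) ∈ [0,1]²: an egg-shaped
outline (width profile narrowing toward the lobule), with relief built
from a helix-like rim ridge along the top and sides, a concha-like
depression, a triangular-fossa hollow, a lobule bulge, and a low-amplitude
seeded Fourier detail field. Height 62 mm, width 34 mm — typical adult
auricle proportions. Landmarks sit on fixed parametric grid vertices;
vertices with v < 0.22 form the lobule region (~28 % of the sheet).

Three resolutions are packaged (600, 2 400, and 5 507 vertices). The
highest level reproduces the reference template's exact counts of 5 507
vertices and 16 521 faces. Because 16 521 = 3 × 5 507 exceeds the Euler
bound F < 2V for any manifold triangulation, the face count at that level
is reached by deterministic centroid splits (vertex count) followed by a
run of coincident reversed-winding duplicate faces, as surface-render
exports commonly contain. Duplicate faces move no vertex and are invisible
to every vertex-wise statistic (DBV, PCA, masks); the default working
resolution is 600 vertices, where no such adjustment is applied.

Cohorts follow shape_i = template + Σ_k z_ik·φ_k + ε, with z_ik ~
N(0, sd_k²) per subject and ε i.i.d. Gaussian per coordinate. The modes
φ_k are Gaussian fields smoothed over the mesh graph, projected off the
template's 7-dimensional similarity subspace (translations, linearised
rotations, scaling) and orthonormalised. The projection makes them pure
shape deformations: Procrustes standardisation cannot absorb them, which
is what makes the mode subspace identifiable from the aligned PCA
(recovery tests find principal angles < 5° at n ≥ 10K). Because PCA is
only rotation-identifiable within equal-eigenvalue groups, recovery is
asserted on subspaces, never on individual vectors.

Defaults are chosen to emulate the study conditions at desk scale: 228
subjects (186 bilateral, 32 left-only, 10 right-only — the unique split
giving 218 left + 196 right = 414 ear images and 186 bilateral subjects),
ages uniform on 17–93, K = 10 modes with SDs 12…3 (a graded spectrum so
both regions display ≥ 6 components at CR ≥ 1 %), vertex noise 0.3 mm,
and a 0.5 mm left–right asymmetry perturbation. An optional age-linked
mode uses z = r·std(age) + √(1−r²)·noise rescaled, giving the requested
Pearson correlation in expectation. Right ears are mirrored across the yz
plane with face winding flipped.

What the generator does *not* emulate: anatomical detail beyond
qualitative ear-likeness, sex differences, scan artefacts (holes, hair,
topological noise), or non-Gaussian shape variation. Passing tests
therefore demonstrate the pipeline's correctness and stability on a
known-truth population of realistic scale and noise, not classification
accuracy on real ears.

## Template fitting

Pipeline: (1) Umeyama similarity Procrustes on the 18 landmark pairs;
(2) 3D thin-plate-spline warp (biharmonic kernel U(r) = r) interpolating
the residual landmark displacements, with kernel-diagonal regularisation
λ = 10⁻³ × target bounding-box diagonal; (3) exact nearest-point
projection of each warped vertex onto the target surface; (4) optionally,
rounds of Laplacian relaxation blended with re-projection.

Projection uses a cKDTree over triangle centroids (16 candidates) with the
exact barycentric point-to-triangle distance; distance ties break to the
lowest face index, so fitting is fully deterministic. Relaxation defaults
to **zero iterations**: on clean targets projection alone is exact (a
similarity-transformed copy of the template is recovered to machine
precision, and fitting is rigid-equivariant), whereas relaxation
introduces tangential drift that trades that exactness for smoother
correspondence. It is worth enabling (1–3 iterations, weight 0.5) on
re-triangulated or noisy targets, where it repairs collapsed
correspondences (the triangle aspect-ratio degradation drops sharply from
iteration 0 to 1).

`fit_residual` is the mean vertex-to-surface distance after the final
step; with relaxation off and projection on it is numerically zero, so it
is informative mainly when relaxation is enabled or targets are degenerate.

Region splitting assigns each face to the region holding ≥ 2 of its
vertices (an exact tie is impossible for triangles). The labelled vertex
sets partition the template exactly; each sub-model additionally carries
the few boundary vertices of the other label referenced by its majority
faces, appended after the core block, so straddling faces remain
representable. The index maps are functions of the template labels only
and hence identical across subjects.

## Shape space

GPA: iterative similarity alignment to the evolving mean, stopping when
the mean moves < 10⁻⁸ × its bounding-box diagonal (max 100 iterations);
the mean is centred at the origin and, with scaling, every aligned shape's
centroid size is pinned to the mean's. PCA is computed by SVD of the
centred n × 3N matrix — never the explicit 3N × 3N covariance — with
eigenvalues under the population convention (divisor n; `ddof=1` is a
switch). Eigenvector signs are fixed so the largest-magnitude entry is
positive, making outputs backend-independent. Eigenvalues below
10⁻¹² × EV₁ are discarded as numerical rank padding. CR/CCR are reported
at 0.1 % precision and correlations with age at 0.01, matching
conventional table formatting; zero-variance covariates yield NaN.

## Component selection

* `ev_threshold_select`: largest m with EV_m ≥ threshold. On the published
  reference spectra this crosses exactly at PC6 with thresholds 500
  (upper auricle) and 100 (lobule).
* `scree_elbow`: interior index maximising the discrete second difference
  of the EV curve, returned as that index minus one ("immediately before
  the bend"); ties break low. With no pronounced elbow the rule still
  returns the largest-curvature index — scree reading is inherently
  visual, and the function is deliberately a reproducible approximation.
* `dbv_per_pc`: DBV of the ±3 SD shape pair per component; for the mean
  statistic this has the closed form 6·√EV_k·mean_i‖φ_k,i‖, used as the
  test oracle. Note DBV scales with √EV, not EV.
* Shape-change masks threshold each component's mean→+3 SD per-vertex
  displacement at its own 75th percentile (no absolute cutoff is published
  for the "red region" rendering; an absolute override exists). Dice
  overlap between cohorts is computed against both signs of the second
  model's component and the maximum kept, absorbing eigenvector sign
  ambiguity.
* `subset_sweep` draws nested age-stratified subsets (seven strata:
  17–29, 30–39, …, 80–93) at the classic 123/242/300/363/full ladder,
  scaled proportionally for smaller cohorts, and reruns GPA + PCA + all
  three criteria per subset.

## CIs and CCIs

CI amplitudes are raw PC scores (±100 upper auricle, ±60 lobule; CCIs at
±100 and ±30), not multiples of √EV — the grids are defined on raw-score
biplot axes. The symmetric grid makes the second-stage spectrum exactly
degenerate: every one of the first k second-stage eigenvalues equals
(2 + 4(k−1))·A²/n_CI, so the second-stage eigenvectors are an arbitrary
orthonormal basis of the first-stage span. This is harmless — the CCI
*set* is what matters, and `cci_set_distance` compares sets after a
Hungarian assignment on the pairwise DBV matrix, absorbing both the
rotation ambiguity and sign flips. The pipeline picks the second-stage
component count as min(k, displayed components); the scree elbow is
available for manual inspection but is not well defined on a degenerate
spectrum.

## Classification

Assignment is always the DBV-minimising CCI (ties break by label order);
any manual visual override among multiple under-threshold CCIs is left to
the examiner, who gets the full ranked under-threshold list. No published
numeric threshold exists, so the default is calibrated: the q-th
percentile (default 90) of the calibration cohort's minimum-DBV
distribution, which by construction leaves ≈ (100 − q) % out of
classification. Reports label the threshold as calibrated. Asymmetry is
computed per region over subjects with both sides present; an
out-of-classification side counts as differing from anything, including
another out-of-classification side.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through named
`SeedSequence` substreams; reruns of any stage, and of the whole pipeline,
are byte-identical. The test suite and examples run at the 600-vertex
resolution with cohorts of 24–1 000 meshes — sizes at which GPA + PCA on
414 specimens takes a few seconds — while the 5 507-vertex template is
exercised for its exact counts. The acceptance script uses a 60-subject
single-side cohort, sufficient for both regions to display the six
components its configuration requires.

## Known limitations

* The dense-correspondence recipe is a standard open reimplementation of
  an unpublished proprietary fitting step; it reproduces the data contract
  (fixed topology, shared vertex order), not that software's exact output.
* Nearest-point projection can collapse neighbouring template vertices
  onto the same target point on coarse or noisy targets; enable relaxation
  there.
* The synthetic cohort's classification statistics (multi-match rate,
  asymmetry rate) depend on the generator's mode spectrum and are not
  predictions for real cohorts.
* Landmark placement noise is not modelled; target landmarks are exact
  vertex positions, so fitting accuracy on real data (hand-placed
  landmarks) will be worse than the test figures.
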