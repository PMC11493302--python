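"""Synthetic ear-like template and cohort generator.

Real cohorts of CT-derived ear surfaces are not redistributable, so every
downstream stage (homologous fitting, shape-space PCA, component selection,
CCI derivation, classification) is exercised on meshes drawn from a known
generative model:

    shape = template + sum_k z_k * phi_k + noise

with smooth orthonormal deformation fields ``phi_k`` and per-subject latent
scores ``z_k ~ N(0, mode_sd_k^2)``.  Because the ground truth is known, the
tests can check parameter recovery (mode subspace, injected age correlation)
rather than only self-consistency.

The template is a parametric ear-shaped sheet: an egg-shaped outline, a
helix-like rim ridge running around the top and sides, a concha-like
central depression and a lobule-like lower lobe, with 18 landmarks at fixed
parametric locations and per-vertex upper-auricle/lobule labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._geometry import laplacian_smooth, vertex_adjacency
from .meshkit import (
    LANDMARK_NAMES,
    REGION_LOBULE,
    REGION_UPPER,
    MeshValidationError,
    SubjectMeta,
    TriangleMesh,
    mirror_mesh,
)

__all__ = [
    "PopulationSpec",
    "SyntheticSubject",
    "make_template",
    "make_modes",
    "sample_population",
    "default_cohort_spec",
    "landmark_vertex_indices",
    "MAX_RESOLUTION",
]

# grid (rows along height, cols across width) per subdivision level; the
# highest level is adjusted to the reference template's exact vertex and
# face counts (5,507 / 16,521)
_GRID = {0: (25, 24), 1: (50, 48), 2: (75, 73)}
MAX_RESOLUTION = 2
_FULL_COUNTS = (5507, 16521)

#: parametric (u, v) landmark chart; u across the ear width, v up its
#: height.  v = _LOBULE_V is the cauda helicis / incisura intertragica /
#: otobasion inferius line that separates the lobule from the upper auricle.
_LOBULE_V = 0.22
_LANDMARK_UV = {
    "superaurale": (0.50, 1.00),
    "subaurale": (0.50, 0.00),
    "preaurale": (0.02, 0.55),
    "postaurale": (0.98, 0.55),
    "otobasion_superius": (0.04, 0.80),
    "otobasion_inferius": (0.10, _LOBULE_V),
    "tragion": (0.20, 0.42),
    "antitragion": (0.42, 0.30),
    "incisura_intertragica": (0.32, _LOBULE_V),
    "cauda_helicis": (0.78, _LOBULE_V),
    "helix_root": (0.25, 0.62),
    "helix_apex": (0.55, 0.97),
    "helix_posterior": (0.93, 0.70),
    "antihelix_apex": (0.62, 0.70),
    "crus_antihelicis": (0.45, 0.78),
    "concha_center": (0.40, 0.52),
    "fossa_triangularis": (0.38, 0.85),
    "lobule_apex": (0.55, 0.06),
}
assert set(_LANDMARK_UV) == set(LANDMARK_NAMES)

# overall scale (mm): an adult auricle is ~60 mm tall and ~35 mm wide
_HEIGHT = 62.0
_WIDTH = 34.0


def _relief(u: np.ndarray, v: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Out-of-plane (x) relief in mm: helix rim, concha hollow, lobule lobe."""
    # distance to the rim in parameter space; the helix wraps top and sides
    d_rim = np.minimum.reduce([u, 1.0 - u, 1.0 - v])
    helix = 4.0 * np.exp(-((d_rim - 0.06) / 0.05) ** 2) * (v > _LOBULE_V * 0.6)
    concha = -6.0 * np.exp(-(((u - 0.42) / 0.22) ** 2 + ((v - 0.52) / 0.16) ** 2))
    fossa = -2.5 * np.exp(-(((u - 0.40) / 0.14) ** 2 + ((v - 0.85) / 0.08) ** 2))
    lobule = 2.0 * np.exp(-(((u - 0.50) / 0.30) ** 2 + ((v - 0.08) / 0.12) ** 2))
    bowl = 3.0 * np.sin(np.pi * v) * np.sin(np.pi * u)
    # small seeded Fourier detail so distinct seeds give distinct templates
    detail = np.zeros_like(u)
    for _ in range(4):
        fu, fv = rng.integers(2, 6, size=2)
        pu, pv = rng.uniform(0, 2 * np.pi, size=2)
        detail += rng.uniform(0.2, 0.5) * np.sin(fu * np.pi * u + pu) * np.sin(
            fv * np.pi * v + pv
        )
    return helix + concha + fossa + lobule + bowl + detail


def _width_profile(v: np.ndarray) -> np.ndarray:
    """Half-width of the ear outline as a function of height; egg-shaped."""
    return 0.30 + 0.70 * np.sin(np.pi * np.clip(0.18 + 0.78 * v, 0.0, 1.0)) ** 0.8


def make_template(resolution: int = 0, seed: int = 0) -> TriangleMesh:
    """Build the ear-like template sheet at a given subdivision level.

    Levels 0..2 are supported; level 2 reproduces the reference template's
    5,507 vertices and 16,521 faces exactly.  The face count at level 2
    includes a deterministic run of coincident reversed-winding (double
    sided) triangles, as surface-render exports commonly contain; these do
    not move any vertex and are invisible to all vertex-wise statistics.
    """
    if resolution < 0:
        raise MeshValidationError("resolution must be >= 0")
    if resolution not in _GRID:
        raise MeshValidationError(
            f"unsupported resolution {resolution}; available: {sorted(_GRID)}"
        )
    rng = np.random.default_rng(seed)
    nv, nu = _GRID[resolution]
    vv, uu = np.meshgrid(
        np.linspace(0.0, 1.0, nv), np.linspace(0.0, 1.0, nu), indexing="ij"
    )
    u = uu.ravel()
    v = vv.ravel()
    x = _relief(u, v, rng)
    y = _HEIGHT * (v - 0.5)
    z = _WIDTH * _width_profile(v) * (u - 0.5)
    vertices = np.column_stack([x, y, z])

    # two triangles per grid quad, row-major
    idx = np.arange(nv * nu).reshape(nv, nu)
    q00 = idx[:-1, :-1].ravel()
    q01 = idx[:-1, 1:].ravel()
    q10 = idx[1:, :-1].ravel()
    q11 = idx[1:, 1:].ravel()
    faces = np.concatenate(
        [np.column_stack([q00, q01, q11]), np.column_stack([q00, q11, q10])]
    )
    order = np.argsort(
        np.concatenate([np.arange(len(q00)) * 2, np.arange(len(q00)) * 2 + 1])
    )
    faces = faces[order]

    labels = np.where(v < _LOBULE_V, REGION_LOBULE, REGION_UPPER).astype(object)

    if resolution == MAX_RESOLUTION:
        vertices, faces, labels = _adjust_counts(vertices, faces, labels)

    landmarks = {}
    for name, (lu, lv) in _LANDMARK_UV.items():
        i = int(round(lv * (nv - 1))) * nu + int(round(lu * (nu - 1)))
        landmarks[name] = vertices[i].copy()
    return TriangleMesh(vertices, faces, landmarks, labels)


def _adjust_counts(vertices, faces, labels):
    """Tune counts to the reference 5,507 / 16,521 by centroid splits then
    duplicate reversed faces (coincident; geometry unchanged)."""
    target_v, target_f = _FULL_COUNTS
    n_split = target_v - len(vertices)
    if n_split < 0:
        raise MeshValidationError("grid exceeds reference vertex count")
    new_vertices = [vertices]
    new_labels = list(labels)
    out_faces = []
    for fi, f in enumerate(faces):
        if fi < n_split:
            c = vertices[f].mean(axis=0)
            ci = len(vertices) + fi
            new_vertices.append(c[None, :])
            # centroid inherits the face's majority region label
            lab = [labels[j] for j in f]
            new_labels.append(max(set(lab), key=lambda s: (lab.count(s), s)))
            out_faces.extend([(f[0], f[1], ci), (f[1], f[2], ci), (f[2], f[0], ci)])
        else:
            out_faces.append(tuple(f))
    vertices = np.concatenate(new_vertices)
    faces = np.array(out_faces, dtype=np.int64)
    n_dup = target_f - len(faces)
    if n_dup < 0:
        raise MeshValidationError("split mesh exceeds reference face count")
    dup = faces[:n_dup, ::-1]
    faces = np.concatenate([faces, dup])
    return vertices, faces, np.array(new_labels, dtype=object)


def landmark_vertex_indices(mesh: TriangleMesh) -> dict[str, int]:
    """Vertex index realising each landmark (landmarks sit on vertices)."""
    if mesh.landmarks is None:
        raise MeshValidationError("mesh carries no landmarks")
    out = {}
    for name, p in mesh.landmarks.items():
        d = np.einsum("ij,ij->i", mesh.vertices - p, mesh.vertices - p)
        out[name] = int(np.argmin(d))
    return out


def make_modes(
    template: TriangleMesh, K: int, smoothness: int = 10, seed: int = 0
) -> np.ndarray:
    """K orthonormal, spatially smooth deformation fields, shape (K, 3N).

    Gaussian fields are smoothed by ``smoothness`` rounds of neighbour
    averaging over the mesh graph, projected off the template's similarity
    subspace (translations, linearised rotations, scaling) so they encode
    pure shape change that Procrustes standardisation cannot absorb, then
    orthonormalised (QR); the Gram matrix of the result is the identity to
    machine precision.
    """
    n = template.n_vertices
    if K < 1:
        raise MeshValidationError("K must be >= 1")
    if K > 3 * n - 7:
        raise MeshValidationError("K exceeds the 3N - 7 shape degrees of freedom")
    rng = np.random.default_rng(seed)
    adj = vertex_adjacency(n, template.faces)
    sim = _similarity_subspace(template.vertices)
    fields = np.empty((K, 3 * n))
    for k in range(K):
        f = rng.standard_normal((n, 3))
        f = laplacian_smooth(f, adj, iterations=smoothness).ravel()
        f = f - sim.T @ (sim @ f)
        fields[k] = f
    q, r = np.linalg.qr(fields.T)
    q = q * np.sign(np.diag(r))[None, :]
    return q.T


def _similarity_subspace(vertices: np.ndarray) -> np.ndarray:
    """Orthonormal basis (7, 3N) of infinitesimal similarity motions."""
    v = vertices - vertices.mean(axis=0)
    n = len(v)
    basis = []
    for ax in range(3):
        t = np.zeros((n, 3))
        t[:, ax] = 1.0
        basis.append(t.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        basis.append(np.cross(np.broadcast_to(e, v.shape), v).ravel())
    basis.append(v.ravel())
    q, _ = np.linalg.qr(np.stack(basis).T)
    return q.T


@dataclass
class PopulationSpec:
    """Conditions under which a synthetic cohort is drawn.

    ``side_plan`` is either a per-subject sequence of ``left`` / ``right`` /
    ``both``, or a float: the probability that a subject contributes both
    ears (remaining subjects split evenly left/right).
    """

    n_subjects: int = 228
    side_plan: Sequence[str] | float = 0.8
    n_modes: int = 10
    mode_sd: Sequence[float] = (12.0, 10.0, 8.0, 7.0, 6.0, 5.0, 4.5, 4.0, 3.5, 3.0)
    age_range: tuple[int, int] = (17, 93)
    age_linked_mode: tuple[int, float] | None = None
    asymmetry_sd: float = 0.5
    vertex_noise_sd: float = 0.3
    correspondence_jitter: str = "none"  # {"none", "resample"}
    resolution: int = 0
    mode_smoothness: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        self.mode_sd = tuple(float(s) for s in self.mode_sd)
        if len(self.mode_sd) != self.n_modes:
            raise MeshValidationError("mode_sd must have length n_modes")
        if any(s < 0 for s in self.mode_sd):
            raise MeshValidationError("mode_sd must be nonnegative")
        if self.age_linked_mode is not None:
            k, r = self.age_linked_mode
            if not 0 <= k < self.n_modes:
                raise MeshValidationError("age-linked mode index out of range")
            if not abs(r) < 1:
                raise MeshValidationError("|target correlation| must be < 1")
        if self.correspondence_jitter not in ("none", "resample"):
            raise MeshValidationError("correspondence_jitter: none|resample")


@dataclass
class SyntheticSubject:
    """One synthetic ear specimen with its generative ground truth."""

    meta: SubjectMeta
    mesh: TriangleMesh
    true_scores: np.ndarray
    true_region_labels: np.ndarray


def default_cohort_spec(seed: int = 0, **overrides) -> PopulationSpec:
    """Demo cohort emulating the study's 218 left + 196 right = 414 ears.

    228 subjects: 186 contribute both sides, 32 left only, 10 right only —
    the unique split matching the published side totals and the 186
    bilateral subjects used for the asymmetry statistic.
    """
    plan = ["both"] * 186 + ["left"] * 32 + ["right"] * 10
    base = dict(n_subjects=228, side_plan=plan, seed=seed)
    base.update(overrides)
    return PopulationSpec(**base)


def _resolve_side_plan(spec: PopulationSpec, rng: np.random.Generator) -> list[str]:
    if isinstance(spec.side_plan, (float, int)) and not isinstance(
        spec.side_plan, bool
    ):
        p = float(spec.side_plan)
        plan = []
        for _ in range(spec.n_subjects):
            if rng.random() < p:
                plan.append("both")
            else:
                plan.append("left" if rng.random() < 0.5 else "right")
        return plan
    plan = list(spec.side_plan)
    if len(plan) != spec.n_subjects:
        raise MeshValidationError("side_plan length must equal n_subjects")
    if set(plan) - {"left", "right", "both"}:
        raise MeshValidationError("side_plan entries must be left/right/both")
    return plan


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    return (x - x.mean()) / s if s > 0 else np.zeros_like(x)


def _jitter_topology(
    mesh: TriangleMesh, rng: np.random.Generator
) -> TriangleMesh:
    """Re-triangulate (centroid subdivision) and permute vertices so the
    target shares neither the template's vertex order nor its count."""
    v, f = mesh.vertices, mesh.faces
    centroids = v[f].mean(axis=1)
    ci = np.arange(len(f)) + len(v)
    newf = np.concatenate(
        [
            np.column_stack([f[:, 0], f[:, 1], ci]),
            np.column_stack([f[:, 1], f[:, 2], ci]),
            np.column_stack([f[:, 2], f[:, 0], ci]),
        ]
    )
    newv = np.concatenate([v, centroids])
    perm = rng.permutation(len(newv))
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return TriangleMesh(
        newv[perm], inv[newf], mesh.landmarks, None, mesh.landmark_names
    )


def sample_population(
    spec: PopulationSpec, template: TriangleMesh | None = None
) -> list[SyntheticSubject]:
    """Draw a cohort of ear meshes from the latent-mode generative model.

    Right-side specimens are mirrored copies of the subject's shape with an
    extra per-vertex asymmetry perturbation; each specimen additionally
    receives i.i.d. vertex noise.  Landmarks ride on their template
    vertices, so every specimen carries a full 18-landmark set.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0xA1]))
    if template is None:
        template = make_template(spec.resolution, seed=spec.seed)
    lm_idx = landmark_vertex_indices(template)
    modes = make_modes(
        template, spec.n_modes, smoothness=spec.mode_smoothness, seed=spec.seed
    )
    plan = _resolve_side_plan(spec, rng)

    n = spec.n_subjects
    ages = rng.integers(spec.age_range[0], spec.age_range[1] + 1, size=n)
    z = rng.standard_normal((n, spec.n_modes)) * np.array(spec.mode_sd)
    if spec.age_linked_mode is not None:
        k, r = spec.age_linked_mode
        raw = r * _standardize(ages.astype(float)) + np.sqrt(
            1 - r**2
        ) * _standardize(rng.standard_normal(n))
        z[:, k] = _standardize(raw) * spec.mode_sd[k]

    base = template.vertices
    subjects: list[SyntheticSubject] = []
    for i in range(n):
        shape = base + (z[i] @ modes).reshape(-1, 3)
        sides = ("left", "right") if plan[i] == "both" else (plan[i],)
        for side in sides:
            verts = shape.copy()
            if side == "right":
                verts = verts + spec.asymmetry_sd * rng.standard_normal(
                    verts.shape
                )
            verts = verts + spec.vertex_noise_sd * rng.standard_normal(verts.shape)
            lms = {nm: verts[j].copy() for nm, j in lm_idx.items()}
            mesh = TriangleMesh(
                verts, template.faces.copy(), lms, None, template.landmark_names
            )
            if side == "right":
                mesh = mirror_mesh(mesh, "yz")
            if spec.correspondence_jitter == "resample":
                mesh = _jitter_topology(mesh, rng)
            meta = SubjectMeta(f"S{i:04d}", side, int(ages[i]))
            subjects.append(
                SyntheticSubject(
                    meta, mesh, z[i].copy(), template.region_labels.copy()
                )
            )
    return subjects
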