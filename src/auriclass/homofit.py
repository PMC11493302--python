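"""Dense-correspondence template fitting and region splitting.

Every subject mesh is re-parameterised onto the template topology so that
vertex ``i`` means the same anatomical location on every specimen (the
"homologous model").  The fitting recipe is a standard landmark-guided
dense-correspondence pipeline:

1. similarity Procrustes alignment of the template onto the target using
   the 18 landmark pairs (Umeyama closed form);
2. a 3D thin-plate-spline warp (biharmonic kernel ``U(r) = r``)
   interpolating the residual landmark displacements, applied to all
   template vertices;
3. projection of each warped vertex to its exact nearest point on the
   target surface;
4. optionally, rounds of Laplacian relaxation blended with re-projection
   to regularise the correspondence on noisy or re-triangulated targets.

The output keeps the template's vertex order, faces and region labels, so
all downstream statistics operate on fixed-length coordinate vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._geometry import SurfaceProjector, laplacian_smooth, vertex_adjacency
from .meshkit import (
    REGION_LOBULE,
    REGION_UPPER,
    MeshValidationError,
    SubjectMeta,
    TriangleMesh,
)

__all__ = [
    "FitParams",
    "HomologousModel",
    "RegionSubmesh",
    "fit_template",
    "split_regions",
    "similarity_procrustes",
    "tps_warp",
]


@dataclass
class FitParams:
    """Tunable knobs of the template-fitting pipeline.

    ``tps_regularization`` is a fraction of the target bounding-box
    diagonal added to the TPS kernel diagonal (0 gives landmark-exact
    interpolation).  Relaxation is off by default: it trades landmark
    exactness for smoother correspondence and is only needed on targets
    that do not share the template's vertex order.
    """

    tps_regularization: float = 1e-3
    n_relax_iters: int = 0
    relax_weight: float = 0.5
    projection: str = "nearest_point_on_surface"

    def __post_init__(self) -> None:
        if not 0.0 <= self.relax_weight <= 1.0:
            raise MeshValidationError("relax_weight must lie in [0, 1]")
        if self.tps_regularization < 0:
            raise MeshValidationError("tps_regularization must be nonnegative")
        if self.projection != "nearest_point_on_surface":
            raise MeshValidationError("unknown projection mode")


@dataclass
class HomologousModel:
    """A fitted specimen in template vertex order.

    ``fit_residual`` is the mean distance (mm) from the fitted vertices to
    the target surface.
    """

    meta: SubjectMeta
    vertices: np.ndarray
    faces: np.ndarray
    region_labels: np.ndarray
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.fit_residual < 0:
            raise MeshValidationError("fit_residual must be >= 0")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    def as_mesh(self) -> TriangleMesh:
        return TriangleMesh(
            self.vertices.copy(), self.faces.copy(), None, self.region_labels.copy()
        )


@dataclass
class RegionSubmesh:
    """A region of a homologous model with its template index map.

    ``vertex_map`` holds, for every submesh vertex, its index in the parent
    template: first the ``n_core`` vertices labelled with this region (the
    region vertex sets partition the template), then any boundary vertices
    of the other label referenced by faces assigned to this region.  The
    map is a pure function of the template labels, hence identical across
    all subjects.
    """

    region: str
    vertex_map: np.ndarray
    faces: np.ndarray
    n_core: int = 0

    def extract(self, vertices: np.ndarray) -> np.ndarray:
        return np.asarray(vertices, float).reshape(-1, 3)[self.vertex_map]


def similarity_procrustes(
    source: np.ndarray, target: np.ndarray, allow_scaling: bool = True
) -> tuple[float, np.ndarray, np.ndarray]:
    """Least-squares similarity transform mapping source points to target.

    Returns ``(s, R, t)`` with ``x -> s * R @ x + t`` (Umeyama closed form;
    the rotation is proper, determinant +1).
    """
    src = np.asarray(source, float)
    tgt = np.asarray(target, float)
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    a = src - mu_s
    b = tgt - mu_t
    cov = b.T @ a / len(src)
    u, d, vt = np.linalg.svd(cov)
    sgn = np.eye(3)
    if np.linalg.det(u @ vt) < 0:
        sgn[2, 2] = -1.0
    rot = u @ sgn @ vt
    var_s = (a**2).sum() / len(src)
    scale = float(np.trace(np.diag(d) @ sgn) / var_s) if allow_scaling else 1.0
    t = mu_t - scale * rot @ mu_s
    return scale, rot, t


def tps_warp(
    control_src: np.ndarray,
    control_dst: np.ndarray,
    points: np.ndarray,
    regularization: float = 0.0,
) -> np.ndarray:
    """3D thin-plate-spline interpolation of control displacements.

    Uses the 3D biharmonic kernel ``U(r) = r``; with zero regularization
    the warp maps each control source exactly to its destination.
    """
    src = np.asarray(control_src, float)
    dst = np.asarray(control_dst, float)
    pts = np.asarray(points, float)
    m = len(src)
    k = np.linalg.norm(src[:, None, :] - src[None, :, :], axis=-1)
    k = k + regularization * np.eye(m)
    p = np.column_stack([np.ones(m), src])
    lhs = np.zeros((m + 4, m + 4))
    lhs[:m, :m] = k
    lhs[:m, m:] = p
    lhs[m:, :m] = p.T
    rhs = np.zeros((m + 4, 3))
    rhs[:m] = dst - src
    coef = np.linalg.solve(lhs, rhs)
    w, a = coef[:m], coef[m:]
    ker = np.linalg.norm(pts[:, None, :] - src[None, :, :], axis=-1)
    disp = ker @ w + np.column_stack([np.ones(len(pts)), pts]) @ a
    if not np.all(np.isfinite(disp)):
        raise FloatingPointError("non-finite coordinates after TPS warp")
    return pts + disp


def fit_template(
    template: TriangleMesh,
    target: TriangleMesh,
    target_landmarks: dict[str, np.ndarray] | None = None,
    params: FitParams | None = None,
    meta: SubjectMeta | None = None,
) -> HomologousModel:
    """Fit the template to one target mesh, producing a homologous model."""
    params = params or FitParams()
    if template.landmarks is None:
        raise MeshValidationError("template carries no landmarks")
    if target_landmarks is None:
        target_landmarks = target.landmarks
    if target_landmarks is None:
        raise MeshValidationError("target carries no landmarks")
    missing = set(template.landmark_names) - set(target_landmarks)
    if missing:
        raise MeshValidationError(f"target missing landmarks: {sorted(missing)}")

    src_lm = template.landmark_array()
    dst_lm = np.stack(
        [np.asarray(target_landmarks[n], float) for n in template.landmark_names]
    )

    s, rot, t = similarity_procrustes(src_lm, dst_lm)
    verts = s * template.vertices @ rot.T + t
    lm = s * src_lm @ rot.T + t

    lam = params.tps_regularization * target.bbox_diagonal()
    verts = tps_warp(lm, dst_lm, verts, regularization=lam)

    projector = SurfaceProjector(target.vertices, target.faces)
    verts, _ = projector.project(verts)

    if params.n_relax_iters > 0:
        adj = vertex_adjacency(template.n_vertices, template.faces)
        for _ in range(params.n_relax_iters):
            smoothed = laplacian_smooth(verts, adj, iterations=1)
            verts = (1 - params.relax_weight) * verts + params.relax_weight * smoothed
            verts, _ = projector.project(verts)

    residual = float(projector.distance(verts).mean())
    if meta is None:
        meta = SubjectMeta("unknown", "left", 0)
    return HomologousModel(
        meta, verts, template.faces.copy(), template.region_labels.copy(), residual
    )


def region_submeshes(
    faces: np.ndarray, region_labels: np.ndarray
) -> dict[str, RegionSubmesh]:
    """Partition a labelled topology into upper-auricle and lobule submeshes.

    Faces straddling the boundary go to the region holding at least two of
    their three vertices (an exact tie is impossible for triangles).
    """
    if region_labels is None:
        raise MeshValidationError("region labels are required to split")
    labels = np.asarray(region_labels, dtype=object)
    out: dict[str, RegionSubmesh] = {}
    for region in (REGION_UPPER, REGION_LOBULE):
        vmask = labels == region
        core = np.nonzero(vmask)[0]
        fsel = faces[vmask[faces].sum(axis=1) >= 2]  # majority rule
        # boundary vertices of the other label pulled in by assigned faces
        extra = np.setdiff1d(np.unique(fsel), core)
        vmap = np.concatenate([core, extra])
        reindex = -np.ones(len(labels), dtype=np.int64)
        reindex[vmap] = np.arange(len(vmap))
        out[region] = RegionSubmesh(region, vmap, reindex[fsel], len(core))
    return out


def split_regions(
    model: HomologousModel,
) -> tuple[HomologousModel, HomologousModel]:
    """Split a homologous model into (upper auricle, lobule) sub-models."""
    subs = region_submeshes(model.faces, model.region_labels)
    out = []
    for region in (REGION_UPPER, REGION_LOBULE):
        sub = subs[region]
        out.append(
            HomologousModel(
                model.meta,
                model.vertices[sub.vertex_map],
                sub.faces,
                model.region_labels[sub.vertex_map],
                model.fit_residual,
            )
        )
    return out[0], out[1]
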