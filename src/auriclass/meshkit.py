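"""Core mesh and landmark data types with file I/O.

A :class:`TriangleMesh` is the raw-surface currency of the pipeline:
vertex coordinates in millimetres, triangle faces, an optional registry of
18 named anatomical landmarks, and optional per-vertex region labels
(``upper_auricle`` / ``lobule``).  STL/PLY/OBJ files carry no attributes,
so landmarks and region labels travel in a JSON sidecar
(``<mesh>.landmarks.json``) written and read alongside the mesh file.
Vertex indexing is 0-based everywhere, including sidecars.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import trimesh

__all__ = [
    "LANDMARK_NAMES",
    "REGION_UPPER",
    "REGION_LOBULE",
    "TriangleMesh",
    "SubjectMeta",
    "read_mesh",
    "write_mesh",
    "mirror_mesh",
]

REGION_UPPER = "upper_auricle"
REGION_LOBULE = "lobule"

#: Default 18-landmark registry.  Three names mark the auricle/lobule
#: boundary (cauda helicis, incisura intertragica, otobasion inferius);
#: the remainder follow standard auricular anatomy.
LANDMARK_NAMES: tuple[str, ...] = (
    "superaurale",
    "subaurale",
    "preaurale",
    "postaurale",
    "otobasion_superius",
    "otobasion_inferius",
    "tragion",
    "antitragion",
    "incisura_intertragica",
    "cauda_helicis",
    "helix_root",
    "helix_apex",
    "helix_posterior",
    "antihelix_apex",
    "crus_antihelicis",
    "concha_center",
    "fossa_triangularis",
    "lobule_apex",
)

_SIDES = ("left", "right")
_FORMATS = ("stl", "ply", "obj")


class MeshValidationError(ValueError):
    """Raised when a mesh or its annotations violate a structural invariant."""


@dataclass
class TriangleMesh:
    """Triangle surface in mm with optional landmarks and region labels.

    Parameters
    ----------
    vertices : (N, 3) float array
    faces : (F, 3) int array of vertex indices
    landmarks : optional mapping of the 18 configured landmark names to
        3-vectors
    region_labels : optional length-N array of strings in
        {``upper_auricle``, ``lobule``}
    """

    vertices: np.ndarray
    faces: np.ndarray
    landmarks: dict[str, np.ndarray] | None = None
    region_labels: np.ndarray | None = None
    landmark_names: tuple[str, ...] = LANDMARK_NAMES

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.vertices.shape[0] == 0:
            raise MeshValidationError("mesh has no vertices")
        if self.faces.size and (
            self.faces.min() < 0 or self.faces.max() >= self.n_vertices
        ):
            raise MeshValidationError("face index out of range")
        if self.landmarks is not None:
            self.landmarks = {
                str(k): np.asarray(v, dtype=float).reshape(3)
                for k, v in self.landmarks.items()
            }
            expected = set(self.landmark_names)
            got = set(self.landmarks)
            if got != expected:
                raise MeshValidationError(
                    f"landmark names mismatch: missing {sorted(expected - got)}, "
                    f"unexpected {sorted(got - expected)}"
                )
        if self.region_labels is not None:
            self.region_labels = np.asarray(self.region_labels, dtype=object)
            if self.region_labels.shape != (self.n_vertices,):
                raise MeshValidationError(
                    "region_labels must have one label per vertex"
                )
            bad = set(self.region_labels) - {REGION_UPPER, REGION_LOBULE}
            if bad:
                raise MeshValidationError(f"unknown region labels: {sorted(bad)}")

    @property
    def n_vertices(self) -> int:
        return int(self.vertices.shape[0])

    @property
    def n_faces(self) -> int:
        return int(self.faces.shape[0])

    def landmark_array(self) -> np.ndarray:
        """Landmark coordinates as an (18, 3) array in registry order."""
        if self.landmarks is None:
            raise MeshValidationError("mesh carries no landmarks")
        return np.stack([self.landmarks[n] for n in self.landmark_names])

    def bbox_diagonal(self) -> float:
        ext = self.vertices.max(axis=0) - self.vertices.min(axis=0)
        return float(np.linalg.norm(ext))

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.landmarks is None else {
                k: v.copy() for k, v in self.landmarks.items()
            },
            None if self.region_labels is None else self.region_labels.copy(),
            self.landmark_names,
        )

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        """Same topology and annotations, new vertex positions (landmarks dropped)."""
        return TriangleMesh(
            np.asarray(vertices, dtype=float),
            self.faces.copy(),
            None,
            None if self.region_labels is None else self.region_labels.copy(),
            self.landmark_names,
        )


@dataclass(frozen=True)
class SubjectMeta:
    """Identity of one ear specimen: subject id, side, and age in years."""

    subject_id: str
    side: str
    age: int
    age_range: tuple[int, int] = (0, 120)

    def __post_init__(self) -> None:
        if self.side not in _SIDES:
            raise MeshValidationError(f"side must be one of {_SIDES}")
        lo, hi = self.age_range
        if not lo <= self.age <= hi:
            raise MeshValidationError(
                f"age {self.age} outside plausible range [{lo}, {hi}]"
            )


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".landmarks.json")


def _resolve_format(path: Path, fmt: str) -> str:
    if fmt == "auto":
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unsupported mesh format {fmt!r}; expected {_FORMATS}")
    return fmt


def read_mesh(path: str | Path, fmt: str = "auto") -> TriangleMesh:
    """Read an STL/PLY/OBJ mesh and, when present, its JSON sidecar.

    Coordinates are preserved as stored (no merging, re-ordering or repair).
    """
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if not path.exists():
        raise IOError(f"mesh file not found: {path}")
    loaded = trimesh.load(path, file_type=fmt, process=False, force="mesh")
    vertices = np.asarray(loaded.vertices, dtype=float)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if vertices.shape[0] == 0:
        raise MeshValidationError(f"degenerate mesh (0 vertices): {path}")

    landmarks = None
    region_labels = None
    names = LANDMARK_NAMES
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if meta.get("landmarks"):
            landmarks = {k: np.array(v, float) for k, v in meta["landmarks"].items()}
            names = tuple(meta.get("landmark_names", sorted(landmarks)))
        if meta.get("region_labels"):
            region_labels = np.array(meta["region_labels"], dtype=object)
    return TriangleMesh(vertices, faces, landmarks, region_labels, names)


def write_mesh(mesh: TriangleMesh, path: str | Path, fmt: str = "auto") -> Path:
    """Write a mesh file plus a JSON sidecar when it carries annotations."""
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
    tm.export(path, file_type=fmt)

    sidecar = _sidecar_path(path)
    if mesh.landmarks is not None or mesh.region_labels is not None:
        payload: dict = {}
        if mesh.landmarks is not None:
            payload["landmark_names"] = list(mesh.landmark_names)
            payload["landmarks"] = {
                k: [float(x) for x in v] for k, v in mesh.landmarks.items()
            }
        if mesh.region_labels is not None:
            payload["region_labels"] = [str(x) for x in mesh.region_labels]
        sidecar.write_text(json.dumps(payload))
    elif sidecar.exists():
        sidecar.unlink()
    return path


_MIRROR_AXIS = {"yz": 0, "xz": 1, "xy": 2}


def mirror_mesh(mesh: TriangleMesh, plane: str = "yz") -> TriangleMesh:
    """Reflect a mesh across a coordinate plane.

    The mirrored axis coordinate is negated for vertices and landmarks and
    the face winding is flipped so outward normals remain outward.  Used to
    map right ears into the left-ear frame before homologous modelling.
    """
    if plane not in _MIRROR_AXIS:
        raise ValueError(f"plane must be one of {sorted(_MIRROR_AXIS)}")
    axis = _MIRROR_AXIS[plane]
    vertices = mesh.vertices.copy()
    vertices[:, axis] *= -1.0
    faces = mesh.faces[:, ::-1].copy()
    landmarks = None
    if mesh.landmarks is not None:
        landmarks = {}
        for k, v in mesh.landmarks.items():
            w = v.copy()
            w[axis] *= -1.0
            landmarks[k] = w
    labels = None if mesh.region_labels is None else mesh.region_labels.copy()
    return TriangleMesh(vertices, faces, landmarks, labels, mesh.landmark_names)
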