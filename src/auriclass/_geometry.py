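"""Low-level surface geometry: exact nearest-point projection and adjacency.

The projection routine replaces an R-tree based proximity query: candidate
triangles come from a cKDTree over triangle centroids (k nearest, k sized
generously relative to triangle extent) and the exact closest point on each
candidate triangle is computed with the standard barycentric region test.
Ties in distance are broken by the lowest face index, which makes the
projection fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SurfaceProjector", "vertex_adjacency", "laplacian_smooth"]


def _closest_on_triangles(p: np.ndarray, a, b, c) -> np.ndarray:
    """Closest point to ``p`` on each triangle (a[i], b[i], c[i]).

    Vectorised version of the barycentric-region algorithm (Ericson,
    *Real-Time Collision Detection*).  ``p`` is (3,), a/b/c are (M, 3).
    """
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(a)
    done = np.zeros(len(a), dtype=bool)

    # vertex regions
    m = (d1 <= 0) & (d2 <= 0)
    out[m] = a[m]
    done |= m
    m = (~done) & (d3 >= 0) & (d4 <= d3)
    out[m] = b[m]
    done |= m
    m = (~done) & (d6 >= 0) & (d5 <= d6)
    out[m] = c[m]
    done |= m

    # edge AB
    vc = d1 * d4 - d3 * d2
    m = (~done) & (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    denom = d1[m] - d3[m]
    t = np.where(denom > 0, d1[m] / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = a[m] + t[:, None] * ab[m]
    done |= m

    # edge AC
    vb = d5 * d2 - d1 * d6
    m = (~done) & (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    denom = d2[m] - d6[m]
    t = np.where(denom > 0, d2[m] / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = a[m] + t[:, None] * ac[m]
    done |= m

    # edge BC
    va = d3 * d6 - d5 * d4
    m = (~done) & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    denom = (d4[m] - d3[m]) + (d5[m] - d6[m])
    t = np.where(denom > 0, (d4[m] - d3[m]) / np.where(denom > 0, denom, 1.0), 0.0)
    out[m] = b[m] + t[:, None] * (c[m] - b[m])
    done |= m

    # interior
    m = ~done
    denom = va[m] + vb[m] + vc[m]
    denom = np.where(np.abs(denom) > 0, denom, 1.0)
    v = vb[m] / denom
    w = vc[m] / denom
    out[m] = a[m] + v[:, None] * ab[m] + w[:, None] * ac[m]
    return out


class SurfaceProjector:
    """Deterministic nearest-point-on-surface queries for one triangle mesh."""

    def __init__(self, vertices: np.ndarray, faces: np.ndarray, k: int = 16):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=np.int64)
        self.tri = self.vertices[self.faces]  # (F, 3, 3)
        self.centroids = self.tri.mean(axis=1)
        # half of the largest triangle circum-extent bounds how far the true
        # nearest triangle's centroid can be beyond the k-NN radius
        self.k = min(k, len(self.faces))
        self.tree = cKDTree(self.centroids)

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Closest surface points and distances for each query point."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        _, idx = self.tree.query(points, k=self.k)
        idx = np.atleast_2d(idx)
        out = np.empty_like(points)
        dist = np.empty(len(points))
        for i, p in enumerate(points):
            cand = np.sort(idx[i])
            cp = _closest_on_triangles(p, *np.swapaxes(self.tri[cand], 0, 1))
            d2 = np.einsum("ij,ij->i", cp - p, cp - p)
            j = int(np.argmin(d2))  # first minimum -> lowest face index
            out[i] = cp[j]
            dist[i] = np.sqrt(d2[j])
        return out, dist

    def distance(self, points: np.ndarray) -> np.ndarray:
        return self.project(points)[1]


def vertex_adjacency(n_vertices: int, faces: np.ndarray) -> list[np.ndarray]:
    """Per-vertex sorted arrays of neighbouring vertex indices."""
    neigh: list[set[int]] = [set() for _ in range(n_vertices)]
    for i, j, k in np.asarray(faces, dtype=np.int64):
        neigh[i].update((j, k))
        neigh[j].update((i, k))
        neigh[k].update((i, j))
    return [np.array(sorted(s), dtype=np.int64) for s in neigh]


def laplacian_smooth(
    values: np.ndarray, adjacency: list[np.ndarray], iterations: int = 1,
    weight: float = 1.0,
) -> np.ndarray:
    """Iterated neighbour averaging of per-vertex values (any trailing shape)."""
    out = np.asarray(values, dtype=float).copy()
    for _ in range(iterations):
        means = np.stack(
            [out[a].mean(axis=0) if len(a) else out[i]
             for i, a in enumerate(adjacency)]
        )
        out = (1.0 - weight) * out + weight * means
    return out
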