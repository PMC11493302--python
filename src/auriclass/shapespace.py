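"""Shape space: Procrustes standardisation, coordinate PCA, shape synthesis.

Homologous models are first standardised for size and posture by
generalized Procrustes analysis (GPA), then analysed by PCA of the n x 3N
matrix of flattened vertex coordinates.  Eigenvalues (EV) use the
population convention (divisor n); the contribution ratio of component k is

    CR_k = 100 * EV_k / sum_j EV_j        (percent)

and CCR is its running sum.  Following the source software's convention,
only components with CR at or above a display threshold (default 1 %) are
"displayed", but the total variance always includes every eigenvalue.  The
standard deviation of a component is sqrt(EV), and shapes are synthesised
as ``mean + sum_k score_k * eigvec_k``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .homofit import HomologousModel, similarity_procrustes
from .meshkit import MeshValidationError, TriangleMesh

__all__ = [
    "ShapeModel",
    "generalized_procrustes",
    "fit_shape_pca",
    "synthesize",
    "score_covariate_correlation",
    "save_shape_model",
    "load_shape_model",
]


@dataclass
class ShapeModel:
    """PCA decomposition of a set of aligned homologous shapes."""

    mean_shape: np.ndarray          # (3N,)
    eigenvalues: np.ndarray         # (m,) descending, >= 0
    eigenvectors: np.ndarray        # (m, 3N) orthonormal rows
    contribution_ratio: np.ndarray  # (m,) percent of total variance
    cumulative_cr: np.ndarray       # (m,) percent, nondecreasing
    scores: np.ndarray              # (n, m) per-specimen projections
    total_variance: float           # trace of the full covariance
    display_cr_threshold: float = 1.0
    n_specimens: int = 0
    faces: np.ndarray | None = None
    region_labels: np.ndarray | None = None

    @property
    def n_displayed(self) -> int:
        """Components with CR at or above the display threshold."""
        return int(np.sum(self.contribution_ratio >= self.display_cr_threshold))

    @property
    def displayed(self) -> np.ndarray:
        return np.arange(len(self.eigenvalues))[
            self.contribution_ratio >= self.display_cr_threshold
        ]

    def sd(self, k: int) -> float:
        """Standard deviation of component k (0-based): sqrt(EV_k)."""
        return float(np.sqrt(self.eigenvalues[k]))

    @property
    def n_vertices(self) -> int:
        return len(self.mean_shape) // 3


def _centroid_size(x: np.ndarray) -> float:
    c = x - x.mean(axis=0)
    return float(np.sqrt((c**2).sum()))


def generalized_procrustes(
    models: list[HomologousModel],
    allow_scaling: bool = True,
    tol_factor: float = 1e-8,
    max_iter: int = 100,
) -> tuple[list[HomologousModel], np.ndarray]:
    """Iterative similarity alignment of a sample of shapes to their mean.

    Each shape is aligned to the current mean by a least-squares similarity
    transform (rotation, translation, and scale when ``allow_scaling``);
    the mean is recomputed and the loop repeats until the mean moves less
    than ``tol_factor`` times its bounding-box diagonal, or 100 iterations.
    The returned mean has its centroid at the origin.
    """
    if len(models) < 2:
        raise MeshValidationError("GPA needs at least two models")
    shapes = [m.vertices.copy() for m in models]
    n_v = shapes[0].shape[0]
    if any(s.shape[0] != n_v for s in shapes):
        raise MeshValidationError("models do not share topology")

    mean = shapes[0] - shapes[0].mean(axis=0)
    for _ in range(max_iter):
        aligned = []
        for s in shapes:
            sc, rot, t = similarity_procrustes(s, mean, allow_scaling)
            aligned.append(sc * s @ rot.T + t)
        new_mean = np.mean(aligned, axis=0)
        new_mean -= new_mean.mean(axis=0)
        if allow_scaling:
            # keep the frame well defined: normalise mean centroid size to
            # the average of the aligned shapes' sizes
            target = np.mean([_centroid_size(a) for a in aligned])
            ms = _centroid_size(new_mean)
            if ms > 0:
                new_mean *= target / ms
        diag = np.linalg.norm(new_mean.max(axis=0) - new_mean.min(axis=0))
        delta = np.linalg.norm(new_mean - mean)
        shapes_out = aligned
        mean = new_mean
        if delta < tol_factor * max(diag, 1e-12):
            break
    if allow_scaling:
        # final pass: pin every shape's centroid size to the mean's
        target = _centroid_size(mean)
        final = []
        for a in shapes_out:
            ac = a - a.mean(axis=0)
            cs = _centroid_size(ac)
            final.append(ac * (target / cs) if cs > 0 else ac)
        shapes_out = final
    out = [
        HomologousModel(m.meta, s, m.faces, m.region_labels, m.fit_residual)
        for m, s in zip(models, shapes_out)
    ]
    return out, mean


def fit_shape_pca(
    models: list[HomologousModel],
    display_cr_threshold: float = 1.0,
    ddof: int = 0,
) -> ShapeModel:
    """PCA of aligned homologous models via SVD of the centered data matrix.

    ``ddof=0`` (divisor n) is the default eigenvalue convention.  The sign
    of each eigenvector is fixed so its largest-magnitude entry is
    positive, making outputs backend-independent.
    """
    n = len(models)
    if n < 2:
        raise MeshValidationError("PCA needs at least two specimens")
    x = np.stack([m.vertices.ravel() for m in models])
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    ev = s**2 / (n - ddof)
    keep = ev > max(ev[0], 1.0) * 1e-12 if len(ev) else slice(0)
    ev = ev[keep]
    vt = vt[keep]
    # deterministic sign: largest-|component| entry positive
    piv = np.argmax(np.abs(vt), axis=1)
    signs = np.sign(vt[np.arange(len(ev)), piv])
    signs[signs == 0] = 1.0
    vt = vt * signs[:, None]
    scores = xc @ vt.T
    total = float(ev.sum())
    cr = 100.0 * ev / total if total > 0 else np.zeros_like(ev)
    first = models[0]
    return ShapeModel(
        mean_shape=mean,
        eigenvalues=ev,
        eigenvectors=vt,
        contribution_ratio=cr,
        cumulative_cr=np.cumsum(cr),
        scores=scores,
        total_variance=total,
        display_cr_threshold=display_cr_threshold,
        n_specimens=n,
        faces=None if first.faces is None else first.faces.copy(),
        region_labels=(
            None if first.region_labels is None else first.region_labels.copy()
        ),
    )


def synthesize(model: ShapeModel, scores: dict[int, float]) -> TriangleMesh:
    """Shape at the given component scores: ``mean + sum score_k * vec_k``.

    ``scores`` maps 0-based component indices to raw score values (same
    units as sqrt(EV)); omitted components are zero.
    """
    v = model.mean_shape.copy()
    for k, val in scores.items():
        if not 0 <= k < len(model.eigenvalues):
            raise MeshValidationError(f"unknown component index {k}")
        v = v + float(val) * model.eigenvectors[k]
    faces = model.faces
    if faces is None:
        raise MeshValidationError("shape model carries no topology")
    return TriangleMesh(
        v.reshape(-1, 3),
        faces.copy(),
        None,
        None if model.region_labels is None else model.region_labels.copy(),
    )


def project_scores(model: ShapeModel, mesh_vertices: np.ndarray) -> np.ndarray:
    """Project a shape (same topology) onto the model's components."""
    x = np.asarray(mesh_vertices, float).ravel() - model.mean_shape
    return model.eigenvectors @ x


def score_covariate_correlation(
    model: ShapeModel, ages: np.ndarray, decimals: int = 2
) -> np.ndarray:
    """Pearson R between each displayed component's scores and age.

    Returns NaN for all components when the covariate has zero variance.
    Values are rounded to ``decimals`` places, matching how such tables are
    conventionally printed.
    """
    ages = np.asarray(ages, dtype=float)
    if len(ages) != model.n_specimens:
        raise MeshValidationError("ages length must equal number of specimens")
    disp = model.displayed
    if ages.std() == 0:
        return np.full(len(disp), np.nan)
    out = np.empty(len(disp))
    for i, k in enumerate(disp):
        sc = model.scores[:, k]
        if sc.std() == 0:
            out[i] = np.nan
        else:
            out[i] = stats.pearsonr(sc, ages)[0]
    return np.round(out, decimals)


def save_shape_model(model: ShapeModel, path: str | Path) -> Path:
    """Persist a shape model as a directory: manifest JSON + CSV + arrays."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_specimens": model.n_specimens,
        "n_vertices": model.n_vertices,
        "total_variance": model.total_variance,
        "display_cr_threshold": model.display_cr_threshold,
        "n_components": len(model.eigenvalues),
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    import pandas as pd

    pd.DataFrame(
        {
            "pc": np.arange(1, len(model.eigenvalues) + 1),
            "ev": model.eigenvalues,
            "cr_pct": np.round(model.contribution_ratio, 1),
            "ccr_pct": np.round(model.cumulative_cr, 1),
        }
    ).to_csv(path / "spectrum.csv", index=False)
    np.savetxt(path / "mean_shape.txt", model.mean_shape)
    np.savetxt(path / "eigenvectors.txt", model.eigenvectors)
    np.savetxt(path / "scores.txt", model.scores)
    np.savetxt(path / "eigenvalues.txt", model.eigenvalues)
    if model.faces is not None:
        np.savetxt(path / "faces.txt", model.faces, fmt="%d")
    if model.region_labels is not None:
        (path / "region_labels.json").write_text(
            json.dumps([str(x) for x in model.region_labels])
        )
    return path


def load_shape_model(path: str | Path) -> ShapeModel:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    ev = np.atleast_1d(np.loadtxt(path / "eigenvalues.txt"))
    vec = np.atleast_2d(np.loadtxt(path / "eigenvectors.txt"))
    total = float(manifest["total_variance"])
    cr = 100.0 * ev / total if total > 0 else np.zeros_like(ev)
    faces_file = path / "faces.txt"
    labels_file = path / "region_labels.json"
    return ShapeModel(
        mean_shape=np.loadtxt(path / "mean_shape.txt"),
        eigenvalues=ev,
        eigenvectors=vec,
        contribution_ratio=cr,
        cumulative_cr=np.cumsum(cr),
        scores=np.atleast_2d(np.loadtxt(path / "scores.txt")),
        total_variance=total,
        display_cr_threshold=float(manifest["display_cr_threshold"]),
        n_specimens=int(manifest["n_specimens"]),
        faces=np.loadtxt(faces_file, dtype=np.int64) if faces_file.exists() else None,
        region_labels=(
            np.array(json.loads(labels_file.read_text()), dtype=object)
            if labels_file.exists()
            else None
        ),
    )
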