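"""Composite images (CIs) and classification criterion images (CCIs).

From a first-stage shape model, composite images are synthesised on a
score grid: two per component (score -A and +A) and four per unordered
component pair (all sign combinations at amplitude A), giving
``2k + 4 C(k, 2)`` CIs for the first k components — 50 for k = 5 and 72
for k = 6.  A second-stage PCA over the CI meshes re-concentrates that
variation, and the CCIs are the ±amplitude shapes of its leading
components: ``2 n_pcs`` labelled prototype meshes (Roman numerals) that
serve as class templates for nearest-prototype classification.

Amplitudes are raw PC scores (not multiples of sqrt(EV)), matching the
fixed ±100 / ±60 / ±30 grids used on raw-score biplot axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .homofit import HomologousModel
from .meshkit import MeshValidationError, SubjectMeta, TriangleMesh
from .pcselect import dbv
from .shapespace import ShapeModel, fit_shape_pca, synthesize

__all__ = [
    "CompositeImage",
    "CCISet",
    "make_composite_images",
    "second_stage_pca",
    "derive_ccis",
    "cci_set_distance",
    "roman",
]


def roman(n: int) -> str:
    """Roman numeral for n >= 1 (labels I, II, III, ...)."""
    vals = (
        (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"),
        (90, "XC"), (50, "L"), (40, "XL"), (10, "X"), (9, "IX"),
        (5, "V"), (4, "IV"), (1, "I"),
    )
    if n < 1:
        raise ValueError("roman numerals start at 1")
    out = []
    for v, s in vals:
        while n >= v:
            out.append(s)
            n -= v
    return "".join(out)


@dataclass
class CompositeImage:
    """A synthesised mesh at fixed scores on one or two components."""

    mesh: TriangleMesh
    provenance: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        if len(self.provenance) not in (1, 2):
            raise MeshValidationError("provenance must list 1 or 2 components")
        idx = [k for k, _ in self.provenance]
        if len(set(idx)) != len(idx):
            raise MeshValidationError("component indices must be distinct")
        if any(a == 0 for _, a in self.provenance):
            raise MeshValidationError("amplitudes must be nonzero")


@dataclass
class CCISet:
    """Ordered, labelled prototype meshes for one ear region."""

    region: str
    ccis: list[tuple[str, TriangleMesh, tuple[tuple[int, float], ...]]]
    first_stage_pcs: int
    ci_amplitude: float
    cci_amplitude: float
    threshold: float = float("nan")
    ci_mean_shape: np.ndarray | None = None

    def __post_init__(self) -> None:
        labels = [lab for lab, _, _ in self.ccis]
        if len(set(labels)) != len(labels):
            raise MeshValidationError("CCI labels must be unique")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _, _ in self.ccis]

    def mesh(self, label: str) -> TriangleMesh:
        for lab, mesh, _ in self.ccis:
            if lab == label:
                return mesh
        raise KeyError(label)


def make_composite_images(
    model: ShapeModel, k: int, amplitude: float
) -> list[CompositeImage]:
    """All single and pairwise score-grid syntheses over the first k PCs.

    Ordering is deterministic: singles by component then sign (-, +), then
    pairs lexicographically with sign pairs (--, -+, +-, ++).
    Count: ``2k + 4 C(k, 2)``.
    """
    if k < 1:
        raise MeshValidationError("k must be >= 1")
    if k > model.n_displayed:
        raise MeshValidationError(
            f"k={k} exceeds the {model.n_displayed} displayed components"
        )
    if amplitude <= 0:
        raise MeshValidationError("amplitude must be positive")
    out: list[CompositeImage] = []
    for j in range(k):
        for s in (-1.0, +1.0):
            out.append(
                CompositeImage(
                    synthesize(model, {j: s * amplitude}),
                    ((j, s * amplitude),),
                )
            )
    for a, b in combinations(range(k), 2):
        for sa in (-1.0, +1.0):
            for sb in (-1.0, +1.0):
                out.append(
                    CompositeImage(
                        synthesize(model, {a: sa * amplitude, b: sb * amplitude}),
                        ((a, sa * amplitude), (b, sb * amplitude)),
                    )
                )
    return out


def second_stage_pca(
    cis: list[CompositeImage], display_cr_threshold: float = 1.0
) -> ShapeModel:
    """PCA over the composite-image meshes (no re-alignment needed; CIs
    already share the first-stage frame)."""
    if len(cis) < 2:
        raise MeshValidationError("second-stage PCA needs at least 2 CIs")
    models = [
        HomologousModel(
            SubjectMeta(f"CI{i:03d}", "left", 0),
            ci.mesh.vertices,
            ci.mesh.faces,
            ci.mesh.region_labels
            if ci.mesh.region_labels is not None
            else np.array(["upper_auricle"] * ci.mesh.n_vertices, dtype=object),
        )
        for i, ci in enumerate(cis)
    ]
    return fit_shape_pca(models, display_cr_threshold)


def derive_ccis(
    ci_model: ShapeModel,
    n_pcs: int,
    cci_amplitude: float,
    region: str,
    threshold: float = float("nan"),
    ci_amplitude: float = float("nan"),
) -> CCISet:
    """CCIs = ±amplitude shapes of the second-stage model's leading PCs.

    Produces ``2 n_pcs`` prototypes labelled I, II, ... in deterministic
    order (component-major, - before +).
    """
    if cci_amplitude <= 0:
        raise MeshValidationError("cci_amplitude must be positive")
    if n_pcs < 1 or n_pcs > ci_model.n_displayed:
        raise MeshValidationError(
            f"n_pcs={n_pcs} outside 1..{ci_model.n_displayed} displayed"
        )
    ccis = []
    label_i = 1
    for j in range(n_pcs):
        for s in (-1.0, +1.0):
            mesh = synthesize(ci_model, {j: s * cci_amplitude})
            ccis.append((roman(label_i), mesh, ((j, s * cci_amplitude),)))
            label_i += 1
    return CCISet(
        region=region,
        ccis=ccis,
        first_stage_pcs=n_pcs,
        ci_amplitude=ci_amplitude,
        cci_amplitude=cci_amplitude,
        threshold=threshold,
        ci_mean_shape=ci_model.mean_shape.copy(),
    )


def cci_set_distance(
    set_a: CCISet, set_b: CCISet, statistic: str = "mean"
) -> dict:
    """DBV between corresponding CCIs of two sets, after optimal matching.

    Component order and eigenvector sign are unstable across cohorts, so
    labels are matched by a Hungarian assignment on the pairwise DBV
    matrix before reporting per-label distances and their summary.
    """
    if len(set_a.ccis) != len(set_b.ccis):
        raise MeshValidationError("CCI sets must have equal counts")
    n = len(set_a.ccis)
    cost = np.empty((n, n))
    for i, (_, ma, _) in enumerate(set_a.ccis):
        for j, (_, mb, _) in enumerate(set_b.ccis):
            cost[i, j] = dbv(ma, mb, statistic)
    rows, cols = linear_sum_assignment(cost)
    per_label = {
        set_a.ccis[i][0]: float(cost[i, j]) for i, j in zip(rows, cols)
    }
    vals = np.array(list(per_label.values()))
    return {
        "per_label": per_label,
        "matching": {set_a.ccis[i][0]: set_b.ccis[j][0] for i, j in zip(rows, cols)},
        "min": float(vals.min()),
        "max": float(vals.max()),
        "mean": float(vals.mean()),
    }
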