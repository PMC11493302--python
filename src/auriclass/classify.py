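"""Nearest-prototype classification of ear meshes against a CCI set.

Each specimen is compared with every CCI by mean DBV; the CCI with the
minimum DBV is the assignment if that minimum is at or below the set's
threshold, otherwise the specimen is *out of classification*.  When
several CCIs fall under the threshold the full ranked list is reported
(multi-match), so a human examiner can apply a visual override; the
algorithmic assignment is always the DBV minimiser.

The threshold itself is not a universal constant: it is calibrated as a
percentile (default 90th) of the cohort's minimum-DBV distribution, which
by construction leaves about the complementary percentage out of
classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ccibuild import CCISet
from .homofit import HomologousModel
from .meshkit import MeshValidationError
from .pcselect import dbv

__all__ = [
    "OUT_OF_CLASSIFICATION",
    "ClassificationResult",
    "CohortClassificationSummary",
    "classify_one",
    "classify_cohort",
    "calibrate_threshold",
    "assignment_frequencies",
]

OUT_OF_CLASSIFICATION = "OUT_OF_CLASSIFICATION"


@dataclass
class ClassificationResult:
    """Per-specimen outcome: full DBV table, assignment, multi-match list."""

    subject_id: str
    side: str
    region: str
    dbv_by_cci: dict[str, float]
    assigned: str
    under_threshold_labels: list[str]
    rank_of_assigned: int | None

    @property
    def is_out(self) -> bool:
        return self.assigned == OUT_OF_CLASSIFICATION

    @property
    def is_multi_match(self) -> bool:
        return len(self.under_threshold_labels) >= 2


@dataclass
class CohortClassificationSummary:
    """Cohort-level accuracy and asymmetry statistics for one region."""

    region: str
    n_total: int
    n_under_threshold: int
    n_over_threshold: int
    n_multi_match: int
    cci_counts: dict[str, int]
    n_asymmetric: int
    n_bilateral_subjects: int
    results: list[ClassificationResult]

    @property
    def pct_under(self) -> float:
        return 100.0 * self.n_under_threshold / self.n_total

    @property
    def pct_over(self) -> float:
        return 100.0 * self.n_over_threshold / self.n_total

    @property
    def pct_multi(self) -> float:
        return 100.0 * self.n_multi_match / self.n_total

    @property
    def pct_asymmetric(self) -> float:
        if self.n_bilateral_subjects == 0:
            return float("nan")
        return 100.0 * self.n_asymmetric / self.n_bilateral_subjects


def classify_one(mesh, ccis: CCISet, meta=None) -> ClassificationResult:
    """Classify a single corresponded mesh against a CCI set.

    ``mesh`` may be a HomologousModel, TriangleMesh or (N, 3) array sharing
    the CCI topology.  Ties on the minimum DBV break by label order.
    """
    verts = np.asarray(getattr(mesh, "vertices", mesh), float).reshape(-1, 3)
    n_cci = ccis.ccis[0][1].n_vertices
    if verts.shape[0] != n_cci:
        raise MeshValidationError(
            f"topology mismatch: mesh has {verts.shape[0]} vertices, CCIs {n_cci}"
        )
    table = {lab: dbv(verts, m) for lab, m, _ in ccis.ccis}
    order = sorted(table, key=lambda lab: (table[lab], ccis.labels.index(lab)))
    thr = ccis.threshold
    under = [lab for lab in order if table[lab] <= thr] if np.isfinite(thr) else list(order)
    if under:
        assigned = under[0]
        rank = 1
    else:
        assigned = OUT_OF_CLASSIFICATION
        rank = None
    if meta is None:
        meta = getattr(mesh, "meta", None)
    return ClassificationResult(
        subject_id=getattr(meta, "subject_id", "unknown"),
        side=getattr(meta, "side", "left"),
        region=ccis.region,
        dbv_by_cci=table,
        assigned=assigned,
        under_threshold_labels=under,
        rank_of_assigned=rank,
    )


def calibrate_threshold(
    models: list, ccis: CCISet, q: float = 90.0
) -> float:
    """q-th percentile of the cohort's minimum CCI DBVs.

    Classifying the calibration cohort at this threshold leaves about
    (100 - q) % of specimens out of classification.
    """
    if not models:
        raise MeshValidationError("empty calibration cohort")
    mins = []
    for m in models:
        verts = np.asarray(getattr(m, "vertices", m), float).reshape(-1, 3)
        mins.append(min(dbv(verts, cci_mesh) for _, cci_mesh, _ in ccis.ccis))
    return float(np.percentile(mins, q))


def classify_cohort(
    models: list[HomologousModel], ccis: CCISet
) -> CohortClassificationSummary:
    """Classify every specimen and aggregate the four headline statistics.

    Asymmetry is evaluated only over subjects contributing both sides;
    a subject is asymmetric when its left and right assignments differ
    (out-of-classification differs from every label).
    """
    if not models:
        raise MeshValidationError("empty cohort")
    results = [classify_one(m, ccis, m.meta) for m in models]
    n_total = len(results)
    n_under = sum(not r.is_out for r in results)
    n_multi = sum(r.is_multi_match for r in results)
    counts = {lab: 0 for lab in ccis.labels}
    for r in results:
        if not r.is_out:
            counts[r.assigned] += 1

    by_subject: dict[str, dict[str, str]] = {}
    for r in results:
        by_subject.setdefault(r.subject_id, {})[r.side] = r.assigned
    bilateral = {
        sid: sides for sid, sides in by_subject.items()
        if "left" in sides and "right" in sides
    }
    n_asym = sum(
        1
        for sides in bilateral.values()
        if sides["left"] != sides["right"]
        or sides["left"] == OUT_OF_CLASSIFICATION
    )
    return CohortClassificationSummary(
        region=ccis.region,
        n_total=n_total,
        n_under_threshold=n_under,
        n_over_threshold=n_total - n_under,
        n_multi_match=n_multi,
        cci_counts=counts,
        n_asymmetric=n_asym,
        n_bilateral_subjects=len(bilateral),
        results=results,
    )


def assignment_frequencies(
    summary: CohortClassificationSummary,
) -> dict[str, float]:
    """Fraction of under-threshold assignments per CCI (sums to 1)."""
    total = summary.n_under_threshold
    if total == 0:
        return {lab: 0.0 for lab in summary.cci_counts}
    return {lab: c / total for lab, c in summary.cci_counts.items()}
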