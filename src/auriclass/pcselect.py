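"""How many principal components carry real shape variation?

Three complementary criteria are implemented, mirroring how the number of
meaningful components is chosen in 3D morphometric practice:

* an eigenvalue-magnitude threshold (``ev_threshold_select``);
* the scree elbow — the component immediately before the EV curve turns
  from steep to smooth (``scree_elbow``);
* the distance between vertices (DBV) of the two shapes synthesised at
  -3 SD and +3 SD of each component (``dbv_per_pc``), whose slope drops
  once components stop moving the surface;

plus a stability check across nested cohort subsets: the Dice overlap of
per-component shape-change areas (``shape_change_overlap``) and a sweep
driver (``subset_sweep``).

DBV between two corresponded meshes is the mean (or max) of the per-vertex
Euclidean distances — the workhorse statistic of the whole pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .homofit import HomologousModel
from .meshkit import MeshValidationError
from .shapespace import ShapeModel, fit_shape_pca, generalized_procrustes, synthesize

__all__ = [
    "DBVReport",
    "ShapeChangeMask",
    "dbv",
    "ev_threshold_select",
    "scree_elbow",
    "dbv_per_pc",
    "shape_change_mask",
    "shape_change_overlap",
    "subset_sweep",
    "AGE_BANDS",
]

#: the study's seven age strata (years, inclusive bounds)
AGE_BANDS: tuple[tuple[int, int], ...] = (
    (17, 29), (30, 39), (40, 49), (50, 59), (60, 69), (70, 79), (80, 93),
)


def dbv(mesh_a, mesh_b, statistic: str = "mean") -> float:
    """Distance between vertices of two corresponded meshes (mm).

    Accepts anything exposing ``vertices`` or a raw (N, 3) array; the two
    vertex sets must be in correspondence (same count and order).
    """
    a = np.asarray(getattr(mesh_a, "vertices", mesh_a), float).reshape(-1, 3)
    b = np.asarray(getattr(mesh_b, "vertices", mesh_b), float).reshape(-1, 3)
    if a.shape != b.shape:
        raise MeshValidationError(
            f"vertex count mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    d = np.linalg.norm(a - b, axis=1)
    if statistic == "mean":
        return float(d.mean())
    if statistic == "max":
        return float(d.max())
    raise MeshValidationError("statistic must be 'mean' or 'max'")


def ev_threshold_select(eigenvalues: np.ndarray, threshold: float) -> int:
    """Largest m such that EV_m >= threshold (0 if none).

    The eigenvalue sequence must be nonincreasing, as produced by PCA.
    """
    ev = np.asarray(eigenvalues, float)
    if np.any(np.diff(ev) > 1e-9 * max(abs(ev[0]), 1.0)):
        raise MeshValidationError("eigenvalues must be nonincreasing")
    return int(np.sum(ev >= threshold))


def scree_elbow(eigenvalues: np.ndarray) -> int:
    """Component count immediately before the EV curve turns smooth.

    The elbow is located at the interior index maximising the discrete
    second difference EV_{k-1} - 2 EV_k + EV_{k+1}; the returned count is
    k - 1 (1-based components), i.e. the component just before the bend.
    Ties break to the smallest count.
    """
    ev = np.asarray(eigenvalues, float)
    if len(ev) < 3:
        raise MeshValidationError("scree elbow needs at least 3 eigenvalues")
    second = ev[:-2] - 2 * ev[1:-1] + ev[2:]  # index i -> interior k = i + 2
    k = int(np.argmax(second)) + 2
    return k - 1


@dataclass
class DBVReport:
    """Per-component DBV of the (-3 SD, +3 SD) shape pair."""

    values: np.ndarray
    statistic: str = "mean"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if np.any(self.values < 0):
            raise MeshValidationError("DBV values must be nonnegative")


def dbv_per_pc(
    model: ShapeModel, upto: int | None = None, statistic: str = "mean"
) -> DBVReport:
    """DBV between the -3 SD and +3 SD shapes of each component.

    For the mean statistic this equals ``6 sqrt(EV_k) mean_i ||phi_k,i||``
    where ``phi_k,i`` is vertex i's 3-vector within eigenvector k.
    """
    m = model.n_displayed if upto is None else int(upto)
    if m > len(model.eigenvalues):
        raise MeshValidationError("upto exceeds available components")
    vals = np.empty(m)
    for k in range(m):
        amp = 3.0 * model.sd(k)
        lo = synthesize(model, {k: -amp})
        hi = synthesize(model, {k: +amp})
        vals[k] = dbv(lo, hi, statistic)
    return DBVReport(vals, statistic)


@dataclass
class ShapeChangeMask:
    """Vertices displaced beyond a threshold between mean and +3 SD shape."""

    displacement: np.ndarray  # per-vertex mm
    threshold: float
    mask: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.mask & (self.displacement < self.threshold)):
            raise MeshValidationError("mask true requires displacement >= threshold")


def shape_change_mask(
    model: ShapeModel,
    pc: int,
    displacement_threshold: float | None = None,
    sign: float = +1.0,
) -> ShapeChangeMask:
    """Displacement map of component ``pc`` at +3 SD (or -3 SD) vs the mean.

    With no absolute threshold given, the cutoff defaults to the 75th
    percentile of that component's per-vertex displacements — a relative
    "red region" rule.
    """
    amp = sign * 3.0 * model.sd(pc)
    shape = synthesize(model, {pc: amp})
    disp = np.linalg.norm(
        shape.vertices - model.mean_shape.reshape(-1, 3), axis=1
    )
    thr = (
        float(np.percentile(disp, 75.0))
        if displacement_threshold is None
        else float(displacement_threshold)
    )
    return ShapeChangeMask(disp, thr, disp >= thr)


def _dice(a: np.ndarray, b: np.ndarray) -> float:
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def shape_change_overlap(
    model_a: ShapeModel,
    model_b: ShapeModel,
    pc: int,
    displacement_threshold: float | None = None,
) -> float:
    """Dice overlap of the two models' shape-change areas for one component.

    The comparison is run against both signs of model B's component and
    the larger Dice kept, absorbing the sign ambiguity of eigenvectors.
    """
    if model_a.n_vertices != model_b.n_vertices:
        raise MeshValidationError("models do not share topology")
    ma = shape_change_mask(model_a, pc, displacement_threshold).mask
    best = 0.0
    for sign in (+1.0, -1.0):
        mb = shape_change_mask(model_b, pc, displacement_threshold, sign).mask
        best = max(best, _dice(ma, mb))
    return best


@dataclass
class SubsetResult:
    size: int
    indices: np.ndarray
    model: ShapeModel
    ev_count: int | None = None
    elbow: int | None = None
    dbv_slope: np.ndarray | None = None
    dice_vs_full: np.ndarray | None = None


def _stratified_nested_indices(
    ages: np.ndarray, sizes: list[int], rng: np.random.Generator
) -> list[np.ndarray]:
    """Nested age-stratified subsets of the requested sizes (ascending)."""
    n = len(ages)
    strata = []
    for lo, hi in AGE_BANDS:
        strata.append(np.nonzero((ages >= lo) & (ages <= hi))[0])
    leftover = np.nonzero(
        ~np.logical_or.reduce([(ages >= lo) & (ages <= hi) for lo, hi in AGE_BANDS])
    )[0]
    # a per-stratum random order; nested subsets take prefixes proportionally
    orders = [rng.permutation(s) for s in strata if len(s)]
    if len(leftover):
        orders.append(rng.permutation(leftover))
    out = []
    for size in sorted(sizes):
        if size > n:
            raise MeshValidationError(f"subset size {size} exceeds cohort {n}")
        take: list[np.ndarray] = []
        remaining = size
        for j, order in enumerate(orders):
            frac = len(order) / n
            k = min(len(order), int(round(frac * size)))
            take.append(order[:k])
            remaining -= k
        flat = np.concatenate(take) if take else np.array([], dtype=int)
        # fix rounding drift deterministically
        if len(flat) > size:
            flat = flat[:size]
        elif len(flat) < size:
            pool = np.setdiff1d(np.concatenate(orders), flat)
            flat = np.concatenate([flat, pool[: size - len(flat)]])
        out.append(np.sort(flat))
    # enforce nesting: each smaller subset a subset of the next
    for i in range(len(out) - 1):
        missing = np.setdiff1d(out[i], out[i + 1])
        if len(missing):
            pool = np.setdiff1d(out[i + 1], out[i])
            out[i + 1] = np.sort(
                np.concatenate([np.setdiff1d(out[i + 1], pool[: len(missing)]),
                                missing])
            )
    return out


def subset_sweep(
    models: list[HomologousModel],
    sizes: list[int] | None = None,
    seed: int = 0,
    ev_threshold: float | None = None,
    display_cr_threshold: float = 1.0,
) -> list[SubsetResult]:
    """Run GPA + PCA + the selection criteria on nested cohort subsets.

    Default sizes follow the study design scaled to the cohort at hand:
    with at least 414 models the classic 123/242/300/363/full ladder is
    used; otherwise the same proportions of the full size.
    """
    n = len(models)
    if sizes is None:
        ladder = [123, 242, 300, 363]
        if n >= 414:
            sizes = [s for s in ladder if s < n] + [n]
        else:
            sizes = sorted({max(2, int(round(n * s / 414))) for s in ladder} | {n})
    sizes = sorted(sizes)
    if sizes[-1] > n:
        raise MeshValidationError("largest subset size exceeds cohort size")
    ages = np.array([m.meta.age for m in models])
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5B]))
    index_sets = _stratified_nested_indices(ages, sizes, rng)

    results: list[SubsetResult] = []
    for size, idx in zip(sizes, index_sets):
        subset = [models[i] for i in idx]
        aligned, _ = generalized_procrustes(subset)
        model = fit_shape_pca(aligned, display_cr_threshold)
        res = SubsetResult(size, idx, model)
        res.elbow = scree_elbow(model.eigenvalues) if len(model.eigenvalues) >= 3 else None
        if ev_threshold is not None:
            res.ev_count = ev_threshold_select(model.eigenvalues, ev_threshold)
        res.dbv_slope = dbv_per_pc(model).values
        results.append(res)

    full = results[-1].model
    for res in results:
        m = min(res.model.n_displayed, full.n_displayed)
        res.dice_vs_full = np.array(
            [shape_change_overlap(res.model, full, k) for k in range(m)]
        )
    return results
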