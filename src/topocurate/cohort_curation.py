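"""Cohort-side curation via dominant cycles.

Each cohort (row of the expression matrix) becomes one point of an
m-dimensional point cloud.  The longest H1/H2 intervals of its Rips
filtration are localized as representative cycles, and a cycle is
*dominant* when a single phenotype label covers at least half of its
vertex set: ``max_count >= floor(|Vert(Z)| / 2)``.  The curated cohort
set is the union of the vertex sets of the dominant cycles — cohorts
that participate in no dominant cycle are treated as uncorrelated or
erroneous measurements and dropped.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .complex_core import (
    Filtration,
    PointCloud,
    build_rips_filtration,
    compute_persistence,
    finite_intervals,
    top_k_by_length,
)
from .rep_cycles import RepCycle, cycles_for_intervals, pseudo_manifoldize

__all__ = [
    "ExpressionDataset",
    "DominanceReport",
    "CurationResult",
    "cohorts_to_point_cloud",
    "dominance_report",
    "curate_cohorts",
    "DominantCycleCohortCurator",
]


@dataclass
class ExpressionDataset:
    """An n-cohort x m-gene expression matrix with phenotype labels."""

    values: np.ndarray
    cohort_ids: list
    gene_ids: list
    labels: dict  # cohort_id -> int phenotype

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or 0 in self.values.shape:
            raise ValueError("values must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        self.cohort_ids = list(self.cohort_ids)
        self.gene_ids = list(self.gene_ids)
        n, m = self.values.shape
        if len(self.cohort_ids) != n or len(set(self.cohort_ids)) != n:
            raise ValueError("cohort_ids must be unique and match row count")
        if len(self.gene_ids) != m or len(set(self.gene_ids)) != m:
            raise ValueError("gene_ids must be unique and match column count")
        missing = [c for c in self.cohort_ids if c not in self.labels]
        if missing:
            raise ValueError(f"cohorts without labels: {missing[:5]}")
        self.labels = {c: int(self.labels[c]) for c in self.cohort_ids}

    @property
    def n_cohorts(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def label_array(self) -> np.ndarray:
        return np.array([self.labels[c] for c in self.cohort_ids], dtype=int)

    def subset_cohorts(self, cohort_ids) -> "ExpressionDataset":
        """Restrict to the given cohorts, preserving original row order."""
        wanted = set(cohort_ids)
        idx = [i for i, c in enumerate(self.cohort_ids) if c in wanted]
        ids = [self.cohort_ids[i] for i in idx]
        return ExpressionDataset(
            self.values[idx], ids, self.gene_ids, {c: self.labels[c] for c in ids}
        )

    def subset_genes(self, gene_ids) -> "ExpressionDataset":
        """Restrict to the given genes, preserving original column order."""
        wanted = set(gene_ids)
        idx = [j for j, g in enumerate(self.gene_ids) if g in wanted]
        return ExpressionDataset(
            self.values[:, idx],
            self.cohort_ids,
            [self.gene_ids[j] for j in idx],
            dict(self.labels),
        )


def _scale(values: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "none":
        return values
    if scaling == "zscore":
        mu = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        sd = np.where(sd == 0, 1.0, sd)  # constant columns map to zero
        return (values - mu) / sd
    if scaling == "log2":
        if np.any(values <= 0):
            raise ValueError("log2 scaling requires strictly positive values")
        return np.log2(values)
    raise ValueError(f"unknown scaling {scaling!r}")


def cohorts_to_point_cloud(
    ds: ExpressionDataset, scaling: str = "none"
) -> PointCloud:
    """One point per cohort; coordinates are its (scaled) expression row."""
    return PointCloud(
        coords=_scale(ds.values, scaling),
        point_ids=list(ds.cohort_ids),
        labels=[ds.labels[c] for c in ds.cohort_ids],
    )


@dataclass
class DominanceReport:
    """Label census of one cycle's vertex set and the dominance verdict."""

    cycle: RepCycle
    label_counts: dict[int, int]
    dominant: bool
    dominating_label: int | None
    dominance_ratio: float


def dominance_report(cycle: RepCycle, labels: dict[int, int]) -> DominanceReport:
    """Classify a cycle as dominant or not.

    ``labels`` maps vertex index -> phenotype.  A cycle is dominant when
    its most frequent label reaches ``floor(|Vert(Z)| / 2)`` (the >= is
    deliberate: 7 of 15 vertices qualifies).  Among labels tied at the
    maximal count the smallest label value dominates.
    """
    verts = sorted(cycle.vertex_set)
    if not verts:
        raise ValueError("cycle has an empty vertex set")
    counts: dict[int, int] = {}
    for v in verts:
        if v not in labels:
            raise ValueError(f"cycle vertex {v} has no label")
        counts[labels[v]] = counts.get(labels[v], 0) + 1
    best = max(counts.values())
    winner = min(lbl for lbl, c in counts.items() if c == best)
    dominant = best >= math.floor(len(verts) / 2)
    return DominanceReport(
        cycle=cycle,
        label_counts=counts,
        dominant=dominant,
        dominating_label=winner if dominant else None,
        dominance_ratio=best / len(verts),
    )


@dataclass
class CurationResult:
    """Outcome of dominant-cycle cohort curation."""

    selected_cohorts: list
    mode: str
    k: int
    reports: list[DominanceReport]
    curated: ExpressionDataset | None
    failures: list = field(default_factory=list)


_MODES = {"h1": (1,), "h2": (2,), "h1+h2": (1, 2)}


def _curation_filtration(
    cloud: PointCloud, mode: str, filtration_params: dict | None
) -> tuple[Filtration, Filtration | None]:
    params = dict(filtration_params or {})
    dims = _MODES[mode]
    need_dim = 3 if 2 in dims else 2
    params.setdefault("max_dim", need_dim)
    if params["max_dim"] < need_dim:
        raise ValueError(f"mode {mode} needs max_dim >= {need_dim}")
    filt = build_rips_filtration(cloud, **params)
    pm = pseudo_manifoldize(filt) if 2 in dims else None
    return filt, pm


def _top_cycles(
    filt: Filtration,
    pm: Filtration | None,
    dims: tuple[int, ...],
    k: int,
    weight_schemes: dict | None,
):
    schemes = weight_schemes or {}
    cycles, failures = [], []
    for d in dims:
        source = pm if d == 2 else filt
        ivs = finite_intervals(compute_persistence(source, max_hom_dim=d), d)
        top = top_k_by_length(ivs, k)
        cyc, fail = cycles_for_intervals(source, top, d, schemes.get(d))
        cycles.extend(cyc)
        failures.extend(fail)
    return cycles, failures


def curate_cohorts(
    ds: ExpressionDataset,
    k: int = 100,
    mode: str = "h1+h2",
    scaling: str = "none",
    filtration_params: dict | None = None,
    weight_schemes: dict | None = None,
) -> CurationResult:
    """Select the topologically relevant cohort subset.

    Builds the cohort point cloud and its Rips filtration, takes the
    ``k`` longest finite intervals per requested homology dimension,
    extracts representative cycles, and keeps the union of the vertex
    sets of the dominant ones.  Row order of the original matrix is
    preserved in the curated output.
    """
    mode = mode.lower()
    if mode not in _MODES:
        raise ValueError(f"mode must be one of {sorted(_MODES)}")
    if k < 0:
        raise ValueError("k must be non-negative")
    cloud = cohorts_to_point_cloud(ds, scaling)
    filt, pm = _curation_filtration(cloud, mode, filtration_params)
    cycles, failures = _top_cycles(filt, pm, _MODES[mode], k, weight_schemes)
    labels = {i: cloud.labels[i] for i in range(len(cloud))}
    reports = [dominance_report(c, labels) for c in cycles]
    selected_idx = sorted(
        {v for r in reports if r.dominant for v in r.cycle.vertex_set}
    )
    if not cycles and k > 0:
        warnings.warn("no finite intervals in requested dimensions; empty selection")
    selected = [ds.cohort_ids[i] for i in selected_idx]
    curated = ds.subset_cohorts(selected) if selected else None
    return CurationResult(
        selected_cohorts=selected,
        mode=mode,
        k=k,
        reports=reports,
        curated=curated,
        failures=failures,
    )


class DominantCycleCohortCurator(BaseEstimator):
    """Sample (cohort) selector driven by dominant persistent cycles.

    scikit-learn style estimator; note that it selects *rows*, so
    ``transform`` returns ``(X_sel, y_sel)`` rather than composing with
    column-transform pipelines.

    Parameters
    ----------
    k : number of longest intervals per homology dimension to localize.
    mode : 'h1', 'h2' or 'h1+h2'.
    scaling : 'none', 'zscore' or 'log2' applied to rows before the
        point cloud is built.
    max_scale : Rips scale cap (essential for tractability in dim 3).
    sparsity : optional sparse-Rips interleaving ratio.

    Attributes
    ----------
    support_ : boolean mask over input rows (selected cohorts).
    reports_ : list of DominanceReport, one per extracted cycle.
    n_selected_ : number of selected cohorts.
    """

    def __init__(
        self,
        k: int = 100,
        mode: str = "h1+h2",
        scaling: str = "none",
        max_scale: float = math.inf,
        sparsity: float | None = None,
    ):
        self.k = k
        self.mode = mode
        self.scaling = scaling
        self.max_scale = max_scale
        self.sparsity = sparsity

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        ids = list(range(X.shape[0]))
        ds = ExpressionDataset(
            X, ids, [f"g{j}" for j in range(X.shape[1])], dict(zip(ids, y.tolist()))
        )
        result = curate_cohorts(
            ds,
            k=self.k,
            mode=self.mode,
            scaling=self.scaling,
            filtration_params={"max_scale": self.max_scale, "sparsity": self.sparsity},
        )
        mask = np.zeros(X.shape[0], dtype=bool)
        mask[[int(c) for c in result.selected_cohorts]] = True
        self.support_ = mask
        self.reports_ = result.reports
        self.n_selected_ = int(mask.sum())
        return self

    def transform(self, X, y=None):
        if not hasattr(self, "support_"):
            raise ValueError("curator is not fitted")
        X = np.asarray(X)
        if y is None:
            return X[self.support_]
        return X[self.support_], np.asarray(y)[self.support_]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X, y)
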