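"""Gene-side curation via the kappa maximal-cover statistic.

Transposing the expression matrix turns every gene into a point in
cohort-space; representative cycles on that point cloud group genes
that are geometrically entangled.  For each cycle Z the statistic

    kappa(Z) = min{ |S| : S a set of annotation terms such that every
                    gene in Vert(Z) carries at least one term of S }

is the exact minimum set cover of the cycle's genes by their functional
annotations.  A low kappa means the cycle is functionally coherent;
genes from low-kappa cycles form the curated gene set G'.

Genes without curated annotations carry the reserved term
``"Not annotated"``, which is an ordinary coverable term (it can and
does appear in minimum covers).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .cohort_curation import ExpressionDataset, _curation_filtration, _scale, _top_cycles
from .complex_core import PointCloud
from .rep_cycles import RepCycle

__all__ = [
    "NOT_ANNOTATED",
    "AnnotationMap",
    "CoverResult",
    "genes_to_point_cloud",
    "kappa_cover",
    "minimum_set_cover",
    "greedy_set_cover",
    "curate_genes",
    "GeneCurationResult",
    "KappaGeneSelector",
]

NOT_ANNOTATED = "Not annotated"


@dataclass
class AnnotationMap:
    """gene id -> non-empty set of functional terms."""

    terms: dict

    def __post_init__(self):
        self.terms = {g: frozenset(ts) for g, ts in self.terms.items()}
        for g, ts in self.terms.items():
            if not ts:
                raise ValueError(f"gene {g!r} has an empty term set")

    @property
    def vocabulary(self) -> frozenset:
        return frozenset(t for ts in self.terms.values() for t in ts)

    @classmethod
    def from_pairs(cls, pairs) -> "AnnotationMap":
        """Aggregate (gene, term) rows into term sets."""
        acc: dict = {}
        for g, t in pairs:
            acc.setdefault(g, set()).add(str(t))
        return cls(acc)

    def for_genes(self, gene_ids) -> "AnnotationMap":
        """Restrict/extend to gene_ids; unknown genes get NOT_ANNOTATED."""
        return AnnotationMap(
            {g: self.terms.get(g, frozenset({NOT_ANNOTATED})) for g in gene_ids}
        )

    def __getitem__(self, gene):
        return self.terms[gene]

    def __contains__(self, gene):
        return gene in self.terms


def genes_to_point_cloud(ds: ExpressionDataset, scaling: str = "none") -> PointCloud:
    """One point per gene; coordinates are its expression across cohorts."""
    return PointCloud(
        coords=_scale(ds.values, scaling).T,
        point_ids=list(ds.gene_ids),
        labels=None,
    )


def greedy_set_cover(sets: list[frozenset]) -> list:
    """Classic greedy cover (upper bound on the exact minimum)."""
    uncovered = set(range(len(sets)))
    cover = []
    while uncovered:
        term = max(
            sorted({t for i in uncovered for t in sets[i]}),
            key=lambda t: sum(1 for i in uncovered if t in sets[i]),
        )
        cover.append(term)
        uncovered -= {i for i in uncovered if term in sets[i]}
    return cover


def minimum_set_cover(sets: list[frozenset]) -> list:
    """Exact minimum set cover, lexicographically least among minima.

    Branch-and-bound determines the optimum size; the witness cover is
    then the first covering combination of that size in lexicographic
    term order.  Instances here are tiny (cycle vertex sets, ~5–30
    genes), so exactness is cheap.
    """
    if not sets:
        raise ValueError("cannot cover an empty collection")
    n = len(sets)
    best = len(greedy_set_cover(sets))

    def dfs(uncovered: frozenset, size: int):
        nonlocal best
        if not uncovered:
            best = min(best, size)
            return
        if size + 1 > best:
            return
        # branch on the hardest gene: fewest candidate terms
        g = min(uncovered, key=lambda i: (len(sets[i]), i))
        for t in sorted(sets[g]):
            dfs(frozenset(i for i in uncovered if t not in sets[i]), size + 1)

    dfs(frozenset(range(n)), 0)
    vocab = sorted({t for s in sets for t in s})
    for combo in itertools.combinations(vocab, best):
        chosen = set(combo)
        if all(s & chosen for s in sets):
            return list(combo)
    raise AssertionError("branch-and-bound optimum not realizable")  # pragma: no cover


@dataclass
class CoverResult:
    """kappa and one certified minimum cover for a cycle's gene set."""

    kappa: int
    cover: list
    cycle: RepCycle


def kappa_cover(
    cycle: RepCycle, ann: AnnotationMap, gene_ids: list | None = None
) -> CoverResult:
    """Exact kappa (minimum annotation cover size) of a cycle.

    ``gene_ids`` translates the cycle's vertex indices into gene
    identifiers; when omitted the vertices are assumed to *be* the ids.
    """
    verts = sorted(cycle.vertex_set)
    if not verts:
        raise ValueError("cycle has an empty vertex set")
    genes = [gene_ids[v] for v in verts] if gene_ids is not None else verts
    missing = [g for g in genes if g not in ann]
    if missing:
        raise KeyError(f"genes without annotations: {missing[:5]}")
    sets = [ann[g] for g in genes]
    cover = minimum_set_cover(sets)
    return CoverResult(kappa=len(cover), cover=cover, cycle=cycle)


@dataclass
class GeneCurationResult:
    selected_genes: list
    covers: list[CoverResult]
    kappa_max: float
    curated: ExpressionDataset | None
    failures: list = field(default_factory=list)


def curate_genes(
    ds: ExpressionDataset,
    ann: AnnotationMap,
    k: int = 100,
    kappa_max: float = 3,
    dims: tuple[int, ...] = (1, 2),
    scaling: str = "none",
    filtration_params: dict | None = None,
) -> GeneCurationResult:
    """Select the topologically and functionally relevant gene subset G'.

    Builds the gene point cloud (transposed matrix), extracts the top-k
    representative cycles per requested dimension, scores each by
    kappa, and returns the union of the vertex (gene) sets of cycles
    with ``kappa <= kappa_max``.  Column order of the original matrix
    is preserved.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    if kappa_max < 1:
        raise ValueError("kappa_max must be >= 1")
    dims = tuple(sorted(set(dims)))
    if not dims or any(d not in (1, 2) for d in dims):
        raise ValueError("dims must be a non-empty subset of {1, 2}")
    mode = {(1,): "h1", (2,): "h2", (1, 2): "h1+h2"}[dims]
    cloud = genes_to_point_cloud(ds, scaling)
    filt, pm = _curation_filtration(cloud, mode, filtration_params)
    cycles, failures = _top_cycles(filt, pm, dims, k, None)
    full_ann = ann.for_genes(ds.gene_ids)
    covers = [kappa_cover(c, full_ann, gene_ids=ds.gene_ids) for c in cycles]
    selected_idx = sorted(
        {v for cv in covers if cv.kappa <= kappa_max for v in cv.cycle.vertex_set}
    )
    if not selected_idx and k > 0:
        warnings.warn("no cycle satisfies the kappa threshold; empty gene set")
    selected = [ds.gene_ids[j] for j in selected_idx]
    curated = ds.subset_genes(selected) if selected else None
    return GeneCurationResult(
        selected_genes=selected,
        covers=covers,
        kappa_max=kappa_max,
        curated=curated,
        failures=failures,
    )


class KappaGeneSelector(SelectorMixin, BaseEstimator):
    """Feature (gene) selector keeping genes of low-kappa cycles.

    Composes with sklearn pipelines: ``fit(X)`` builds the gene point
    cloud from the columns of X, extracts top-k cycles, computes kappa
    against the annotation map, and exposes the selected columns via
    ``get_support()`` / ``transform``.

    Parameters
    ----------
    annotations : AnnotationMap or {gene_id: terms}; genes absent from
        it are annotated NOT_ANNOTATED.
    gene_ids : column identifiers; defaults to the column index.
    k, kappa_max, dims, scaling, max_scale, sparsity : see curate_genes.

    Attributes
    ----------
    support_ : boolean column mask.
    covers_ : list of CoverResult per extracted cycle.
    """

    def __init__(
        self,
        annotations=None,
        gene_ids=None,
        k: int = 100,
        kappa_max: float = 3,
        dims: tuple[int, ...] = (1, 2),
        scaling: str = "none",
        max_scale: float = float("inf"),
        sparsity: float | None = None,
    ):
        self.annotations = annotations
        self.gene_ids = gene_ids
        self.k = k
        self.kappa_max = kappa_max
        self.dims = dims
        self.scaling = scaling
        self.max_scale = max_scale
        self.sparsity = sparsity

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, m = X.shape
        gene_ids = list(self.gene_ids) if self.gene_ids is not None else list(range(m))
        ann = self.annotations
        if ann is None:
            ann = AnnotationMap({})
        elif not isinstance(ann, AnnotationMap):
            ann = AnnotationMap(dict(ann))
        ds = ExpressionDataset(
            X, list(range(n)), gene_ids, {i: 0 for i in range(n)}
        )
        result = curate_genes(
            ds,
            ann,
            k=self.k,
            kappa_max=self.kappa_max,
            dims=self.dims,
            scaling=self.scaling,
            filtration_params={"max_scale": self.max_scale, "sparsity": self.sparsity},
        )
        sel = set(result.selected_genes)
        self.support_ = np.array([g in sel for g in gene_ids], dtype=bool)
        self.covers_ = result.covers
        self.n_features_in_ = m
        return self

    def _get_support_mask(self):
        if not hasattr(self, "support_"):
            raise ValueError("selector is not fitted")
        return self.support_
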