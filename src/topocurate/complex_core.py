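"""Point clouds, Rips filtrations and persistence pairing.

The pipeline treats every cohort (or, transposed, every gene) of an
expression matrix as a point in Euclidean space, builds a Vietoris–Rips
filtration on the resulting point cloud and computes persistent homology
over Z/2.  Unlike barcode-only libraries, the pairing here keeps the
*creator* and *destroyer* simplices of every interval explicitly: the
creator edge of an H1 interval and the creator triangle / destroyer
tetrahedron of an H2 interval are the raw material for representative
cycle extraction downstream.

Simplices are plain tuples of strictly increasing vertex indices; the
dimension of a simplex is ``len(s) - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PointCloud",
    "Filtration",
    "PersistenceInterval",
    "simplex",
    "build_rips_filtration",
    "compute_persistence",
    "finite_intervals",
    "top_k_by_length",
]

Simplex = tuple[int, ...]

INF = math.inf


def simplex(vertices) -> Simplex:
    """Canonicalize a vertex collection into a simplex tuple.

    Vertices are sorted; duplicates are rejected; dimensions above 3 are
    rejected (nothing in the pipeline needs them).
    """
    vs = tuple(sorted(int(v) for v in vertices))
    if len(set(vs)) != len(vs):
        raise ValueError(f"duplicate vertices in simplex {vertices!r}")
    if not 1 <= len(vs) <= 4:
        raise ValueError(f"simplex dimension {len(vs) - 1} outside 0..3")
    return vs


@dataclass
class PointCloud:
    """A finite set of labelled points in Euclidean space.

    Parameters
    ----------
    coords : (n, d) array of finite floats.
    point_ids : n unique opaque identifiers (row order = coordinate order).
    labels : optional integer phenotype per point.
    """

    coords: np.ndarray
    point_ids: list
    labels: list | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[0] == 0:
            raise ValueError("coords must be a non-empty 2-D array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("point cloud contains non-finite coordinates")
        self.point_ids = list(self.point_ids)
        if len(self.point_ids) != self.coords.shape[0]:
            raise ValueError("point_ids length does not match coords")
        if len(set(self.point_ids)) != len(self.point_ids):
            raise ValueError("point_ids must be unique")
        if self.labels is not None:
            self.labels = [int(x) for x in self.labels]
            if len(self.labels) != self.coords.shape[0]:
                raise ValueError("labels length does not match coords")

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class Filtration:
    """An ordered simplicial filtration.

    ``simplices[i]`` enters the complex at position ``i`` with scale
    ``values[i]``; values are non-decreasing and every proper face of a
    simplex appears earlier.  ``is_pseudo_manifold`` marks output of the
    pseudo-manifold conversion (every triangle has <= 2 tetra cofacets),
    a precondition of the H2 min-cut algorithm.
    """

    simplices: list[Simplex]
    values: list[float]
    is_pseudo_manifold: bool = False
    index_of: dict[Simplex, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self.index_of:
            self.index_of = {s: i for i, s in enumerate(self.simplices)}

    def __len__(self) -> int:
        return len(self.simplices)

    def dim(self) -> int:
        return max(len(s) for s in self.simplices) - 1

    def validate(self) -> None:
        """Check the filtration invariants, raising on the first violation."""
        if len(self.simplices) != len(self.values):
            raise ValueError("simplices/values length mismatch")
        if self.index_of != {s: i for i, s in enumerate(self.simplices)}:
            raise ValueError("index_of is not the bijection onto filtration order")
        prev = -INF
        for i, (s, v) in enumerate(zip(self.simplices, self.values)):
            if v < prev:
                raise ValueError(f"values decrease at index {i} ({s})")
            prev = v
            for face in facets(s):
                j = self.index_of.get(face)
                if j is None or j >= i:
                    raise ValueError(
                        f"face {face} of simplex {s} (index {i}) missing or later"
                    )


def facets(s: Simplex) -> list[Simplex]:
    """All codimension-1 faces of a simplex (empty for a vertex)."""
    if len(s) == 1:
        return []
    return [s[:i] + s[i + 1 :] for i in range(len(s))]


@dataclass
class PersistenceInterval:
    """A birth–death pair of a homology class, with its witness simplices.

    ``creator`` is the simplex whose insertion gives birth to the class
    (an edge for H1, a triangle for H2); ``destroyer`` is the simplex
    whose insertion kills it (one dimension higher), absent for
    essential classes where ``death_index`` is +inf.
    """

    dim: int
    birth_index: int
    death_index: float  # int or math.inf
    birth_value: float
    death_value: float
    creator: Simplex
    destroyer: Simplex | None = None

    @property
    def finite(self) -> bool:
        return self.death_index != INF

    @property
    def length(self) -> float:
        return self.death_value - self.birth_value


def _rips_simplices(dist: np.ndarray, max_dim: int, max_scale: float):
    """Incremental Vietoris–Rips expansion via lower-neighbor intersection.

    Yields (value, simplex) for every simplex of dimension <= max_dim
    whose diameter (max pairwise distance) is <= max_scale.
    """
    n = dist.shape[0]
    # lower neighbours: j < i with d(i, j) <= max_scale
    lower = [set(np.nonzero(dist[i, :i] <= max_scale)[0].tolist()) for i in range(n)]
    for i in range(n):
        yield 0.0, (i,)

    def expand(tau: Simplex, nbrs: set, value: float, dim_left: int):
        for v in sorted(nbrs):
            sigma = (v,) + tau  # v < all of tau by construction
            val = max(value, max(dist[v, u] for u in tau))
            yield val, sigma
            if dim_left > 1:
                yield from expand(sigma, nbrs & lower[v], val, dim_left - 1)

    if max_dim >= 1:
        for i in range(n):
            yield from expand((i,), lower[i], 0.0, max_dim)


def _greedy_permutation(dist: np.ndarray) -> np.ndarray:
    """Insertion radii of the farthest-point greedy permutation."""
    n = dist.shape[0]
    lam = np.full(n, INF)
    cur = 0
    d = dist[cur].copy()
    lam[cur] = INF
    for _ in range(1, n):
        cur = int(np.argmax(d))
        lam[cur] = d[cur]
        d = np.minimum(d, dist[cur])
    return lam


def build_rips_filtration(
    points: PointCloud,
    max_dim: int = 2,
    max_scale: float = INF,
    sparsity: float | None = None,
) -> Filtration:
    """Build a (sparse) Vietoris–Rips filtration on a point cloud.

    Each simplex's filtration value is the *diameter* of its vertex set
    (max pairwise Euclidean distance).  Simplices are ordered by
    ``(value, dim, vertices)`` so that pairing is deterministic.

    Parameters
    ----------
    max_dim : highest simplex dimension to include (1–3).
    max_scale : only simplices of diameter <= max_scale are built.
    sparsity : if set (interleaving ratio in (0, 1), e.g. 0.9), apply a
        greedy-permutation edge pruning: point ``q`` with insertion
        radius ``lam_q`` accepts no edge longer than
        ``lam_q * (1 + eps) / eps`` where ``eps = (1 - sparsity) /
        sparsity``.  This is an approximation; exact mode
        (``sparsity=None``) is the reference path.
    """
    if max_dim not in (1, 2, 3):
        raise ValueError("max_dim must be 1, 2 or 3")
    if not max_scale > 0:
        raise ValueError("max_scale must be positive")
    n = len(points)
    if n == 1:
        return Filtration([(0,)], [0.0])
    dist = squareform(pdist(points.coords))
    if sparsity is not None:
        if not 0 < sparsity < 1:
            raise ValueError("sparsity must lie in (0, 1)")
        eps = (1.0 - sparsity) / sparsity
        lam = _greedy_permutation(dist)
        cutoff = np.minimum.outer(lam, lam) * (1.0 + eps) / eps
        dist = np.where(dist <= cutoff, dist, INF)
    entries = sorted(
        _rips_simplices(dist, max_dim, max_scale),
        key=lambda e: (e[0], len(e[1]), e[1]),
    )
    return Filtration([s for _, s in entries], [v for v, _ in entries])


def compute_persistence(
    filt: Filtration, max_hom_dim: int = 2
) -> list[PersistenceInterval]:
    """Z/2 persistence pairing by boundary-matrix reduction.

    Standard column reduction with the youngest-kill convention: the
    insertion of a (d+1)-simplex whose reduced boundary column has pivot
    ``i`` kills the class created by simplex ``i`` — the youngest
    then-unpaired d-class.  Columns are stored as python integers used
    as bitmasks, so adding two columns is one XOR.

    Returns finite and essential intervals for dimensions
    ``0..max_hom_dim`` in order of death (essential ones last, by birth).
    """
    simplices, values = filt.simplices, filt.values
    k = len(simplices)
    index_of = filt.index_of
    columns: list[int] = []
    for i, s in enumerate(simplices):
        col = 0
        for f in facets(s):
            j = index_of.get(f)
            if j is None or j >= i:
                raise ValueError(f"malformed filtration: face {f} of {s} not earlier")
            col |= 1 << j
        columns.append(col)

    low_inv: dict[int, int] = {}  # pivot row -> column index owning it
    pairs: list[tuple[int, int]] = []
    paired = [False] * k
    for j in range(k):
        col = columns[j]
        while col:
            piv = col.bit_length() - 1
            other = low_inv.get(piv)
            if other is None:
                break
            col ^= columns[other]
        columns[j] = col
        if col:
            piv = col.bit_length() - 1
            low_inv[piv] = j
            pairs.append((piv, j))
            paired[piv] = paired[j] = True

    intervals: list[PersistenceInterval] = []
    for i, j in pairs:
        d = len(simplices[i]) - 1
        if d > max_hom_dim:
            continue
        intervals.append(
            PersistenceInterval(
                dim=d,
                birth_index=i,
                death_index=j,
                birth_value=values[i],
                death_value=values[j],
                creator=simplices[i],
                destroyer=simplices[j],
            )
        )
    for i in range(k):
        if not paired[i]:
            d = len(simplices[i]) - 1
            if d > max_hom_dim:
                continue
            intervals.append(
                PersistenceInterval(
                    dim=d,
                    birth_index=i,
                    death_index=INF,
                    birth_value=values[i],
                    death_value=INF,
                    creator=simplices[i],
                )
            )
    intervals.sort(key=lambda iv: (iv.death_index, iv.birth_index))
    return intervals


def finite_intervals(
    intervals: list[PersistenceInterval], dim: int
) -> list[PersistenceInterval]:
    """Finite intervals of one homology dimension, order preserved."""
    return [iv for iv in intervals if iv.finite and iv.dim == dim]


def top_k_by_length(
    intervals: list[PersistenceInterval], k: int
) -> list[PersistenceInterval]:
    """The k longest intervals by persistence ``death - birth``.

    Descending by length; ties broken by earlier birth index.  All
    intervals are returned when fewer than k are available.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    for iv in intervals:
        if not iv.finite:
            raise ValueError("top_k_by_length requires finite intervals")
    ranked = sorted(intervals, key=lambda iv: (-iv.length, iv.birth_index))
    return ranked[:k]
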