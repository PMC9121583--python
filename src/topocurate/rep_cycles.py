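"""Representative persistent cycles.

Two polynomial-time constructions localize the homology classes behind
barcode intervals:

* **H1** — at the birth of a 1-cycle an edge closes a loop; the
  representative is that creator edge plus the shortest path between
  its endpoints through the strictly earlier 1-skeleton.  This is the
  shortest cycle at birth; verifying it is still the class that dies at
  the death time is skipped (it is in most practical point-cloud cases),
  so the result is a well-motivated approximation, not a certified
  minimal cycle for the interval.

* **H2** — on a pseudo-manifold (every triangle with at most two
  tetrahedral cofacets) the *minimal* persistent 2-cycle of an interval
  [beta, delta) is exact: build the dual flow network (a node per
  tetrahedron plus one infinite vertex, an arc per triangle), give
  triangles born at or before beta their weight as capacity and +inf
  otherwise, and take the triangles dual to a minimum cut separating
  the destroyer tetrahedron from the infinite vertex and all
  tetrahedra born after delta.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .complex_core import (
    Filtration,
    PersistenceInterval,
    Simplex,
    facets,
)

__all__ = [
    "RepCycle",
    "DualFlowNetwork",
    "h1_cycle",
    "h2_cycle",
    "pseudo_manifoldize",
    "cycles_for_intervals",
    "boundary_is_zero",
]

INF = math.inf
_INF_NODE = "inf"


@dataclass
class RepCycle:
    """A representative d-cycle: a set of d-simplices with its interval."""

    dim: int
    simplices: frozenset[Simplex]
    interval: PersistenceInterval

    @property
    def vertex_set(self) -> frozenset[int]:
        """Vert(Z): the union of the member simplices' vertices."""
        return frozenset(v for s in self.simplices for v in s)

    def validate(self, filt: Filtration) -> None:
        if not boundary_is_zero(self.simplices):
            raise ValueError("simplex set has non-zero Z/2 boundary")
        for s in self.simplices:
            if filt.index_of[s] > self.interval.birth_index:
                raise ValueError(f"cycle simplex {s} born after the interval")


def boundary_is_zero(simplices) -> bool:
    """True iff every codim-1 face occurs an even number of times (Z/2)."""
    counts = Counter(f for s in simplices for f in facets(s))
    return all(c % 2 == 0 for c in counts.values())


def h1_cycle(
    filt: Filtration,
    interval: PersistenceInterval,
    weight_scheme: str = "euclidean",
) -> RepCycle:
    """Shortest cycle through the creator edge at its birth.

    The 1-skeleton is restricted to edges inserted strictly before the
    creator; the shortest path between the creator's endpoints is found
    there and closed by the creator edge.  ``weight_scheme='euclidean'``
    weights edges by their filtration value (for a Rips filtration this
    is exactly the Euclidean endpoint distance); ``'hop'`` counts edges.
    """
    if interval.dim != 1 or not interval.finite:
        raise ValueError("h1_cycle needs a finite H1 interval")
    if weight_scheme not in ("euclidean", "hop"):
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    beta = interval.birth_index
    creator = interval.creator
    g = nx.Graph()
    for idx, s in enumerate(filt.simplices[:beta]):
        if len(s) == 2:
            w = filt.values[idx] if weight_scheme == "euclidean" else 1.0
            g.add_edge(s[0], s[1], weight=w)
    u, v = creator
    try:
        path = nx.shortest_path(g, u, v, weight="weight")
    except (nx.NetworkXNoPath, nx.NodeNotFound) as exc:
        raise ValueError(
            "no path between creator endpoints before birth: corrupted filtration"
        ) from exc
    edges = {creator} | {
        tuple(sorted((path[i], path[i + 1]))) for i in range(len(path) - 1)
    }
    return RepCycle(dim=1, simplices=frozenset(edges), interval=interval)


def pseudo_manifoldize(filt: Filtration) -> Filtration:
    """Trim a filtration so that every triangle has <= 2 tetra cofacets.

    All simplices of dimension <= 2 are kept.  A tetrahedron survives
    only if it is among the first two cofacets (by filtration order) of
    *each* of its four triangles.  Order and values are inherited; the
    output is flagged ``is_pseudo_manifold``.
    """
    quota: dict[Simplex, int] = defaultdict(int)
    keep: list[int] = []
    for idx, s in enumerate(filt.simplices):
        if len(s) <= 3:
            keep.append(idx)
            continue
        tris = facets(s)
        if all(quota[t] < 2 for t in tris):
            for t in tris:
                quota[t] += 1
            keep.append(idx)
    return Filtration(
        [filt.simplices[i] for i in keep],
        [filt.values[i] for i in keep],
        is_pseudo_manifold=True,
    )


@dataclass
class DualFlowNetwork:
    """Dual graph of a pseudo-manifold set up as an s-t flow problem.

    Nodes are tetrahedron filtration indices plus the infinite vertex;
    each triangle contributes one undirected arc between the nodes of
    its <= 2 cofacets (to the infinite vertex when it has fewer).  Arcs
    of triangles born after the interval's birth are uncuttable (+inf).
    """

    graph: nx.Graph
    source: object
    sink_set: set
    arc_of_triangle: dict[Simplex, tuple] = field(default_factory=dict)


def _build_dual_network(
    filt: Filtration, interval: PersistenceInterval, weight_scheme: str
) -> DualFlowNetwork:
    beta, delta = interval.birth_index, interval.death_index
    cofacets: dict[Simplex, list[int]] = defaultdict(list)
    for idx, s in enumerate(filt.simplices):
        if len(s) == 4:
            for t in facets(s):
                cofacets[t].append(idx)
    g = nx.Graph()
    arc_of: dict[Simplex, tuple] = {}
    for idx, s in enumerate(filt.simplices):
        if len(s) != 3:
            continue
        cf = cofacets.get(s, [])
        if len(cf) > 2:
            raise ValueError(
                f"triangle {s} has {len(cf)} cofacets; run pseudo_manifoldize first"
            )
        a = cf[0] if len(cf) >= 1 else _INF_NODE
        b = cf[1] if len(cf) == 2 else _INF_NODE
        if a == b:  # both ends the infinite vertex: arc can never be cut usefully
            continue
        if idx <= beta:
            cap = filt.values[idx] if weight_scheme == "filtration_value" else 1.0
        else:
            cap = INF
        # one intermediate node per triangle keeps parallel arcs distinct
        mid = ("tri", idx)
        g.add_edge(a, mid, capacity=cap)
        g.add_edge(mid, b, capacity=cap)
        arc_of[s] = (a, mid, b)
    sinks = {_INF_NODE} | {
        i for i, s in enumerate(filt.simplices) if len(s) == 4 and i > delta
    }
    return DualFlowNetwork(
        graph=g, source=interval.death_index, sink_set=sinks, arc_of_triangle=arc_of
    )


def h2_cycle(
    filt: Filtration,
    interval: PersistenceInterval,
    weight_scheme: str = "filtration_value",
) -> RepCycle:
    """Minimal persistent 2-cycle of an H2 interval by dual min-cut.

    Requires ``filt.is_pseudo_manifold``.  The source is the node of the
    destroyer tetrahedron; the sink is the infinite vertex together with
    all tetrahedra inserted after the death (contracted).  The triangles
    dual to the minimum cut's arcs form the cycle, which always contains
    the creator triangle.
    """
    if interval.dim != 2 or not interval.finite:
        raise ValueError("h2_cycle needs a finite H2 interval")
    if not filt.is_pseudo_manifold:
        raise ValueError("filtration is not a pseudo-manifold; run pseudo_manifoldize")
    if weight_scheme not in ("filtration_value", "unit"):
        raise ValueError(f"unknown weight_scheme {weight_scheme!r}")
    net = _build_dual_network(filt, interval, weight_scheme)
    g = net.graph.copy()
    supersink = ("sink",)
    for node in net.sink_set:
        if node in g or node == _INF_NODE:
            g.add_edge(supersink, node)  # no 'capacity' attr => infinite
    if net.source not in g:
        raise ValueError("destroyer tetrahedron is isolated in the dual graph")
    cut_value, (src_side, _) = nx.minimum_cut(g, net.source, supersink)
    if not math.isfinite(cut_value):
        raise ValueError("no finite-capacity cut: interval/complex inconsistent")
    src_side = set(src_side)
    cycle = {
        tri
        for tri, (a, mid, b) in net.arc_of_triangle.items()
        if (a in src_side) != (b in src_side)
    }
    result = RepCycle(dim=2, simplices=frozenset(cycle), interval=interval)
    if interval.creator not in cycle:
        raise ValueError("min-cut cycle does not contain the creator triangle")
    return result


def cycles_for_intervals(
    filt: Filtration,
    intervals: list[PersistenceInterval],
    dim: int,
    weight_scheme: str | None = None,
) -> tuple[list[RepCycle], list[tuple[PersistenceInterval, Exception]]]:
    """Extract a representative cycle per interval; collect failures.

    Returns ``(cycles, failures)`` where failures pair each offending
    interval with the exception it raised; successes keep input order.
    """
    if dim not in (1, 2):
        raise ValueError("dim must be 1 or 2")
    extract = h1_cycle if dim == 1 else h2_cycle
    kwargs = {} if weight_scheme is None else {"weight_scheme": weight_scheme}
    cycles: list[RepCycle] = []
    failures: list[tuple[PersistenceInterval, Exception]] = []
    for iv in intervals:
        try:
            cycles.append(extract(filt, iv, **kwargs))
        except Exception as exc:  # noqa: BLE001 - per-item error channel
            failures.append((iv, exc))
    return cycles, failures
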