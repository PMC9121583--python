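import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from topocurate.cohort_curation import ExpressionDataset
from topocurate.complex_core import (
    Filtration,
    PersistenceInterval,
    PointCloud,
    build_rips_filtration,
)
from topocurate.rep_cycles import RepCycle
from topocurate.synth_fixtures import six_gene_annotations, square_diagonals_filtration


@pytest.fixture(scope="session")
def worked_filtration():
    return square_diagonals_filtration()


@pytest.fixture(scope="session")
def worked_annotations():
    return six_gene_annotations()


@pytest.fixture
def square_filtration():
    """Unit square a-b-c-d with edge da inserted last, then no triangles."""
    entries = [
        ((0,), 0.0), ((1,), 0.0), ((2,), 0.0), ((3,), 0.0),
        ((0, 1), 1.0), ((1, 2), 1.0), ((2, 3), 1.0),
        ((0, 3), 1.5),
        ((0, 2), 2.0), ((0, 1, 2), 3.0), ((0, 2, 3), 3.0),
    ]
    return Filtration([s for s, _ in entries], [v for _, v in entries])


@pytest.fixture
def triangle_filtration():
    """Triangle a,b,c with edge ca inserted last."""
    entries = [
        ((0,), 0.0), ((1,), 0.0), ((2,), 0.0),
        ((0, 1), 1.0), ((1, 2), 1.0),
        ((0, 2), 2.0),
        ((0, 1, 2), 3.0),
    ]
    return Filtration([s for s, _ in entries], [v for _, v in entries])


def hollow_tetra_filtration():
    """Boundary of a tetrahedron, coned off by the solid tet at the end."""
    verts = [((i,), 0.0) for i in range(4)]
    edges = [(tuple(e), 1.0) for e in
             [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]]
    tris = [(tuple(t), 2.0) for t in
            [(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)]]
    tet = [((0, 1, 2, 3), 3.0)]
    entries = verts + edges + tris + tet
    f = Filtration([s for s, _ in entries], [v for _, v in entries])
    f.is_pseudo_manifold = True
    return f


@pytest.fixture
def hollow_tetra():
    return hollow_tetra_filtration()


def octahedron_filtration():
    """Octahedron boundary (8 triangles) filled afterwards by interior tets.

    Vertices 0/1 are the poles, 2-5 the equator.  The 8 boundary
    triangles enter at value 2; the four tetrahedra filling the volume
    (each pole pair with an equator edge) enter at value 3.
    """
    equator = [(2, 3), (3, 4), (4, 5), (2, 5)]
    verts = [((i,), 0.0) for i in range(6)]
    edges = set()
    tris = []
    for pole in (0, 1):
        for e in equator:
            tris.append(tuple(sorted((pole,) + e)))
    for t in tris:
        for i in range(3):
            edges.add(t[:i] + t[i + 1 :])
    tets = [tuple(sorted((0, 1) + e)) for e in equator]
    for tet in tets:
        for i in range(4):
            tris_needed = tet[:i] + tet[i + 1 :]
            if tris_needed not in tris:
                tris.append(tris_needed)
            for j in range(3):
                edges.add(tris_needed[:j] + tris_needed[j + 1 :])
    entries = (
        verts
        + [(e, 1.0) for e in sorted(edges)]
        + [(t, 2.0) for t in sorted(set(tris) - set(_interior_tris(tets)))]
        + [(t, 2.5) for t in sorted(_interior_tris(tets))]
        + [(t, 3.0) for t in sorted(tets)]
    )
    f = Filtration([s for s, _ in entries], [v for _, v in entries])
    f.is_pseudo_manifold = True
    return f


def _interior_tris(tets):
    """Triangles containing both poles (interior walls of the octahedron)."""
    out = set()
    for tet in tets:
        for i in range(4):
            t = tet[:i] + tet[i + 1 :]
            if 0 in t and 1 in t:
                out.add(t)
    return out


@pytest.fixture
def octahedron():
    return octahedron_filtration()


@pytest.fixture
def small_dataset():
    rng = np.random.default_rng(0)
    values = rng.normal(size=(6, 4))
    ids = [f"c{i}" for i in range(6)]
    return ExpressionDataset(
        values, ids, [f"g{j}" for j in range(4)],
        {c: i % 2 for i, c in enumerate(ids)},
    )


def make_cycle(n_vertices: int, dim: int = 1) -> RepCycle:
    """A polygon RepCycle on vertices 0..n-1 with a dummy interval."""
    edges = frozenset(
        tuple(sorted((i, (i + 1) % n_vertices))) for i in range(n_vertices)
    )
    iv = PersistenceInterval(
        dim=1, birth_index=0, death_index=1, birth_value=0.0, death_value=1.0,
        creator=min(edges),
    )
    return RepCycle(dim=1, simplices=edges, interval=iv)


def random_filtration(seed: int, max_simplices: int = 200) -> Filtration:
    """Seeded random Rips filtration with at most max_simplices simplices."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    d = int(rng.integers(2, 4))
    pts = rng.normal(size=(n, d))
    max_dim = int(rng.integers(1, 4))
    filt = build_rips_filtration(
        PointCloud(pts, list(range(n))), max_dim=max_dim,
        max_scale=float(rng.uniform(1.0, 3.0)),
    )
    if len(filt) > max_simplices:
        filt = Filtration(
            filt.simplices[:max_simplices], filt.values[:max_simplices]
        )
        # truncation may orphan cofaces; drop any simplex missing a face
        keep, have = [], set()
        for s, v in zip(filt.simplices, filt.values):
            if all(s[:i] + s[i + 1 :] in have for i in range(len(s))) or len(s) == 1:
                keep.append((s, v))
                have.add(s)
        filt = Filtration([s for s, _ in keep], [v for _, v in keep])
    return filt
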