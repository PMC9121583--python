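"""Representative H1/H2 cycles, pseudo-manifold conversion, min-cut."""

import math

import numpy as np
import pytest

from oracles import edmonds_karp, min_two_cycle_through
from topocurate.complex_core import (
    Filtration,
    PointCloud,
    build_rips_filtration,
    compute_persistence,
    finite_intervals,
    top_k_by_length,
)
from topocurate.rep_cycles import (
    _build_dual_network,
    boundary_is_zero,
    cycles_for_intervals,
    h1_cycle,
    h2_cycle,
    pseudo_manifoldize,
)


def _h1(filt):
    return finite_intervals(compute_persistence(filt, 1), 1)


def _h2(filt):
    return finite_intervals(compute_persistence(filt, 2), 2)


class TestH1Cycle:
    def test_triangle_unique_cycle(self, triangle_filtration):
        (iv,) = _h1(triangle_filtration)
        cyc = h1_cycle(triangle_filtration, iv)
        assert cyc.simplices == frozenset({(0, 1), (1, 2), (0, 2)})
        assert cyc.vertex_set == {0, 1, 2}

    def test_square_cycle(self, square_filtration):
        iv = next(i for i in _h1(square_filtration) if i.creator == (0, 3))
        cyc = h1_cycle(square_filtration, iv)
        assert cyc.simplices == frozenset({(0, 1), (1, 2), (2, 3), (0, 3)})

    @pytest.mark.parametrize("scheme", ["euclidean", "hop"])
    def test_cycle_is_valid_boundary_and_temporal(self, scheme):
        from topocurate.synth_fixtures import noisy_circle

        pts = noisy_circle(25, 0.05, seed=4)
        filt = build_rips_filtration(
            PointCloud(pts, list(range(25))), max_dim=2, max_scale=2.0
        )
        for iv in top_k_by_length(_h1(filt), 5):
            cyc = h1_cycle(filt, iv, weight_scheme=scheme)
            cyc.validate(filt)

    def test_planted_circle_geometry(self):
        """The longest H1 cycle of a noisy unit circle stays within
        3*noise of the planted radius."""
        from topocurate.synth_fixtures import noisy_circle

        noise = 0.05
        pts = noisy_circle(30, noise, seed=3)
        filt = build_rips_filtration(
            PointCloud(pts, list(range(30))), max_dim=2, max_scale=2.0
        )
        iv = top_k_by_length(_h1(filt), 1)[0]
        cyc = h1_cycle(filt, iv)
        radii = np.linalg.norm(pts[sorted(cyc.vertex_set)], axis=1)
        assert np.all(np.abs(radii - 1.0) <= 3 * noise)

    def test_bad_interval_rejected(self, worked_filtration):
        h0 = finite_intervals(compute_persistence(worked_filtration), 0)
        with pytest.raises(ValueError):
            h1_cycle(worked_filtration, h0[0])


class TestPseudoManifoldize:
    def test_identity_when_already_pseudo_manifold(self, hollow_tetra):
        out = pseudo_manifoldize(hollow_tetra)
        assert out.simplices == hollow_tetra.simplices
        assert out.values == hollow_tetra.values
        assert out.is_pseudo_manifold

    def test_three_cofacets_drops_latest(self):
        """A triangle with three tetra cofacets at values 1<2<3 keeps the
        first two."""
        base = [((i,), 0.0) for i in range(6)]
        tri = (0, 1, 2)
        tets = [(0, 1, 2, 3), (0, 1, 2, 4), (0, 1, 2, 5)]
        edges, tris = set(), set()
        for tet in tets:
            for i in range(4):
                t = tet[:i] + tet[i + 1 :]
                tris.add(t)
                for j in range(3):
                    edges.add(t[:j] + t[j + 1 :])
        entries = (
            base
            + [(e, 0.5) for e in sorted(edges)]
            + [(t, 0.8) for t in sorted(tris)]
            + [(tets[0], 1.0), (tets[1], 2.0), (tets[2], 3.0)]
        )
        filt = Filtration([s for s, _ in entries], [v for _, v in entries])
        out = pseudo_manifoldize(filt)
        kept_tets = [s for s in out.simplices if len(s) == 4]
        assert tets[0] in kept_tets and tets[1] in kept_tets
        assert tets[2] not in kept_tets

    def test_random_complex_cofacet_census(self):
        """Exhaustive count: no triangle of the output has > 2 cofacets."""
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(12, 3))
        filt = build_rips_filtration(
            PointCloud(pts, list(range(12))), max_dim=3, max_scale=2.5
        )
        out = pseudo_manifoldize(filt)
        out.validate()
        counts = {}
        for s in out.simplices:
            if len(s) == 4:
                for i in range(4):
                    t = s[:i] + s[i + 1 :]
                    counts[t] = counts.get(t, 0) + 1
        assert counts and max(counts.values()) <= 2


class TestH2Cycle:
    def test_hollow_tetra(self, hollow_tetra):
        ivs = _h2(hollow_tetra)
        assert len(ivs) == 1
        cyc = h2_cycle(hollow_tetra, ivs[0])
        assert cyc.simplices == frozenset(
            {(0, 1, 2), (0, 1, 3), (0, 2, 3), (1, 2, 3)}
        )

    def test_octahedron_matches_enumeration(self, octahedron):
        """The min-cut 2-cycle of the octahedron cavity equals the
        minimum over exhaustive Z/2 2-cycle enumeration (unit weights)."""
        ivs = _h2(octahedron)
        iv = min(ivs, key=lambda x: x.birth_value)
        cyc = h2_cycle(octahedron, iv, weight_scheme="unit")
        boundary = {
            s for s in octahedron.simplices
            if len(s) == 3 and not (0 in s and 1 in s)
        }
        assert cyc.simplices == frozenset(boundary)
        tri_le_beta = [
            s for i, s in enumerate(octahedron.simplices)
            if len(s) == 3 and i <= iv.birth_index
        ]
        w, best = min_two_cycle_through(tri_le_beta, iv.creator)
        assert len(cyc.simplices) == w == 8

    def test_requires_pseudo_manifold_flag(self, octahedron):
        plain = Filtration(octahedron.simplices, octahedron.values)
        iv = _h2(octahedron)[0]
        with pytest.raises(ValueError, match="pseudo_manifold"):
            h2_cycle(plain, iv)

    def test_planted_sphere_geometry(self):
        """All vertices of the longest H2 cycle of a noisy unit sphere lie
        within 3*noise of the planted surface."""
        from topocurate.synth_fixtures import noisy_sphere

        noise = 0.05
        pts = noisy_sphere(40, noise, seed=5)
        filt = build_rips_filtration(
            PointCloud(pts, list(range(40))), max_dim=3, max_scale=1.2
        )
        pm = pseudo_manifoldize(filt)
        iv = top_k_by_length(_h2(pm), 1)[0]
        cyc = h2_cycle(pm, iv)
        cyc.validate(pm)
        radii = np.linalg.norm(pts[sorted(cyc.vertex_set)], axis=1)
        assert np.all(np.abs(radii - 1.0) <= 3 * noise)

    @pytest.mark.parametrize("seed", [5, 6])
    def test_min_cut_minimality_small_pseudo_manifolds(self, seed):
        """On pseudo-manifolds with <= 60 triangles the min-cut weight
        equals the exhaustive minimum over 2-cycles containing the creator."""
        from topocurate.synth_fixtures import noisy_sphere

        pts = noisy_sphere(12, 0.03, seed=seed)
        filt = build_rips_filtration(
            PointCloud(pts, list(range(12))), max_dim=3, max_scale=1.4
        )
        pm = pseudo_manifoldize(filt)
        n_tris = sum(1 for s in pm.simplices if len(s) == 3)
        assert n_tris <= 60
        ivs = _h2(pm)
        if not ivs:
            pytest.skip("no finite H2 interval at this seed")
        for iv in top_k_by_length(ivs, 2):
            cyc = h2_cycle(pm, iv, weight_scheme="unit")
            tri_le_beta = [
                s for i, s in enumerate(pm.simplices)
                if len(s) == 3 and i <= iv.birth_index
            ]
            w, _ = min_two_cycle_through(tri_le_beta, iv.creator)
            assert len(cyc.simplices) == w

    def test_cut_value_matches_independent_max_flow(self, octahedron):
        """Sum of cut capacities equals the max-flow value from an
        independent augmenting-path routine."""
        import networkx as nx

        iv = min(_h2(octahedron), key=lambda x: x.birth_value)
        net = _build_dual_network(octahedron, iv, "unit")
        g = net.graph.copy()
        supersink = ("sink",)
        for node in net.sink_set:
            g.add_edge(supersink, node)
        cut_value, _ = nx.minimum_cut(g, net.source, supersink)
        big = 1e9
        capacity = {}
        for u, v, data in g.edges(data=True):
            c = data.get("capacity", big)
            c = big if math.isinf(c) else c
            capacity[(u, v)] = c
            capacity[(v, u)] = c
        flow = edmonds_karp(capacity, iv.death_index, supersink)
        assert flow == pytest.approx(cut_value)


class TestCyclesForIntervals:
    def test_empty(self, worked_filtration):
        cycles, failures = cycles_for_intervals(worked_filtration, [], 1)
        assert cycles == [] and failures == []

    def test_worked_example_three_cycles_boundary_zero(self, worked_filtration):
        ivs = _h1(worked_filtration)
        cycles, failures = cycles_for_intervals(worked_filtration, ivs, 1)
        assert len(cycles) == 3 and not failures
        for c in cycles:
            assert boundary_is_zero(c.simplices)

    def test_corrupt_interval_flagged_not_fatal(self, worked_filtration):
        ivs = _h1(worked_filtration)
        import copy

        bad = copy.deepcopy(ivs[0])
        bad.creator = (0, 1)  # a tree edge: no earlier path exists
        bad.birth_index = 4
        cycles, failures = cycles_for_intervals(worked_filtration, ivs + [bad], 1)
        assert len(cycles) == 3
        assert len(failures) == 1 and failures[0][0] is bad
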