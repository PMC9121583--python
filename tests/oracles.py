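"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: persistence is
re-derived with a set-based column reduction, set cover by subset
enumeration, minimal 2-cycles by GF(2) nullspace enumeration, and
max-flow by BFS augmenting paths.
"""

from __future__ import annotations

import itertools
from collections import defaultdict, deque


def naive_reduction(simplices: list[tuple]) -> tuple[set, set]:
    """Set-based Z/2 boundary reduction.

    Returns (pairs, essential) where pairs is a set of
    (birth_index, death_index) tuples and essential a set of unpaired
    birth indices.
    """
    index = {s: i for i, s in enumerate(simplices)}
    cols = []
    for s in simplices:
        if len(s) == 1:
            cols.append(set())
        else:
            cols.append({index[s[:i] + s[i + 1 :]] for i in range(len(s))})
    low_owner: dict[int, int] = {}
    pairs = set()
    paired = set()
    for j, col in enumerate(cols):
        while col and max(col) in low_owner:
            col ^= cols[low_owner[max(col)]]
        if col:
            piv = max(col)
            low_owner[piv] = j
            pairs.add((piv, j))
            paired.update((piv, j))
    essential = {i for i in range(len(simplices)) if i not in paired}
    return pairs, essential


def exhaustive_min_cover(sets: list[frozenset]) -> int:
    """Minimum set-cover size by enumerating all term subsets."""
    vocab = sorted({t for s in sets for t in s})
    for size in range(1, len(vocab) + 1):
        for combo in itertools.combinations(vocab, size):
            chosen = set(combo)
            if all(s & chosen for s in sets):
                return size
    raise ValueError("uncoverable input")


def gf2_cycle_space(triangles: list[tuple]) -> list[frozenset]:
    """Basis of the Z/2 2-cycle space of a triangle list.

    Gaussian elimination on the edge-by-triangle boundary matrix; each
    basis vector is returned as a frozenset of triangles.
    """
    edges = sorted({t[:i] + t[i + 1 :] for t in triangles for i in range(3)})
    erow = {e: i for i, e in enumerate(edges)}
    ncols = len(triangles)
    # column bitmasks over edge rows
    cols = []
    for t in triangles:
        mask = 0
        for i in range(3):
            mask |= 1 << erow[t[:i] + t[i + 1 :]]
        cols.append(mask)
    # track combinations: ident[j] = bitmask over original columns
    ident = [1 << j for j in range(ncols)]
    pivot_of_row: dict[int, int] = {}
    basis = []
    for j in range(ncols):
        col, comb = cols[j], ident[j]
        while col:
            r = col.bit_length() - 1
            if r not in pivot_of_row:
                break
            k = pivot_of_row[r]
            col ^= cols[k]
            comb ^= ident[k]
        cols[j], ident[j] = col, comb
        if col:
            pivot_of_row[col.bit_length() - 1] = j
        else:
            basis.append(
                frozenset(triangles[i] for i in range(ncols) if comb >> i & 1)
            )
    return basis


def min_two_cycle_through(
    triangles: list[tuple], creator: tuple, weights: dict | None = None
) -> tuple[float, frozenset] | None:
    """Minimum-weight Z/2 2-cycle containing ``creator``.

    Enumerates all 2^k elements of the cycle space (k must stay small);
    unit weights when ``weights`` is None.
    """
    basis = gf2_cycle_space(triangles)
    if len(basis) > 18:
        raise ValueError(f"cycle space too large to enumerate ({len(basis)})")
    best = None
    for r in range(1, len(basis) + 1):
        for combo in itertools.combinations(basis, r):
            cyc = frozenset()
            for b in combo:
                cyc = cyc ^ b
            if creator not in cyc:
                continue
            w = len(cyc) if weights is None else sum(weights[t] for t in cyc)
            if best is None or w < best[0]:
                best = (w, cyc)
    return best


def edmonds_karp(capacity: dict, source, sink) -> float:
    """Max-flow by BFS augmenting paths on a directed capacity dict."""
    cap = defaultdict(float)
    adj = defaultdict(set)
    for (u, v), c in capacity.items():
        cap[(u, v)] += c
        adj[u].add(v)
        adj[v].add(u)  # residual arc
    flow = 0.0
    while True:
        parent = {source: None}
        q = deque([source])
        while q and sink not in parent:
            u = q.popleft()
            for v in adj[u]:
                if v not in parent and cap[(u, v)] > 1e-12:
                    parent[v] = u
                    q.append(v)
        if sink not in parent:
            return flow
        # bottleneck
        bott = float("inf")
        v = sink
        while parent[v] is not None:
            u = parent[v]
            bott = min(bott, cap[(u, v)])
            v = u
        v = sink
        while parent[v] is not None:
            u = parent[v]
            cap[(u, v)] -= bott
            cap[(v, u)] += bott
            v = u
        flow += bott
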