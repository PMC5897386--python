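"""Graphlet degree vectors: per-node automorphism-orbit counts.

A graphlet is a small connected induced subgraph; an orbit is an
automorphism-equivalence class of node positions within a graphlet.  With
graphlets on 2-4 nodes there are 15 orbits (orbit 0 is the node degree, the
K3 node is orbit 3, and so on); extending to 5-node graphlets gives 73.

Counting enumerates every connected induced subgraph exactly once with the
ESU algorithm and classifies it against a table of graphlets built at import
time by brute force over all small connected graphs.  Graphlets are ordered
by (size, edge count, max degree, degree sequence), which reproduces the
conventional numbering of orbits 0-14; orbits within a graphlet are ordered
by a canonical node invariant, so the assignment is deterministic (for
5-node graphlets the within-table order is canonical for this package).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .containers import CooccurrenceNetwork, ValidationError

N_ORBITS = {3: 4, 4: 15, 5: 73}


# ---------------------------------------------------------------------------
# Graphlet/orbit table
# ---------------------------------------------------------------------------

def _edge_bits(n: int, edges: frozenset) -> int:
    bits = 0
    for k, (i, j) in enumerate(itertools.combinations(range(n), 2)):
        if frozenset((i, j)) in edges:
            bits |= 1 << k
    return bits


def _canonical_bits(n: int, edges: frozenset) -> int:
    best = None
    for perm in itertools.permutations(range(n)):
        permuted = frozenset(
            frozenset((perm[i], perm[j])) for e in edges for i, j in [tuple(e)]
        )
        bits = _edge_bits(n, permuted)
        if best is None or bits < best:
            best = bits
    return best


def _is_connected(n: int, edges: frozenset) -> bool:
    adj = {i: set() for i in range(n)}
    for e in edges:
        i, j = tuple(e)
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        for w in adj[stack.pop()]:
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return len(seen) == n


def _orbits_of(n: int, edges: frozenset) -> list[int]:
    """Automorphism orbit id (index of minimal equivalent node) per node."""
    orbit = list(range(n))
    for perm in itertools.permutations(range(n)):
        permuted = frozenset(
            frozenset((perm[i], perm[j])) for e in edges for i, j in [tuple(e)]
        )
        if permuted == edges:
            for i in range(n):
                orbit[perm[i]] = min(orbit[perm[i]], orbit[i])
    # compress until stable (orbit relation is transitive via generators)
    changed = True
    while changed:
        changed = False
        for i in range(n):
            if orbit[orbit[i]] < orbit[i]:
                orbit[i] = orbit[orbit[i]]
                changed = True
    return orbit


def _node_invariant(n: int, edges: frozenset, node: int) -> tuple:
    adj = {i: set() for i in range(n)}
    for e in edges:
        i, j = tuple(e)
        adj[i].add(j)
        adj[j].add(i)
    deg = {i: len(adj[i]) for i in range(n)}
    nb = tuple(sorted(deg[w] for w in adj[node]))
    nb2 = tuple(
        sorted(tuple(sorted(deg[z] for z in adj[w])) for w in adj[node])
    )
    return (deg[node], nb, nb2)


@dataclass(frozen=True)
class _GraphletInfo:
    size: int
    edge_count: int
    #: orbit id (global numbering) keyed by node invariant
    orbit_by_invariant: dict


@lru_cache(maxsize=None)
def _orbit_table(max_graphlet: int) -> dict:
    """Build {(size, canonical_bits): _GraphletInfo} for sizes 2..max."""
    if max_graphlet not in (3, 4, 5):
        raise ValidationError("max_graphlet must be 3, 4 or 5")
    table: dict = {}
    next_orbit = 0
    for n in range(2, max_graphlet + 1):
        graphlets = {}
        all_pairs = list(itertools.combinations(range(n), 2))
        for mask in range(1 << len(all_pairs)):
            edges = frozenset(
                frozenset(all_pairs[k]) for k in range(len(all_pairs)) if mask >> k & 1
            )
            if not edges or not _is_connected(n, edges):
                continue
            canon = _canonical_bits(n, edges)
            if canon not in graphlets:
                graphlets[canon] = edges
        def sort_key(item):
            canon, edges = item
            degs = [0] * n
            for e in edges:
                i, j = tuple(e)
                degs[i] += 1
                degs[j] += 1
            return (len(edges), max(degs), sorted(degs), canon)

        for canon, edges in sorted(graphlets.items(), key=sort_key):
            orbits = _orbits_of(n, edges)
            reps = sorted(set(orbits))
            inv_of_rep = {}
            for rep in reps:
                inv_of_rep[rep] = _node_invariant(n, edges, rep)
            # orbits within a graphlet ordered by their node invariant
            ordered = sorted(reps, key=lambda r: inv_of_rep[r])
            orbit_ids = {rep: next_orbit + k for k, rep in enumerate(ordered)}
            next_orbit += len(reps)
            inv_map = {}
            for rep in reps:
                inv = inv_of_rep[rep]
                if inv in inv_map and inv_map[inv] != orbit_ids[rep]:
                    raise AssertionError(
                        "node invariant does not separate orbits; refine it"
                    )
                inv_map[inv] = orbit_ids[rep]
            table[(n, canon)] = _GraphletInfo(
                size=n, edge_count=len(edges), orbit_by_invariant=inv_map
            )
    assert next_orbit == N_ORBITS[max_graphlet]
    return table


@lru_cache(maxsize=None)
def _degree_lookup(max_graphlet: int) -> dict:
    """Fast classification for graphlets on <= 4 nodes, where the pair
    (edge count, degree multiset) identifies the graphlet and the in-subgraph
    degree identifies the orbit.  Keys: (size, m, sorted degree tuple) ->
    {degree: orbit id}."""
    table = _orbit_table(max_graphlet)
    lookup: dict = {}
    for (n, canon), info in table.items():
        if n > 4:
            continue
        # reconstruct edges from canonical bits
        pairs = list(itertools.combinations(range(n), 2))
        edges = frozenset(
            frozenset(pairs[k]) for k in range(len(pairs)) if canon >> k & 1
        )
        degs = [0] * n
        for e in edges:
            i, j = tuple(e)
            degs[i] += 1
            degs[j] += 1
        by_degree = {}
        for node in range(n):
            inv = _node_invariant(n, edges, node)
            by_degree[degs[node]] = info.orbit_by_invariant[inv]
        lookup[(n, len(edges), tuple(sorted(degs)))] = by_degree
    return lookup


# ---------------------------------------------------------------------------
# Enumeration (ESU) and counting
# ---------------------------------------------------------------------------

def _adjacency(graph) -> tuple[list, dict]:
    if isinstance(graph, CooccurrenceNetwork):
        graph = graph.graph
    nodes = sorted(graph.nodes())
    index = {u: k for k, u in enumerate(nodes)}
    adj = [set() for _ in nodes]
    for u, v in graph.edges():
        if u == v:
            continue
        adj[index[u]].add(index[v])
        adj[index[v]].add(index[u])
    return nodes, adj


def _esu(adj: list[set], k: int):
    """Yield every connected induced subgraph on exactly k nodes once."""
    n = len(adj)
    for v in range(n):
        ext = {u for u in adj[v] if u > v}
        yield from _esu_extend(adj, [v], ext, v, k)


def _esu_extend(adj, sub, ext, v, k):
    if len(sub) == k:
        yield tuple(sub)
        return
    sub_neighbours = set().union(*(adj[u] for u in sub))
    ext = set(ext)
    while ext:
        w = ext.pop()
        new_ext = ext | {
            u for u in adj[w] if u > v and u not in sub and u not in sub_neighbours
        }
        yield from _esu_extend(adj, sub + [w], new_ext, v, k)


def _matrix_orbit_counts(adj: list[set]) -> np.ndarray:
    """Orbit counts 0-14 by per-edge accumulation with boolean vectors.

    Equivalent to exhaustive enumeration of connected induced subgraphs on
    up to 4 nodes (checked against the brute-force oracle) but runs in
    roughly O(E * n) instead of touching every subgraph.
    """
    n = len(adj)
    counts = np.zeros((n, 15), dtype=np.int64)
    amat = np.zeros((n, n), dtype=bool)
    for i, nb in enumerate(adj):
        amat[i, list(nb)] = True
    deg = amat.sum(axis=1).astype(np.int64)
    counts[:, 0] = deg
    a_int = amat.astype(np.int64)
    tri_per_node = ((a_int @ a_int) * a_int).sum(axis=1) // 2
    counts[:, 3] = tri_per_node
    counts[:, 2] = deg * (deg - 1) // 2 - tri_per_node
    counts[:, 1] = a_int @ (deg - 1) - 2 * tri_per_node

    o = counts  # alias; columns 4..14 accumulated below
    k4_acc = np.zeros(n, dtype=np.int64)
    edges = [(u, v) for u in range(n) for v in adj[u] if v > u]
    nodes_arange = np.arange(n)
    for u, v in edges:
        row_u, row_v = amat[u], amat[v]
        w_mask = row_u & row_v
        eu_mask = row_u & ~row_v
        eu_mask[v] = False
        ev_mask = row_v & ~row_u
        ev_mask[u] = False
        eu_idx = nodes_arange[eu_mask]
        ev_idx = nodes_arange[ev_mask]
        w_idx = nodes_arange[w_mask]
        m, eu, ev = len(w_idx), len(eu_idx), len(ev_idx)

        # P4: this is the central edge; C4: this is one of four base edges
        if eu and ev:
            cross = amat[np.ix_(eu_idx, ev_idx)]
            adj_ct = int(cross.sum())
            p4 = eu * ev - adj_ct
            o[u, 5] += p4
            o[v, 5] += p4
            o[eu_idx, 4] += ev - cross.sum(axis=1)
            o[ev_idx, 4] += eu - cross.sum(axis=0)
            o[u, 8] += adj_ct
            o[v, 8] += adj_ct
        elif eu:
            o[eu_idx, 4] += ev  # ev == 0, no-op kept for clarity
        # paw (pendant v at junction u) and claw (center u, leaf v)
        if eu:
            b = amat[np.ix_(eu_idx, eu_idx)]
            rows = b.sum(axis=1)
            e_in = int(rows.sum()) // 2
            o[v, 9] += e_in
            o[u, 11] += e_in
            o[eu_idx, 10] += rows
            o[v, 6] += eu * (eu - 1) // 2 - e_in
        if ev:
            b = amat[np.ix_(ev_idx, ev_idx)]
            rows = b.sum(axis=1)
            e_in = int(rows.sum()) // 2
            o[u, 9] += e_in
            o[v, 11] += e_in
            o[ev_idx, 10] += rows
            o[u, 6] += ev * (ev - 1) // 2 - e_in
        # diamond and K4 around the shared edge (u, v)
        if m:
            b = amat[np.ix_(w_idx, w_idx)]
            rows = b.sum(axis=1)
            k4e = int(rows.sum()) // 2
            o[w_idx, 12] += (m - 1) - rows
            dia = m * (m - 1) // 2 - k4e
            o[u, 13] += dia
            o[v, 13] += dia
            k4_acc[u] += k4e
            k4_acc[v] += k4e
    o[:, 8] //= 2
    o[:, 14] = k4_acc // 3
    # claw centers: independent triples within the neighbourhood
    for c in range(n):
        d = deg[c]
        if d < 3:
            continue
        nb_idx = nodes_arange[amat[c]]
        b = amat[np.ix_(nb_idx, nb_idx)]
        rows = b.sum(axis=1).astype(np.int64)
        t_c = int(rows.sum()) // 2
        cherries = int((rows * (rows - 1) // 2).sum())
        o[c, 7] = d * (d - 1) * (d - 2) // 6 - t_c * (d - 2) + cherries - o[c, 14]
    return counts


def graphlet_degree_vectors(graph, max_graphlet: int = 4) -> dict:
    """Per-node orbit-count vectors (graphlet degree vectors).

    Signs on edges are ignored: topology is taken from the unsigned simple
    graph.  Returns ``{node: ndarray of orbit counts}`` with
    ``N_ORBITS[max_graphlet]`` entries; orbit 0 is the node degree.
    """
    if max_graphlet == 4:
        nodes, adj = _adjacency(graph)
        counts = _matrix_orbit_counts(adj)
        return {node: counts[i] for i, node in enumerate(nodes)}
    table = _orbit_table(max_graphlet)
    nodes, adj = _adjacency(graph)
    n_orbits = N_ORBITS[max_graphlet]
    counts = np.zeros((len(nodes), n_orbits), dtype=np.int64)
    for i, neigh in enumerate(adj):
        counts[i, 0] = len(neigh)
    fast = _degree_lookup(max_graphlet) if max_graphlet >= 3 else {}
    for size in range(3, max_graphlet + 1):
        for sub in _esu(adj, size):
            degs = [sum(1 for b in sub if b in adj[a]) for a in sub]
            m = sum(degs) // 2
            if size <= 4:
                by_degree = fast[(size, m, tuple(sorted(degs)))]
                for u, d in zip(sub, degs):
                    counts[u, by_degree[d]] += 1
            else:
                local = {u: li for li, u in enumerate(sub)}
                edges = frozenset(
                    frozenset((local[a], local[b]))
                    for a, b in itertools.combinations(sub, 2)
                    if b in adj[a]
                )
                canon = _canonical_bits(size, edges)
                info = table[(size, canon)]
                for u in sub:
                    inv = _node_invariant(size, edges, local[u])
                    counts[u, info.orbit_by_invariant[inv]] += 1
    return {node: counts[i] for i, node in enumerate(nodes)}


def brute_force_orbit_counts(graph, max_graphlet: int = 4) -> dict:
    """Independent oracle: enumerate all node subsets of size 2..max and
    classify the connected induced ones.  Exponential; for tiny graphs."""
    table = _orbit_table(max_graphlet)
    nodes, adj = _adjacency(graph)
    counts = np.zeros((len(nodes), N_ORBITS[max_graphlet]), dtype=np.int64)
    for size in range(2, max_graphlet + 1):
        for sub in itertools.combinations(range(len(nodes)), size):
            local = {u: li for li, u in enumerate(sub)}
            edges = frozenset(
                frozenset((local[a], local[b]))
                for a, b in itertools.combinations(sub, 2)
                if b in adj[a]
            )
            if not edges or not _is_connected(size, edges):
                continue
            canon = _canonical_bits(size, edges)
            info = table[(size, canon)]
            for u in sub:
                inv = _node_invariant(size, edges, local[u])
                counts[u, info.orbit_by_invariant[inv]] += 1
    return {node: counts[i] for i, node in enumerate(nodes)}


# ---------------------------------------------------------------------------
# Signature similarity
# ---------------------------------------------------------------------------

def signature_similarity(u_sig, v_sig, weights=None) -> float:
    """Similarity in [0, 1] between two orbit-count vectors.

    ``D_i = w_i |log(u_i+1) - log(v_i+1)| / log(max(u_i, v_i) + 2)`` and the
    similarity is ``1 - sum(D_i) / sum(w_i)``; unit weights by default.
    """
    u = np.asarray(u_sig, dtype=float)
    v = np.asarray(v_sig, dtype=float)
    if u.shape != v.shape:
        raise ValidationError("signature vectors differ in length")
    w = np.ones_like(u) if weights is None else np.asarray(weights, dtype=float)
    d = w * np.abs(np.log(u + 1.0) - np.log(v + 1.0)) / np.log(np.maximum(u, v) + 2.0)
    return float(1.0 - d.sum() / w.sum())


def signature_similarity_matrix(
    sigs1: np.ndarray, sigs2: np.ndarray, weights=None
) -> np.ndarray:
    """Pairwise signature similarity between the rows of two GDV matrices."""
    u = np.log(np.asarray(sigs1, dtype=float) + 1.0)
    v = np.log(np.asarray(sigs2, dtype=float) + 1.0)
    raw1 = np.asarray(sigs1, dtype=float)
    raw2 = np.asarray(sigs2, dtype=float)
    w = np.ones(u.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    num = np.abs(u[:, None, :] - v[None, :, :])
    den = np.log(np.maximum(raw1[:, None, :], raw2[None, :, :]) + 2.0)
    d = (w * num / den).sum(axis=2)
    return 1.0 - d / w.sum()
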