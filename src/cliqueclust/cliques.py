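"""Exact clique-based clustering: maximal cliques, maximum clique,
paraclique, and k-clique communities.

Maximal cliques are enumerated with the Bron-Kerbosch algorithm using
degeneracy ordering for the outer loop and pivoting inside, which keeps the
recursion shallow on the sparse graphs produced by hard-thresholding
correlation matrices.  Everything downstream is deterministic: vertices are
processed in sorted order, clique lists are emitted in lexicographic order
of their sorted membership, and maximum-clique ties are broken by the
lexicographically least membership.

Paraclique grows a maximum-clique core by repeatedly "glomming" on the
first vertex (in lexicographic scan order, restarting after each addition)
that misses at most ``glom`` edges to the current members, emits the
result, deletes its vertices, and repeats while the residual maximum clique
is large enough.  Successive paracliques are therefore vertex-disjoint.

k-clique communities (clique percolation) are computed from maximal cliques
of size >= k: two maximal cliques are joined when they share at least k-1
vertices, and each connected component of that relation contributes the
union of its cliques.  This is equivalent to percolating over individual
k-cliques directly (two k-cliques adjacent iff they share k-1 vertices),
which the test suite verifies against a direct oracle.
"""

from __future__ import annotations

import networkx as nx

from .core import Clustering, InvalidInputError

__all__ = [
    "maximal_cliques",
    "maximum_clique",
    "paraclique",
    "k_clique_communities",
    "CliqueCapExceeded",
]

DEFAULT_MAX_CLIQUES = 10**6


class CliqueCapExceeded(RuntimeError):
    """The number of maximal cliques exceeded the configured cap."""


def _check_simple(g: nx.Graph) -> None:
    if g.is_directed() or g.is_multigraph():
        raise InvalidInputError("graph must be simple and undirected")
    if any(g.has_edge(v, v) for v in g):
        raise InvalidInputError("graph must not contain self-loops")


def _adjacency(g: nx.Graph) -> dict[str, set[str]]:
    return {v: set(g.neighbors(v)) - {v} for v in g}


def _degeneracy_order(adj: dict[str, set[str]]) -> list[str]:
    """Vertices in degeneracy order (repeatedly remove a min-degree vertex);
    ties broken by vertex name for determinism."""
    degree = {v: len(nb) for v, nb in adj.items()}
    buckets: dict[int, list[str]] = {}
    for v in sorted(adj, reverse=True):  # reversed so pops yield sorted order
        buckets.setdefault(degree[v], []).append(v)
    for d in buckets:
        buckets[d].sort(reverse=True)
    removed: set[str] = set()
    order: list[str] = []
    while len(order) < len(adj):
        d = 0  # lowest non-empty bucket; entries may be stale (lazy deletion)
        while d not in buckets or not buckets[d]:
            d += 1
        v = buckets[d].pop()
        if v in removed or degree[v] != d:
            continue
        removed.add(v)
        order.append(v)
        for u in adj[v]:
            if u not in removed:
                degree[u] -= 1
                buckets.setdefault(degree[u], []).append(u)
    return order


def _bron_kerbosch_pivot(
    adj: dict[str, set[str]],
    r: list[str],
    p: set[str],
    x: set[str],
    out: list[frozenset[str]],
    cap: int,
) -> None:
    if not p and not x:
        out.append(frozenset(r))
        if len(out) > cap:
            raise CliqueCapExceeded(
                f"more than {cap} maximal cliques; raise max_cliques or the threshold"
            )
        return
    # pivot: vertex of P|X covering the most of P; ties by name (determinism)
    pivot = max(sorted(p | x), key=lambda u: len(adj[u] & p))
    for v in sorted(p - adj[pivot]):
        nb = adj[v]
        r.append(v)
        _bron_kerbosch_pivot(adj, r, p & nb, x & nb, out, cap)
        r.pop()
        p.remove(v)
        x.add(v)


def _enumerate_maximal(g: nx.Graph, cap: int) -> list[frozenset[str]]:
    adj = _adjacency(g)
    out: list[frozenset[str]] = []
    order = _degeneracy_order(adj)
    pos = {v: i for i, v in enumerate(order)}
    for v in order:
        later = {u for u in adj[v] if pos[u] > pos[v]}
        earlier = {u for u in adj[v] if pos[u] < pos[v]}
        _bron_kerbosch_pivot(adj, [v], later, earlier, out, cap)
    out.sort(key=lambda c: tuple(sorted(c)))
    return out


def maximal_cliques(
    g: nx.Graph, min_size: int = 3, max_cliques: int = DEFAULT_MAX_CLIQUES
) -> Clustering:
    """All inclusion-maximal cliques with at least ``min_size`` vertices.

    Output order is lexicographic by sorted membership.  Exceeding
    ``max_cliques`` raises :class:`CliqueCapExceeded` rather than silently
    truncating: maximal-clique counts grow exponentially on dense graphs.
    """
    _check_simple(g)
    cliques = [c for c in _enumerate_maximal(g, max_cliques) if len(c) >= min_size]
    return Clustering(
        method="maximal_clique",
        parameters={"min_size": min_size},
        clusters=cliques,
    )


def maximum_clique(g: nx.Graph, max_cliques: int = DEFAULT_MAX_CLIQUES) -> frozenset[str]:
    """A largest clique; ties broken by lexicographically least membership.

    Returns the empty set for an empty graph.
    """
    _check_simple(g)
    if g.number_of_nodes() == 0:
        return frozenset()
    best: frozenset[str] | None = None
    best_key: tuple = ()
    for c in _enumerate_maximal(g, max_cliques):
        key = (-len(c), tuple(sorted(c)))
        if best is None or key < best_key:
            best, best_key = c, key
    assert best is not None
    return best


def paraclique(
    g: nx.Graph,
    glom: int = 5,
    min_core: int = 3,
    max_cliques: int = DEFAULT_MAX_CLIQUES,
) -> Clustering:
    """Iterated maximum-clique cores expanded by the glom rule.

    Each round takes the maximum clique of the working graph as the core,
    then repeatedly scans non-members in lexicographic order and admits the
    first vertex with at most ``glom`` non-neighbours among current members
    (restarting the scan after each admission) until no vertex qualifies.
    The paraclique is emitted, its vertices removed, and the process
    repeats while the residual maximum clique has >= ``min_core`` vertices.
    """
    _check_simple(g)
    if glom < 0:
        raise InvalidInputError("glom must be >= 0")
    if min_core < 3:
        raise InvalidInputError("min_core must be >= 3")
    work = g.copy()
    adj = _adjacency(work)
    out: list[frozenset[str]] = []
    while True:
        core = maximum_clique(work, max_cliques=max_cliques)
        if len(core) < min_core:
            break
        members = set(core)
        candidates = sorted(set(work.nodes()) - members)
        changed = True
        while changed:
            changed = False
            for v in candidates:
                if v in members:
                    continue
                missing = sum(1 for u in members if u not in adj[v])
                if missing <= glom:
                    members.add(v)
                    changed = True
                    break  # restart the lexicographic scan
        out.append(frozenset(members))
        work.remove_nodes_from(members)
        adj = _adjacency(work)
    return Clustering(
        method="paraclique",
        parameters={"glom": glom, "min_core": min_core},
        clusters=out,
    )


def k_clique_communities(
    g: nx.Graph, k: int, max_cliques: int = DEFAULT_MAX_CLIQUES, _debug_min_k: int = 3
) -> Clustering:
    """Clique-percolation communities built from maximal cliques.

    Maximal cliques of size >= k seed a union-find; two cliques merge when
    they share >= k-1 vertices; communities are the unions of merged
    cliques.  Communities may overlap (in fewer than k-1 vertices).  A k
    above the maximum clique size yields an empty clustering.  ``k = 2``
    (permitted when ``_debug_min_k`` is lowered) reduces to connected
    components and exists for debugging.
    """
    _check_simple(g)
    if k < _debug_min_k or k < 2:
        raise InvalidInputError(f"k must be >= {max(_debug_min_k, 2)}")
    cliques = [c for c in _enumerate_maximal(g, max_cliques) if len(c) >= k]
    parent = list(range(len(cliques)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    for i in range(len(cliques)):
        for j in range(i + 1, len(cliques)):
            if len(cliques[i] & cliques[j]) >= k - 1:
                union(i, j)

    groups: dict[int, set[str]] = {}
    for i, c in enumerate(cliques):
        groups.setdefault(find(i), set()).update(c)
    communities = sorted(
        (frozenset(s) for s in groups.values()), key=lambda c: tuple(sorted(c))
    )
    return Clustering(
        method="k_clique_communities", parameters={"k": k}, clusters=list(communities)
    )
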