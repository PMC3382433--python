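"""Independent brute-force / transliteration oracles used by the tests.

Everything here is deliberately naive: exhaustive subset enumeration for
cliques, literal restatements of the greedy loops, and from-scratch
entropy sums.  None of it shares code with the package implementation.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import networkx as nx


def brute_maximal_cliques(g: nx.Graph) -> set[frozenset]:
    """All inclusion-maximal cliques by enumerating every vertex subset."""
    nodes = sorted(g.nodes())
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adjmask = [0] * n
    for u, v in g.edges():
        if u == v:
            continue
        adjmask[idx[u]] |= 1 << idx[v]
        adjmask[idx[v]] |= 1 << idx[u]
    cliques = []
    for s in range(1, 1 << n):
        t = s
        ok = True
        while t:
            v = (t & -t).bit_length() - 1
            t &= t - 1
            if (adjmask[v] | (1 << v)) & s != s:
                ok = False
                break
        if ok:
            cliques.append(s)
    clique_set = set(cliques)
    out = set()
    for s in cliques:
        if any(
            not (s >> v) & 1 and (s | (1 << v)) in clique_set for v in range(n)
        ):
            continue
        out.add(frozenset(nodes[i] for i in range(n) if (s >> i) & 1))
    return out


def brute_maximum_clique(g: nx.Graph) -> frozenset:
    """Largest clique, ties by lexicographically least sorted membership."""
    if g.number_of_nodes() == 0:
        return frozenset()
    best = min(
        brute_maximal_cliques(g), key=lambda c: (-len(c), tuple(sorted(c)))
    )
    return best


def brute_paraclique(g: nx.Graph, glom: int, min_core: int = 3) -> list[frozenset]:
    """Literal restatement of the core-plus-glom fixpoint loop."""
    work = set(g.nodes())
    out = []
    while True:
        sub = g.subgraph(work)
        core = brute_maximum_clique(sub)
        if len(core) < min_core:
            break
        members = set(core)
        while True:
            added = False
            for v in sorted(work - members):
                missing = sum(1 for u in members if not g.has_edge(u, v))
                if missing <= glom:
                    members.add(v)
                    added = True
                    break
            if not added:
                break
        out.append(frozenset(members))
        work -= members
    return out


def direct_k_clique_communities(g: nx.Graph, k: int) -> set[frozenset]:
    """Percolate over individual k-cliques (not maximal cliques)."""
    kcliques = [
        frozenset(c)
        for c in itertools.combinations(sorted(g.nodes()), k)
        if all(g.has_edge(u, v) for u, v in itertools.combinations(c, 2))
    ]
    perc = nx.Graph()
    perc.add_nodes_from(range(len(kcliques)))
    for i, j in itertools.combinations(range(len(kcliques)), 2):
        if len(kcliques[i] & kcliques[j]) >= k - 1:
            perc.add_edge(i, j)
    out = set()
    for comp in nx.connected_components(perc):
        members = set()
        for i in comp:
            members |= kcliques[i]
        out.add(frozenset(members))
    return out


def loop_qt_clust(dissim, ids, max_diameter) -> list[frozenset]:
    """Literal grow-emit-remove restatement of QT Clust.

    Growth adds the gene with the smallest maximum dissimilarity to current
    members (lowest index on ties) while that stays within the diameter.
    """
    n = len(ids)
    remaining = list(range(n))
    clusters = []
    while remaining:
        best = None
        for seed in remaining:
            members = [seed]
            while True:
                cand = None
                for j in remaining:
                    if j in members:
                        continue
                    far = max(dissim[j][m] for m in members)
                    if cand is None or far < cand[0]:
                        cand = (far, j)
                if cand is None or cand[0] > max_diameter:
                    break
                members.append(cand[1])
            if best is None or len(members) > len(best):
                best = members
        clusters.append(frozenset(ids[i] for i in best))
        remaining = [i for i in remaining if ids[i] not in clusters[-1]]
    return clusters


def loop_cast(s, ids, t) -> list[frozenset]:
    """Literal add/remove restatement of CAST; s is |r| with zero diagonal."""
    n = len(ids)
    unassigned = set(range(n))
    clusters = []
    while unassigned:
        pool = sorted(unassigned)
        seed = max(pool, key=lambda v: (sum(s[v][u] for u in pool), -v))
        # ties: lowest index -> max over (total, -v) picks lowest v on ties
        members = {seed}
        unassigned.remove(seed)
        while True:
            changed = False
            while unassigned:
                cand = sorted(unassigned)
                v = max(cand, key=lambda u: (sum(s[u][m] for m in members), -u))
                if sum(s[v][m] for m in members) >= t * len(members):
                    members.add(v)
                    unassigned.remove(v)
                    changed = True
                else:
                    break
            while len(members) > 1:
                mem = sorted(members)
                v = min(mem, key=lambda u: (sum(s[u][m] for m in members if m != u), u))
                if sum(s[v][m] for m in members if m != v) < t * (len(members) - 1):
                    members.remove(v)
                    unassigned.add(v)
                    changed = True
                else:
                    break
            if not changed:
                break
        clusters.append(frozenset(ids[i] for i in members))
    return clusters


def entropy_vi(labels_a: dict, labels_b: dict, genes) -> float:
    """H(A) + H(B) - 2 I(A;B) from scratch over the given genes (nats)."""
    genes = list(genes)
    n = len(genes)
    ca = Counter(labels_a[g] for g in genes)
    cb = Counter(labels_b[g] for g in genes)
    cab = Counter((labels_a[g], labels_b[g]) for g in genes)
    ha = -sum((c / n) * math.log(c / n) for c in ca.values())
    hb = -sum((c / n) * math.log(c / n) for c in cb.values())
    mi = sum(
        (c / n) * math.log((c / n) / ((ca[i] / n) * (cb[j] / n)))
        for (i, j), c in cab.items()
    )
    return ha + hb - 2 * mi


def best_category_match(cluster, categories, universe, min_match=2):
    """Loop-over-all-categories scoring oracle; returns (jaccard, category)."""
    restricted = set(cluster) & set(universe)
    best = (0.0, None)
    for cat in sorted(categories):
        genes = set(categories[cat])
        tp = len(restricted & genes)
        if tp < min_match:
            continue
        fn = len(genes - restricted)
        fp = len(restricted - genes)
        j = tp / (tp + fp + fn)
        if j > best[0]:
            best = (j, cat)
    return best


def rank_quartiles(values: dict[str, float]) -> dict[str, int]:
    """Competition-rank quartile assignment oracle for one bin."""
    M = len(values)
    out = {}
    for m, v in values.items():
        rank = 1 + sum(1 for w in values.values() if w > v)
        out[m] = math.ceil(4 * rank / M)
    return out
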