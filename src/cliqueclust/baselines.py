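"""QT Clust and CAST implementations plus adapters for commodity
partitioning methods (k-means and hierarchical agglomeration).

QT Clust ("quality threshold") grows a candidate cluster for every seed
gene by repeatedly adding the gene that least increases the cluster
diameter (the maximum pairwise dissimilarity) while the diameter stays
within ``max_diameter``; the largest candidate is emitted, its genes
removed, and the process repeats until no genes remain.  The default
dissimilarity is 1 - |r| so that "diameter" lives on the same scale as the
correlation machinery.

CAST ("cluster affinity search technique") is a heuristic for cluster
editing: open a cluster, alternately add the unassigned gene of highest
affinity while its affinity is at least t times the cluster size, and
remove the member of lowest affinity while its affinity (to the other
members) falls below t times the remaining size; close the cluster at
stability.  Affinities are summed unthresholded |r| values.  Seeding and
tie-breaks are fixed (maximum total affinity, then lowest index) so runs
are deterministic.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from .core import (
    CapabilityError,
    Clustering,
    CorrelationGraph,
    ExpressionMatrix,
    InvalidInputError,
)
from .io import read_clusters as import_membership  # re-export; shared format

__all__ = ["qt_clust", "cast", "run_adapter", "import_membership", "ADAPTER_METHODS"]

_LINKAGE = {"ward": "ward", "average": "average", "complete": "complete", "mcquitty": "weighted"}
ADAPTER_METHODS = ("kmeans", "ward", "average", "complete", "mcquitty", "som")


def qt_clust(
    dissim: np.ndarray,
    gene_ids: Sequence[str],
    max_diameter: float,
) -> Clustering:
    """Quality-threshold clustering on a pairwise dissimilarity matrix.

    Emits a partition of all genes; trailing singletons are allowed.
    Every emitted cluster has diameter <= ``max_diameter``.
    """
    dissim = np.asarray(dissim, dtype=float)
    n = len(gene_ids)
    if dissim.shape != (n, n):
        raise InvalidInputError("dissimilarity matrix must match gene_ids")
    if not np.allclose(dissim, dissim.T):
        raise InvalidInputError("dissimilarity must be symmetric")
    if np.any(dissim < 0):
        raise InvalidInputError("dissimilarity must be non-negative")
    if max_diameter <= 0:
        raise InvalidInputError("max_diameter must be > 0")

    remaining = list(range(n))
    clusters: list[frozenset[str]] = []
    while remaining:
        idx = np.array(remaining)
        best_members: list[int] | None = None
        for seed in remaining:
            members = [seed]
            # farthest[j] = max dissimilarity from candidate j to members
            farthest = dissim[seed, idx].copy()
            in_cluster = idx == seed
            while True:
                open_mask = ~in_cluster
                if not open_mask.any():
                    break
                new_diam = np.where(open_mask, farthest, np.inf)
                j = int(np.argmin(new_diam))  # lowest index on ties
                if new_diam[j] > max_diameter:
                    break
                g = int(idx[j])
                members.append(g)
                in_cluster[j] = True
                farthest = np.maximum(farthest, dissim[g, idx])
            if best_members is None or len(members) > len(best_members):
                best_members = members  # ties: earliest (lowest) seed wins
        assert best_members is not None
        clusters.append(frozenset(gene_ids[i] for i in best_members))
        chosen = set(best_members)
        remaining = [i for i in remaining if i not in chosen]
    return Clustering(
        method="qt_clust", parameters={"max_diameter": max_diameter}, clusters=clusters
    )


def cast(corr: CorrelationGraph, t: float, max_iter_factor: int = 200) -> Clustering:
    """CAST affinity clustering on an unthresholded correlation matrix.

    ``t`` in (0, 1) is the affinity threshold.  Returns a partition
    covering all genes.  The add/remove loop can in principle cycle; a
    generous iteration cap closes the cluster if that happens.
    """
    if not (0.0 < t < 1.0):
        raise InvalidInputError("CAST threshold must lie in (0, 1)")
    s = np.abs(corr.corr).copy()
    np.fill_diagonal(s, 0.0)  # affinity never counts self-similarity
    n = corr.n_genes
    unassigned = set(range(n))
    clusters: list[frozenset[str]] = []
    while unassigned:
        pool = sorted(unassigned)
        # seed: maximum total affinity to the other unassigned genes
        totals = s[np.ix_(pool, pool)].sum(axis=1)
        seed = pool[int(np.argmax(totals))]
        members: set[int] = {seed}
        unassigned.remove(seed)
        aff = s[seed].copy()  # affinity of every gene to current members
        iters = 0
        cap = max_iter_factor * n
        changed = True
        while changed and iters < cap:
            changed = False
            # add phase: highest-affinity unassigned gene, while it qualifies
            while unassigned:
                cand = sorted(unassigned)
                a = aff[cand]
                j = int(np.argmax(a))
                v = cand[j]
                if a[j] >= t * len(members):
                    members.add(v)
                    unassigned.remove(v)
                    aff += s[v]
                    changed = True
                    iters += 1
                else:
                    break
            # remove phase: lowest-affinity member, while it disqualifies
            while len(members) > 1:
                mem = sorted(members)
                a = aff[mem]
                j = int(np.argmin(a))
                v = mem[j]
                if a[j] < t * (len(members) - 1):
                    members.remove(v)
                    unassigned.add(v)
                    aff -= s[v]
                    changed = True
                    iters += 1
                else:
                    break
        clusters.append(frozenset(corr.gene_ids[i] for i in sorted(members)))
    return Clustering(method="cast", parameters={"t": t}, clusters=clusters)


def _impute_rows(expr: ExpressionMatrix) -> np.ndarray:
    """Mean-impute missing entries per gene (backends need complete data)."""
    x = expr.values.copy()
    row_mean = np.nanmean(np.where(expr.missing_mask, np.nan, x), axis=1)
    row_mean = np.where(np.isnan(row_mean), 0.0, row_mean)
    rows, cols = np.nonzero(expr.missing_mask)
    x[rows, cols] = row_mean[rows]
    return x


def run_adapter(
    method: str,
    expr: ExpressionMatrix,
    n_clusters: int | None = None,
    avg_cluster_size: int | None = None,
    seed: int = 0,
) -> Clustering:
    """Run a commodity partitioning backend and wrap it as a Clustering.

    Either ``n_clusters`` or ``avg_cluster_size`` must be given; the latter
    sets k = n_genes // avg_cluster_size (the usual way cluster counts are
    parameterised when only an average size is of interest).
    """
    if method not in ADAPTER_METHODS:
        raise InvalidInputError(f"unknown adapter method {method!r}")
    if method == "som":
        raise CapabilityError(
            "no self-organising-map backend is installed; "
            "import its membership lists with import_membership() instead"
        )
    if (n_clusters is None) == (avg_cluster_size is None):
        raise InvalidInputError("give exactly one of n_clusters / avg_cluster_size")
    if n_clusters is None:
        assert avg_cluster_size is not None
        if avg_cluster_size < 1:
            raise InvalidInputError("avg_cluster_size must be >= 1")
        n_clusters = max(1, expr.n_genes // avg_cluster_size)
    if not (1 <= n_clusters <= expr.n_genes):
        raise InvalidInputError("n_clusters must be in [1, n_genes]")

    x = _impute_rows(expr)
    if method == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed)
        labels = km.fit_predict(x)
    else:
        if expr.n_genes < 2:
            labels = np.zeros(expr.n_genes, dtype=int)
        else:
            z = sch.linkage(x, method=_LINKAGE[method], metric="euclidean")
            labels = sch.fcluster(z, t=n_clusters, criterion="maxclust") - 1

    groups: dict[int, set[str]] = {}
    for gene, lab in zip(expr.gene_ids, labels):
        groups.setdefault(int(lab), set()).add(gene)
    clusters = [frozenset(g) for _, g in sorted(groups.items())]
    return Clustering(
        method=method,
        parameters={"n_clusters": n_clusters, "seed": seed},
        clusters=clusters,
    )
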