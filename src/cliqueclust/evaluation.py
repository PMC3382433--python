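"""Annotation-driven cluster scoring and clustering comparison.

Each cluster is scored against every category of an annotation source:
only categories sharing at least ``min_match`` genes (default 2) with the
cluster qualify, cluster genes absent from the source's universe are
ignored, and the Jaccard similarity tp / (tp + fp + fn) of the best
qualifying category is assigned to the cluster (fn counted genome-wide
within the source).  Per parameter setting and size bin, the top five
cluster scores are averaged (AT5); the best AT5 over a method's parameter
sweep is its BAT5 for that bin.  Methods are then ranked by quartile of
their BAT5 within each bin and by the average quartile over populated
bins.  Two further comparisons: "prominent annotations" (categories that
ever scored above a cutoff, and how well each method recovers them) and
the variation-of-information distance between disjoint clusterings
(natural logarithms; 0 iff identical).

No multiple-testing correction is applied anywhere: these are descriptive
similarity scores, not enrichment p-values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import AnnotationCollection, Clustering, ClusterScore, InvalidInputError

__all__ = [
    "DEFAULT_BINS",
    "SizeBins",
    "jaccard",
    "score_cluster",
    "score_clustering",
    "at5",
    "bat5",
    "quartile_rank",
    "prominent_annotations",
    "variation_of_information",
    "cluster_count_size_summary",
    "OverlapError",
]


class OverlapError(InvalidInputError):
    """A partition-only comparison was given overlapping clusters."""


@dataclass(frozen=True)
class SizeBins:
    """Cluster-size strata; clusters outside all bins are not scored."""

    edges: tuple[tuple[int, int], ...] = ((3, 10), (11, 100), (101, 1000))
    names: tuple[str, ...] = ("small", "medium", "large")

    def bin_of(self, size: int) -> str | None:
        for (lo, hi), name in zip(self.edges, self.names):
            if lo <= size <= hi:
                return name
        return None


DEFAULT_BINS = SizeBins()


def jaccard(a: Iterable[str], b: Iterable[str]) -> float:
    """|A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def score_cluster(
    cluster: Iterable[str],
    *collections: AnnotationCollection,
    min_match: int = 2,
    cluster_id: str = "cluster",
) -> ClusterScore:
    """Best-Jaccard annotation match for one cluster.

    Scored independently against each collection (cluster genes outside a
    collection's universe are ignored for that collection); the overall
    best is returned.  Ties go to the lexicographically least category ID
    within a collection, and to the earlier-listed collection across
    collections.  With no qualifying category the score is 0 and
    ``best_category`` is unset.
    """
    if not collections:
        raise InvalidInputError("at least one annotation collection is required")
    cluster = frozenset(cluster)
    best: ClusterScore | None = None
    for ann in collections:
        universe = ann.universe
        restricted = cluster & universe
        for cat in sorted(ann.categories):
            genes = ann.categories[cat]
            tp = len(restricted & genes)
            if tp < min_match:
                continue
            fn = len(genes - restricted)
            fp = len(restricted - genes)
            j = tp / (tp + fp + fn)
            if best is None or j > best.jaccard:
                best = ClusterScore(
                    cluster_id=cluster_id,
                    size=len(cluster),
                    jaccard=j,
                    best_category=cat,
                    source=ann.source,
                    tp=tp,
                    fp=fp,
                    fn=fn,
                )
    if best is None:
        return ClusterScore(cluster_id=cluster_id, size=len(cluster), jaccard=0.0)
    return best


def score_clustering(
    clustering: Clustering,
    *collections: AnnotationCollection,
    min_match: int = 2,
    bins: SizeBins = DEFAULT_BINS,
) -> pd.DataFrame:
    """Score every binnable cluster; returns a tidy per-cluster table."""
    rows = []
    for cid, genes in zip(clustering.ids, clustering.clusters):
        b = bins.bin_of(len(genes))
        if b is None:
            continue
        s = score_cluster(genes, *collections, min_match=min_match, cluster_id=cid)
        rows.append(
            {
                "cluster_id": cid,
                "size": len(genes),
                "bin": b,
                "jaccard": s.jaccard,
                "best_category": s.best_category if s.best_category is not None else "",
                "source": s.source if s.source is not None else "",
                "tp": s.tp,
                "fp": s.fp,
                "fn": s.fn,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "size", "bin", "jaccard",
            "best_category", "source", "tp", "fp", "fn",
        ],
    )


def at5(scores: Sequence[float | ClusterScore], top: int = 5) -> tuple[float | None, bool]:
    """Average of the top-``top`` Jaccard scores in one size bin.

    Returns ``(value, underfilled)``.  With fewer than ``top`` scores the
    available ones are averaged and ``underfilled`` is True; an empty bin
    gives ``(None, True)`` (rendered 0.0 in summary tables).
    """
    vals = sorted(
        (s.jaccard if isinstance(s, ClusterScore) else float(s)) for s in scores
    )[::-1]
    if not vals:
        return None, True
    chosen = vals[:top]
    return sum(chosen) / len(chosen), len(vals) < top


def bat5(per_parameter_at5: Mapping[str, float | None]) -> tuple[float, str] | None:
    """Best AT5 over a parameter sweep and the parameter achieving it.

    ``None`` AT5 entries (empty bins) are skipped; ties go to the first
    parameter in sweep (mapping) order.  Returns None when every entry is
    absent; raises on an empty map.
    """
    if not per_parameter_at5:
        raise InvalidInputError("BAT5 requires a non-empty AT5 map")
    best: tuple[float, str] | None = None
    for param, val in per_parameter_at5.items():
        if val is None:
            continue
        if best is None or val > best[0]:
            best = (float(val), param)
    return best


def quartile_rank(
    bat5_table: Mapping[str, Mapping[str, float | None]],
    bins: SizeBins = DEFAULT_BINS,
) -> pd.DataFrame:
    """Rank methods by BAT5 quartile within each size bin.

    ``bat5_table`` maps method -> bin name -> BAT5 (None for an empty
    bin).  Within each bin, methods with a BAT5 are ranked descending
    (ties share the better rank) and assigned quartile
    ceil(4 * rank / M); the average quartile is taken over the bins a
    method populated.  Empty-bin cells render BAT5 0.0 with no quartile.
    Output is sorted by average quartile, then mean BAT5 descending, then
    method name.
    """
    methods = list(bat5_table)
    quart: dict[str, dict[str, int | None]] = {m: {} for m in methods}
    for b in bins.names:
        present = [(m, bat5_table[m].get(b)) for m in methods]
        vals = {m: v for m, v in present if v is not None}
        M = len(vals)
        for m in methods:
            v = vals.get(m)
            if v is None:
                quart[m][b] = None
            else:
                rank = 1 + sum(1 for w in vals.values() if w > v)
                quart[m][b] = math.ceil(4 * rank / M)
    rows = []
    for m in methods:
        qs = [q for q in quart[m].values() if q is not None]
        bvals = [v for v in (bat5_table[m].get(b) for b in bins.names) if v is not None]
        row: dict[str, object] = {"method": m}
        row["avg_quartile"] = round(sum(qs) / len(qs), 4) if qs else float("nan")
        for b in bins.names:
            v = bat5_table[m].get(b)
            row[f"quartile_{b}"] = quart[m][b] if quart[m][b] is not None else ""
            row[f"bat5_{b}"] = round(v, 4) if v is not None else 0.0
        row["_mean_bat5"] = sum(bvals) / len(bvals) if bvals else 0.0
        rows.append(row)
    df = pd.DataFrame(rows)
    df = df.sort_values(
        by=["avg_quartile", "_mean_bat5", "method"], ascending=[True, False, True]
    ).drop(columns="_mean_bat5")
    return df.reset_index(drop=True)


def prominent_annotations(
    scores_by_method: Mapping[str, Iterable[ClusterScore]],
    cutoff: float = 0.25,
) -> tuple[list[str], dict[str, float]]:
    """Consensus metric over categories that ever scored above ``cutoff``.

    A category is selected when some cluster in some run had it as best
    match with Jaccard strictly above ``cutoff``.  Each method is then
    summarised by its best score on each selected category (0 when it
    never matched it), averaged over all selected categories.
    """
    if not (0.0 < cutoff < 1.0):
        raise InvalidInputError("cutoff must lie in (0, 1)")
    best_per: dict[tuple[str, str], float] = {}  # (method, category) -> best jaccard
    cat_max: dict[str, float] = {}
    for method, scores in scores_by_method.items():
        for s in scores:
            if s.best_category is None:
                continue
            key = (method, s.best_category)
            if s.jaccard > best_per.get(key, 0.0):
                best_per[key] = s.jaccard
            if s.jaccard > cat_max.get(s.best_category, 0.0):
                cat_max[s.best_category] = s.jaccard
    selected = sorted(c for c, v in cat_max.items() if v > cutoff)
    means: dict[str, float] = {}
    for method in scores_by_method:
        if selected:
            means[method] = sum(
                best_per.get((method, c), 0.0) for c in selected
            ) / len(selected)
        else:
            means[method] = 0.0
    return selected, means


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def variation_of_information(
    a: Clustering,
    b: Clustering,
    include_unclustered: bool = False,
) -> float:
    """VI(A, B) = H(A) + H(B) - 2 I(A; B) in nats.

    Both clusterings must be disjoint (the metric is undefined for
    overlapping methods such as maximal clique).  By default the metric is
    evaluated over the intersection of the two covered gene sets; with
    ``include_unclustered`` each clustering gets an extra pseudo-cluster
    holding the genes of the union it does not cover.
    """
    for name, c in (("first", a), ("second", b)):
        if not c.is_disjoint():
            raise OverlapError(
                f"variation of information is not applicable: the {name} "
                f"clustering ({c.method}) has overlapping clusters"
            )
    cov_a, cov_b = a.covered_genes(), b.covered_genes()
    genes = sorted((cov_a | cov_b) if include_unclustered else (cov_a & cov_b))
    if not genes:
        raise InvalidInputError("the clusterings cover no common genes")
    mem_a, mem_b = a.membership(), b.membership()
    la = np.array([mem_a.get(g, len(a)) for g in genes])
    lb = np.array([mem_b.get(g, len(b)) for g in genes])
    table = np.zeros((la.max() + 1, lb.max() + 1))
    np.add.at(table, (la, lb), 1.0)
    n = table.sum()
    ha = _entropy(table.sum(axis=1))
    hb = _entropy(table.sum(axis=0))
    # mutual information from the joint table
    nz = table > 0
    pij = table[nz] / n
    pi = (table.sum(axis=1) / n)[np.nonzero(nz)[0]]
    pj = (table.sum(axis=0) / n)[np.nonzero(nz)[1]]
    mi = float((pij * np.log(pij / (pi * pj))).sum())
    vi = ha + hb - 2.0 * mi
    # identical restricted partitions must give exactly 0; snap fp residue
    return 0.0 if abs(vi) < 1e-12 else max(vi, 0.0)


def cluster_count_size_summary(
    clusterings: Mapping[str, Clustering],
    bins: SizeBins = DEFAULT_BINS,
) -> pd.DataFrame:
    """Per method and size bin: number of clusters and mean cluster size.

    Zero-cluster cells are reported explicitly (count 0, mean size 0).
    """
    rows = []
    for method, clustering in clusterings.items():
        by_bin: dict[str, list[int]] = {b: [] for b in bins.names}
        for size in clustering.sizes():
            b = bins.bin_of(size)
            if b is not None:
                by_bin[b].append(size)
        for b in bins.names:
            sizes = by_bin[b]
            rows.append(
                {
                    "method": method,
                    "bin": b,
                    "n_clusters": len(sizes),
                    "mean_size": round(sum(sizes) / len(sizes), 4) if sizes else 0.0,
                }
            )
    return pd.DataFrame(rows, columns=["method", "bin", "n_clusters", "mean_size"])
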