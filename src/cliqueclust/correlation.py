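"""Absolute-Pearson correlation matrices and hard-thresholded graphs.

Correlations are computed on pairwise-complete samples (both genes
measured).  Pairs sharing too few measurements (default: five or fewer)
are set to zero, as are pairs where either gene has zero variance on the
shared samples, so such pairs never form edges.  By default the absolute
value is taken; a signed mode is available for methods that need it.

Thresholding at t keeps edge (i, j) iff corr[i, j] > t (strict), yielding
a simple undirected graph; higher thresholds give fewer edges.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from .core import CorrelationGraph, ExpressionMatrix, InvalidInputError

__all__ = ["compute_correlations", "threshold_graph", "dissimilarity_matrix"]

DEFAULT_MIN_SHARED = 5


def compute_correlations(
    expr: ExpressionMatrix,
    min_shared: int = DEFAULT_MIN_SHARED,
    signed: bool = False,
) -> CorrelationGraph:
    """Pairwise-complete Pearson correlation over all gene pairs.

    Parameters
    ----------
    expr
        Expression matrix; missing entries excluded pairwise.
    min_shared
        Pairs with this many or fewer shared non-missing samples get
        correlation 0.
    signed
        Keep the sign of r instead of taking ``|r|``.
    """
    if min_shared < 0:
        raise InvalidInputError("min_shared must be >= 0")
    if expr.n_samples < 2:
        raise InvalidInputError("at least 2 samples are required")

    valid = (~expr.missing_mask).astype(float)
    x = np.where(expr.missing_mask, 0.0, expr.values)
    x2 = x * x

    # pairwise-complete sufficient statistics via matrix products
    n = valid @ valid.T
    sx = x @ valid.T          # sum of gene-i values over samples shared with j
    sy = sx.T
    sxx = x2 @ valid.T
    syy = sxx.T
    sxy = x @ x.T

    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        denom = np.sqrt(varx * vary)
        r = cov / denom

    # zero variance (or numerically negative variance) and sparse overlap -> 0
    bad = (varx <= 1e-12) | (vary <= 1e-12) | (n <= min_shared)
    r = np.where(bad, 0.0, r)
    r = np.clip(r, -1.0, 1.0)
    if not signed:
        r = np.abs(r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2.0  # enforce exact symmetry against fp asymmetry
    return CorrelationGraph(gene_ids=list(expr.gene_ids), corr=r, signed=signed)


def threshold_graph(g: CorrelationGraph, t: float, strict: bool = True) -> CorrelationGraph:
    """Hard-threshold a correlation matrix into a simple graph.

    Edge rule is ``corr > t`` (or ``>= t`` when ``strict=False``); the
    diagonal is never an edge.  Edge count is non-increasing in t.
    """
    if not (0.0 < t <= 1.0):
        raise InvalidInputError("threshold must lie in (0, 1]")
    n = g.n_genes
    adj = (g.corr > t) if strict else (g.corr >= t)
    np.fill_diagonal(adj, False)
    graph = nx.Graph()
    graph.add_nodes_from(g.gene_ids)
    ii, jj = np.nonzero(np.triu(adj, k=1))
    graph.add_edges_from((g.gene_ids[i], g.gene_ids[j]) for i, j in zip(ii, jj))
    return CorrelationGraph(
        gene_ids=list(g.gene_ids),
        corr=g.corr,
        threshold=t,
        graph=graph,
        signed=g.signed,
    )


def dissimilarity_matrix(g: CorrelationGraph) -> np.ndarray:
    """1 - |r| dissimilarity, the default "diameter" scale for QT Clust."""
    d = 1.0 - np.abs(g.corr)
    np.fill_diagonal(d, 0.0)
    return d
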