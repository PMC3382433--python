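"""Shared containers for expression data, correlation graphs, clusterings
and annotation collections.

All containers are plain dataclasses around numpy arrays and frozensets of
gene identifiers; they validate their structural invariants on construction
and are hashable/comparable only where that is cheap and useful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "ExpressionMatrix",
    "CorrelationGraph",
    "Clustering",
    "AnnotationCollection",
    "ClusterScore",
    "InvalidInputError",
    "CapabilityError",
]


class InvalidInputError(ValueError):
    """Raised when an input container or parameter violates a precondition."""


class CapabilityError(RuntimeError):
    """Raised when a requested backend/method is not available."""


@dataclass
class ExpressionMatrix:
    """Gene x sample matrix of log-ratio expression values.

    ``values`` holds floats with ``nan`` at missing positions;
    ``missing_mask`` is ``True`` where a measurement is absent.  Gene
    identifiers are unique and ordered; at least two samples are required
    for any downstream correlation to be meaningful.
    """

    gene_ids: list[str]
    values: np.ndarray
    missing_mask: np.ndarray = None  # type: ignore[assignment]
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise InvalidInputError("expression values must be a 2-D matrix")
        if self.missing_mask is None:
            self.missing_mask = np.isnan(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise InvalidInputError("missing_mask shape must match values")
        self.gene_ids = [str(g) for g in self.gene_ids]
        if len(self.gene_ids) != self.values.shape[0]:
            raise InvalidInputError("gene_ids length must match row count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidInputError("gene_ids must be unique")
        if self.values.shape[1] < 2:
            raise InvalidInputError("at least 2 samples are required")
        if self.sample_ids is None:
            self.sample_ids = [f"s{j + 1}" for j in range(self.values.shape[1])]
        # keep values and mask consistent: masked entries are nan
        self.values = self.values.copy()
        self.values[self.missing_mask] = np.nan

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationGraph:
    """Absolute-Pearson correlation matrix, optionally hard-thresholded.

    ``corr`` is symmetric with entries in [0, 1] (or [-1, 1] in signed
    mode).  When ``threshold`` is set, ``graph`` is the simple undirected
    graph whose edges are exactly the off-diagonal pairs with
    ``corr > threshold``.
    """

    gene_ids: list[str]
    corr: np.ndarray
    threshold: float | None = None
    graph: nx.Graph | None = None
    signed: bool = False

    def __post_init__(self) -> None:
        self.corr = np.asarray(self.corr, dtype=float)
        n = len(self.gene_ids)
        if self.corr.shape != (n, n):
            raise InvalidInputError("corr must be square and match gene_ids")
        if not np.allclose(self.corr, self.corr.T, atol=0, rtol=0, equal_nan=True):
            raise InvalidInputError("corr must be exactly symmetric")
        lo = -1.0 if self.signed else 0.0
        if np.nanmin(self.corr) < lo - 1e-12 or np.nanmax(self.corr) > 1.0 + 1e-12:
            raise InvalidInputError("corr entries out of range")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def index_of(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError as exc:
            raise KeyError(gene) from exc


@dataclass
class Clustering:
    """A named collection of gene clusters, possibly overlapping.

    ``clusters`` is an ordered list of non-empty frozensets; ``ids`` gives
    a stable label per cluster (auto-numbered when omitted).  Whether
    overlap is legitimate depends on the producing method; ``is_disjoint``
    lets consumers enforce partition semantics where required.
    """

    method: str
    parameters: dict = field(default_factory=dict)
    clusters: list[frozenset[str]] = field(default_factory=list)
    ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.clusters = [frozenset(c) for c in self.clusters]
        if any(len(c) == 0 for c in self.clusters):
            raise InvalidInputError("clusters must be non-empty")
        if self.ids is None:
            width = max(3, len(str(len(self.clusters))))
            self.ids = [f"c{i + 1:0{width}d}" for i in range(len(self.clusters))]
        if len(self.ids) != len(self.clusters):
            raise InvalidInputError("ids length must match clusters")
        if len(set(self.ids)) != len(self.ids):
            raise InvalidInputError("cluster ids must be unique")

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self) -> Iterator[frozenset[str]]:
        return iter(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def covered_genes(self) -> frozenset[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return frozenset(out)

    def is_disjoint(self) -> bool:
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c:
                return False
            seen |= c
        return True

    def membership(self) -> dict[str, int]:
        """gene -> cluster index; only valid for disjoint clusterings."""
        if not self.is_disjoint():
            raise InvalidInputError("membership() requires a disjoint clustering")
        return {g: i for i, c in enumerate(self.clusters) for g in c}


@dataclass
class AnnotationCollection:
    """Gene-set annotation source (GO- or KEGG-like).

    ``categories`` maps category ID -> member gene set; the universe is the
    union of all annotated genes.  Cluster genes outside the universe are
    ignored during scoring.
    """

    source: str
    categories: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.categories = {str(k): frozenset(v) for k, v in self.categories.items()}
        if any(len(v) == 0 for v in self.categories.values()):
            raise InvalidInputError("annotation categories must be non-empty")

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for v in self.categories.values():
            out |= v
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.categories)


@dataclass
class ClusterScore:
    """Best annotation match for one cluster.

    ``jaccard`` = tp / (tp + fp + fn) against ``best_category`` (the
    highest-scoring category sharing at least the minimum number of genes
    with the cluster); 0 with ``best_category`` unset when no category
    qualifies.  ``fn`` counts annotated genes missing from the cluster
    genome-wide within the source.
    """

    cluster_id: str
    size: int
    jaccard: float
    best_category: str | None = None
    source: str | None = None
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        denom = self.tp + self.fp + self.fn
        if denom > 0:
            expected = self.tp / denom
            if abs(self.jaccard - expected) > 1e-12:
                raise InvalidInputError("jaccard inconsistent with tp/fp/fn")
        if self.best_category is not None and self.tp < 1:
            raise InvalidInputError("a qualifying match requires shared genes")
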