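"""Readers and writers for the plain-text formats the toolkit consumes.

Formats:

* expression: TSV, header row of sample IDs, first column gene ID, empty
  cell or ``NA`` means missing;
* annotations: GMT-style TSV (category ID, description, member genes);
* clusterings: one cluster per line, cluster ID then tab-separated genes;
* correlation matrices and edge lists: TSV.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import (
    AnnotationCollection,
    Clustering,
    CorrelationGraph,
    ExpressionMatrix,
    InvalidInputError,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clusters",
    "write_clusters",
    "read_correlation",
    "write_correlation",
    "write_edgelist",
    "ClusterFormatError",
]

_MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class ClusterFormatError(InvalidInputError):
    """Malformed cluster-list file; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=sorted(_MISSING_TOKENS),
        keep_default_na=False,
    )
    values = df.to_numpy(dtype=float)
    return ExpressionMatrix(
        gene_ids=[str(g) for g in df.index],
        values=values,
        sample_ids=[str(s) for s in df.columns],
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.6g")


def read_gmt(path: str | Path, source: str | None = None) -> AnnotationCollection:
    categories: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InvalidInputError(
                    f"line {lineno}: GMT lines need ID, description and >=1 gene"
                )
            cat, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            if cat in categories:
                raise InvalidInputError(f"line {lineno}: duplicate category {cat!r}")
            categories[cat] = frozenset(genes)
            descriptions[cat] = desc
    name = source if source is not None else Path(path).stem
    return AnnotationCollection(source=name, categories=categories, descriptions=descriptions)


def write_gmt(ann: AnnotationCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cat in sorted(ann.categories):
            desc = ann.descriptions.get(cat, "")
            genes = "\t".join(sorted(ann.categories[cat]))
            fh.write(f"{cat}\t{desc}\t{genes}\n")


def read_clusters(
    path: str | Path, method: str = "imported", parameters: dict | None = None
) -> Clustering:
    """Read a cluster-membership list (one cluster per line).

    Unknown genes are retained as-is; a gene repeated within one cluster is
    a format error reported with its line number.
    """
    ids: list[str] = []
    clusters: list[frozenset[str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            cid, genes = fields[0], [g for g in fields[1:] if g]
            if not cid:
                raise ClusterFormatError("missing cluster ID", lineno)
            if not genes:
                raise ClusterFormatError(f"cluster {cid!r} has no genes", lineno)
            if len(set(genes)) != len(genes):
                dup = next(g for g in genes if genes.count(g) > 1)
                raise ClusterFormatError(
                    f"gene {dup!r} repeated within cluster {cid!r}", lineno
                )
            if cid in ids:
                raise ClusterFormatError(f"duplicate cluster ID {cid!r}", lineno)
            ids.append(cid)
            clusters.append(frozenset(genes))
    return Clustering(
        method=method, parameters=dict(parameters or {}), clusters=clusters, ids=ids
    )


def write_clusters(clustering: Clustering, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, genes in zip(clustering.ids, clustering.clusters):
            fh.write(cid + "\t" + "\t".join(sorted(genes)) + "\n")


def read_correlation(path: str | Path, signed: bool = False) -> CorrelationGraph:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise InvalidInputError("correlation matrix row/column IDs disagree")
    return CorrelationGraph(
        gene_ids=[str(g) for g in df.index],
        corr=df.to_numpy(dtype=float),
        signed=signed,
    )


def write_correlation(g: CorrelationGraph, path: str | Path) -> None:
    df = pd.DataFrame(g.corr, index=g.gene_ids, columns=g.gene_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


def write_edgelist(g: CorrelationGraph, path: str | Path) -> None:
    if g.graph is None:
        raise InvalidInputError("graph has not been thresholded; no edges to write")
    with open(path, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.graph.edges()):
            fh.write(f"{u}\t{v}\n")
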