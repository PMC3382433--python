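"""Parameter sweeps: default per-method grids, a single-run dispatcher,
and an idempotent sweep driver that writes cluster lists plus a manifest.

The default grids encode the usual evenly-spaced settings for each method:
CAST thresholds between 0.5 and 1.0; QT Clust diameters 0.05-1.00;
maximal clique at 21 thresholds from 0.80 to 0.90; paraclique thresholds
{0.5, 0.6, 0.7, 0.8} crossed with glom factors {1, 3, 5, 7, 9} (20
combinations); k-clique communities at thresholds {0.80, 0.85, 0.90} with
eight k values evenly spread between 3 and the maximum clique size of each
threshold graph; and cluster-count methods parameterised by average
cluster size over the 10-100 and 100-500 intervals.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import baselines, cliques, correlation
from .core import Clustering, CorrelationGraph, ExpressionMatrix, InvalidInputError
from .io import read_expression, write_clusters

__all__ = ["SweepConfig", "default_grid", "run_method", "run_sweep", "SWEEP_METHODS"]

SWEEP_METHODS = (
    "maximal_clique",
    "paraclique",
    "k_clique_communities",
    "cast",
    "qt_clust",
    "kmeans",
    "ward",
    "average",
    "complete",
    "mcquitty",
)

_GRAPH_METHODS = {"maximal_clique", "paraclique", "k_clique_communities"}


@dataclass
class SweepConfig:
    method: str
    grid: list[dict]
    expression: str | Path | ExpressionMatrix
    out_dir: str | Path
    seed: int = 0
    min_shared: int = correlation.DEFAULT_MIN_SHARED
    min_size: int = 3

    def __post_init__(self) -> None:
        if self.method not in SWEEP_METHODS:
            raise InvalidInputError(f"unknown sweep method {self.method!r}")
        if not self.grid:
            raise InvalidInputError("parameter grid must be non-empty")


def default_grid(method: str, n_genes: int | None = None) -> list[dict]:
    """The evenly-spaced default parameter grid for ``method``."""
    if method == "cast":
        return [{"t": round(t, 4)} for t in np.arange(0.50, 0.9751, 0.025)]
    if method == "qt_clust":
        return [{"max_diameter": round(d, 4)} for d in np.arange(0.05, 1.0001, 0.05)]
    if method == "maximal_clique":
        return [{"threshold": round(t, 4)} for t in np.arange(0.80, 0.9001, 0.005)]
    if method == "paraclique":
        return [
            {"threshold": t, "glom": g}
            for t in (0.50, 0.60, 0.70, 0.80)
            for g in (1, 3, 5, 7, 9)
        ]
    if method == "k_clique_communities":
        # k = "auto" expands at run time to 8 values between 3 and the
        # maximum clique size of the threshold graph
        return [{"threshold": t, "k": "auto"} for t in (0.80, 0.85, 0.90)]
    if method in baselines.ADAPTER_METHODS:
        if n_genes is None:
            n_genes = 6167
        sizes = sorted(
            {int(round(s)) for s in np.linspace(10, 100, 10)}
            | {int(round(s)) for s in np.linspace(100, 500, 10)}
        )
        return [{"avg_cluster_size": s} for s in sizes if s <= n_genes]
    raise InvalidInputError(f"no default grid for method {method!r}")


def run_method(
    method: str,
    params: dict,
    corr: CorrelationGraph | None = None,
    expr: ExpressionMatrix | None = None,
    seed: int = 0,
    min_size: int = 3,
) -> Clustering:
    """Run one method at one parameter setting and tag the result."""
    if method in _GRAPH_METHODS:
        if corr is None:
            raise InvalidInputError(f"{method} needs a correlation graph")
        g = correlation.threshold_graph(corr, params["threshold"]).graph
        assert g is not None
        if method == "maximal_clique":
            result = cliques.maximal_cliques(g, min_size=params.get("min_size", min_size))
        elif method == "paraclique":
            result = cliques.paraclique(
                g, glom=params["glom"], min_core=params.get("min_core", 3)
            )
        else:
            result = cliques.k_clique_communities(g, k=params["k"])
    elif method == "cast":
        if corr is None:
            raise InvalidInputError("cast needs a correlation graph")
        result = baselines.cast(corr, t=params["t"])
    elif method == "qt_clust":
        if corr is None:
            raise InvalidInputError("qt_clust needs a correlation graph")
        d = correlation.dissimilarity_matrix(corr)
        result = baselines.qt_clust(d, corr.gene_ids, max_diameter=params["max_diameter"])
    elif method in baselines.ADAPTER_METHODS:
        if expr is None:
            raise InvalidInputError(f"{method} needs an expression matrix")
        result = baselines.run_adapter(
            method,
            expr,
            n_clusters=params.get("n_clusters"),
            avg_cluster_size=params.get("avg_cluster_size"),
            seed=seed,
        )
    else:
        raise InvalidInputError(f"unknown method {method!r}")
    result.parameters = {**params, **result.parameters}
    return result


def _slug(params: dict) -> str:
    return "_".join(f"{k}-{params[k]}" for k in sorted(params))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _expand_auto_k(grid: list[dict], corr: CorrelationGraph) -> list[dict]:
    out: list[dict] = []
    for params in grid:
        if params.get("k") != "auto":
            out.append(params)
            continue
        g = correlation.threshold_graph(corr, params["threshold"]).graph
        assert g is not None
        omega = len(cliques.maximum_clique(g))
        if omega < 3:
            continue
        ks = sorted({int(round(k)) for k in np.linspace(3, omega, min(8, omega - 2))})
        out.extend({"threshold": params["threshold"], "k": k} for k in ks)
    return out


def run_sweep(cfg: SweepConfig, force: bool = False) -> dict:
    """Run every grid setting, writing one cluster-list file each.

    Re-runs skip settings whose output already exists for the same input
    (matched by content hash) unless ``force`` is set.  Returns the
    manifest, which is also written to ``<out_dir>/manifest.json``.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if isinstance(cfg.expression, ExpressionMatrix):
        expr = cfg.expression
        input_id = "in-memory"
    else:
        expr = read_expression(cfg.expression)
        input_id = _sha256(Path(cfg.expression))

    needs_corr = cfg.method in _GRAPH_METHODS or cfg.method in ("cast", "qt_clust")
    corr = (
        correlation.compute_correlations(expr, min_shared=cfg.min_shared)
        if needs_corr
        else None
    )

    grid = cfg.grid
    if cfg.method == "k_clique_communities":
        assert corr is not None
        grid = _expand_auto_k(grid, corr)

    manifest_path = out_dir / "manifest.json"
    manifest: dict = {"method": cfg.method, "input": input_id, "seed": cfg.seed, "entries": []}
    previous: dict[str, dict] = {}
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("method") == cfg.method and old.get("input") == input_id:
            previous = {e["slug"]: e for e in old.get("entries", [])}

    for params in grid:
        slug = _slug(params)
        fname = f"{cfg.method}__{slug}.clusters.tsv"
        fpath = out_dir / fname
        prior = previous.get(slug)
        if not force and prior is not None and fpath.exists():
            entry = dict(prior)
            entry["recomputed"] = False
        else:
            clustering = run_method(
                cfg.method, params, corr=corr, expr=expr,
                seed=cfg.seed, min_size=cfg.min_size,
            )
            write_clusters(clustering, fpath)
            entry = {
                "slug": slug,
                "params": params,
                "file": fname,
                "n_clusters": len(clustering),
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "recomputed": True,
            }
        manifest["entries"].append(entry)

    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest
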