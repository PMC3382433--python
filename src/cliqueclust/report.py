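"""Aggregate per-cluster score tables into the summary reports:
AT5/BAT5 by size bin, quartile ranking, prominent-annotation consensus,
pairwise variation-of-information min/max, and cluster count/size tables.

Score files are tidy TSVs named ``<method>__<slug>.scores.tsv`` (one row
per scored cluster), as written by the ``score`` CLI subcommand; cluster
files follow the shared cluster-list format.  All reports are plain TSV so
regeneration from identical inputs is byte-identical.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from pathlib import Path

import pandas as pd

from .core import Clustering, ClusterScore
from .evaluation import (
    DEFAULT_BINS,
    OverlapError,
    SizeBins,
    at5,
    bat5,
    cluster_count_size_summary,
    prominent_annotations,
    quartile_rank,
    variation_of_information,
)
from .io import read_clusters

__all__ = ["collect_scores", "bat5_table", "make_report"]

log = logging.getLogger(__name__)


def _parse_name(path: Path) -> tuple[str, str]:
    stem = path.name
    for suffix in (".scores.tsv", ".clusters.tsv"):
        if stem.endswith(suffix):
            stem = stem[: -len(suffix)]
            break
    method, _, slug = stem.partition("__")
    return method, slug


def collect_scores(score_dir: str | Path) -> pd.DataFrame:
    """Long-form table of every scored cluster in a directory."""
    frames = []
    for path in sorted(Path(score_dir).glob("*.scores.tsv")):
        method, slug = _parse_name(path)
        df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
        df["jaccard"] = df["jaccard"].astype(float)
        df["method"] = method
        df["parameters"] = slug
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=[
                "cluster_id", "size", "bin", "jaccard", "best_category",
                "source", "tp", "fp", "fn", "method", "parameters",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def bat5_table(
    scores: pd.DataFrame, bins: SizeBins = DEFAULT_BINS
) -> dict[str, dict[str, float | None]]:
    """method -> bin -> BAT5 (None for bins never populated)."""
    table: dict[str, dict[str, float | None]] = {}
    for method in sorted(scores["method"].unique()):
        sub = scores[scores["method"] == method]
        table[method] = {}
        for b in bins.names:
            at5_by_param: dict[str, float | None] = {}
            for slug in sorted(sub["parameters"].unique()):
                vals = sub[(sub["parameters"] == slug) & (sub["bin"] == b)]["jaccard"]
                at5_by_param[slug], _ = at5(list(vals))
            best = bat5(at5_by_param)
            table[method][b] = best[0] if best is not None else None
    return table


def _scores_by_method(scores: pd.DataFrame) -> dict[str, list[ClusterScore]]:
    out: dict[str, list[ClusterScore]] = {}
    for method in sorted(scores["method"].unique()):
        recs = []
        for row in scores[scores["method"] == method].itertuples():
            cat = row.best_category if row.best_category else None
            recs.append(
                ClusterScore(
                    cluster_id=str(row.cluster_id),
                    size=int(row.size),
                    jaccard=float(row.jaccard),
                    best_category=cat,
                    source=row.source if row.source else None,
                    tp=int(row.tp),
                    fp=int(row.fp),
                    fn=int(row.fn),
                )
            )
        out[method] = recs
    return out


def _vi_minmax(clusterings: dict[tuple[str, str], Clustering]) -> pd.DataFrame:
    methods = sorted({m for m, _ in clusterings})
    rows = []
    for ma, mb in itertools.combinations_with_replacement(methods, 2):
        vis = []
        for (m1, s1), c1 in sorted(clusterings.items()):
            if m1 != ma:
                continue
            for (m2, s2), c2 in sorted(clusterings.items()):
                if m2 != mb or (ma == mb and s2 <= s1):
                    continue
                try:
                    vis.append(variation_of_information(c1, c2))
                except (OverlapError, ValueError):
                    continue
        if vis:
            rows.append(
                {
                    "method_a": ma,
                    "method_b": mb,
                    "vi_min_nats": round(min(vis), 4),
                    "vi_max_nats": round(max(vis), 4),
                    "n_pairs": len(vis),
                }
            )
    return pd.DataFrame(
        rows, columns=["method_a", "method_b", "vi_min_nats", "vi_max_nats", "n_pairs"]
    )


def make_report(
    score_dir: str | Path,
    out_dir: str | Path,
    clusters_dir: str | Path | None = None,
    cutoff: float = 0.25,
    bins: SizeBins = DEFAULT_BINS,
) -> list[Path]:
    """Write the summary TSVs; returns the paths written.

    With an empty score directory an empty report is written and a warning
    is issued.  Tables state units where relevant (VI is in nats).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scores = collect_scores(score_dir)
    written: list[Path] = []
    if scores.empty:
        warnings.warn(f"no score files found in {score_dir}; writing an empty report")

    table = bat5_table(scores, bins) if not scores.empty else {}
    bat5_rows = [
        {
            "method": m,
            **{
                f"bat5_{b}": (round(v, 4) if v is not None else 0.0)
                for b, v in per_bin.items()
            },
        }
        for m, per_bin in table.items()
    ]
    bat5_df = pd.DataFrame(bat5_rows, columns=["method"] + [f"bat5_{b}" for b in bins.names])
    p = out / "bat5.tsv"
    bat5_df.to_csv(p, sep="\t", index=False)
    written.append(p)

    quart_df = quartile_rank(table, bins) if table else pd.DataFrame(columns=["method"])
    p = out / "quartile.tsv"
    quart_df.to_csv(p, sep="\t", index=False)
    written.append(p)

    if not scores.empty:
        selected, means = prominent_annotations(_scores_by_method(scores), cutoff=cutoff)
    else:
        selected, means = [], {}
    prom_df = pd.DataFrame(
        sorted(means.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["method", "mean_best_jaccard"],
    )
    prom_df["mean_best_jaccard"] = prom_df["mean_best_jaccard"].astype(float).round(4)
    p = out / "prominent_methods.tsv"
    prom_df.to_csv(p, sep="\t", index=False)
    written.append(p)
    p = out / "prominent_categories.tsv"
    pd.DataFrame({"category": selected}).to_csv(p, sep="\t", index=False)
    written.append(p)

    if clusters_dir is not None:
        clusterings: dict[tuple[str, str], Clustering] = {}
        for path in sorted(Path(clusters_dir).glob("*.clusters.tsv")):
            method, slug = _parse_name(path)
            clusterings[(method, slug)] = read_clusters(path, method=method)
        p = out / "vi_minmax.tsv"
        _vi_minmax(clusterings).to_csv(p, sep="\t", index=False)
        written.append(p)
        by_label = {
            f"{m}__{s}": c for (m, s), c in sorted(clusterings.items())
        }
        p = out / "cluster_counts_sizes.tsv"
        cluster_count_size_summary(by_label, bins).to_csv(p, sep="\t", index=False)
        written.append(p)

    return written
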