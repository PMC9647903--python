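"""Genomic cluster calling for KRAB-ZFP gene families.

A cluster is a maximal run of same-chromosome genes in which every pair of
neighbours lies within ``max_gap`` base pairs (default 200 kb) and which
contains at least ``min_size`` genes (default 2). Strand is ignored. The
default gap metric is end-of-previous to start-of-next (the strictest
interval reading; overlapping genes give a non-positive gap and always
co-cluster); start-to-start and midpoint metrics are available for
sensitivity analyses. Cluster ids are assigned 1..N in (chromosome
lexicographic, span start) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import GeneRecord, GeneTable

GAP_METRICS = ("end_to_start", "start_to_start", "midpoint")


@dataclass(frozen=True)
class ClusterParams:
    max_gap: int = 200_000  # bp
    min_size: int = 2
    gap_metric: str = "end_to_start"

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_size < 2:
            raise ValueError("min_size must be >= 2")
        if self.gap_metric not in GAP_METRICS:
            raise ValueError(f"gap_metric must be one of {GAP_METRICS}")


@dataclass
class Cluster:
    cluster_id: int
    chromosome: str
    members: tuple[str, ...]  # gene_ids ordered by start
    span_start: int  # 1-based inclusive
    span_end: int


def gene_gap(prev: GeneRecord, nxt: GeneRecord, metric: str = "end_to_start") -> int:
    if metric == "end_to_start":
        return nxt.start - prev.end
    if metric == "start_to_start":
        return nxt.start - prev.start
    if metric == "midpoint":
        return (nxt.start + nxt.end) // 2 - (prev.start + prev.end) // 2
    raise ValueError(f"unknown gap metric {metric!r}")


def call_clusters(
    table: GeneTable, params: ClusterParams | None = None
) -> list[Cluster]:
    """Partition a gene table into maximal gap-bounded clusters."""
    params = params or ClusterParams()
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in table:
        by_chrom.setdefault(rec.chromosome, []).append(rec)

    raw: list[tuple[str, list[GeneRecord]]] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end, r.gene_id))
        run: list[GeneRecord] = []
        for rec in genes:
            if run and gene_gap(run[-1], rec, params.gap_metric) > params.max_gap:
                if len(run) >= params.min_size:
                    raw.append((chrom, run))
                run = []
            run.append(rec)
        if len(run) >= params.min_size:
            raw.append((chrom, run))

    clusters = []
    for cid, (chrom, run) in enumerate(
        sorted(raw, key=lambda cr: (cr[0], cr[1][0].start)), start=1
    ):
        clusters.append(
            Cluster(
                cluster_id=cid,
                chromosome=chrom,
                members=tuple(r.gene_id for r in run),
                span_start=min(r.start for r in run),
                span_end=max(r.end for r in run),
            )
        )
    return clusters


def membership(clusters: Iterable[Cluster]) -> dict[str, int]:
    """gene_id -> cluster_id for every clustered gene."""
    out: dict[str, int] = {}
    for cl in clusters:
        for g in cl.members:
            out[g] = cl.cluster_id
    return out


def cluster_census(clusters: list[Cluster], table: GeneTable) -> dict:
    """Summary counts: clusters, clustered/total genes, per-chromosome and per-cluster tallies."""
    clustered = {g for cl in clusters for g in cl.members}
    per_chrom = (
        table.to_dataframe().groupby("chromosome")["gene_id"].count().sort_index()
    )
    per_cluster = pd.Series(
        {cl.cluster_id: len(cl.members) for cl in clusters}, dtype=int,
        name="n_members",
    )
    return {
        "n_clusters": len(clusters),
        "n_clustered_genes": len(clustered),
        "n_total_genes": len(table),
        "per_chromosome_gene_counts": per_chrom,
        "per_cluster_member_counts": per_cluster,
    }


def write_cluster_table(clusters: list[Cluster], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "cluster_id": cl.cluster_id,
                "chromosome": cl.chromosome,
                "span": f"{cl.span_start}-{cl.span_end}",
                "n_members": len(cl.members),
                "members": ",".join(cl.members),
            }
            for cl in clusters
        ],
        columns=["cluster_id", "chromosome", "span", "n_members", "members"],
    )
    df.to_csv(path, sep="\t", index=False)
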