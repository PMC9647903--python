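"""Gene x fingerprint occurrence matrices and cluster-level usage statistics.

The fingerprint matrix counts, per gene, how often each distinct
three-residue fingerprint occurs among its ZnFs; row sums therefore equal
per-gene ZnF counts. Columns are ordered by descending genome-wide total,
then lexicographically, so exports are deterministic. Genes with zero ZnFs
are kept as all-zero rows so cluster denominators match the gene census.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import ZnFArrayAnnotation
from .clusters import Cluster


def build_fingerprint_matrix(
    annotations: Mapping[str, ZnFArrayAnnotation] | Iterable[ZnFArrayAnnotation],
) -> pd.DataFrame:
    """Exact gene x fingerprint occurrence counts."""
    if isinstance(annotations, Mapping):
        anns = list(annotations.values())
    else:
        anns = list(annotations)
    counts = {a.gene_id: Counter(a.fingerprints) for a in anns}
    matrix = pd.DataFrame.from_dict(counts, orient="index").fillna(0).astype(int)
    matrix = matrix.reindex([a.gene_id for a in anns])
    if matrix.empty:
        return pd.DataFrame(index=[a.gene_id for a in anns], dtype=int)
    totals = matrix.sum(axis=0)
    order = sorted(matrix.columns, key=lambda c: (-totals[c], c))
    return matrix[order]


@dataclass
class TopSpeciesStats:
    """Coverage of a gene subset's ZnFs by its dominant fingerprint species."""

    total_znfs: int
    covered_znfs: int
    fraction: float
    species: tuple[str, ...]  # the qualifying top-k fingerprints


def top_species_stats(
    matrix: pd.DataFrame,
    gene_subset: Sequence[str],
    min_count: int = 10,
    top_k: int = 5,
) -> TopSpeciesStats:
    """Among the top-k fingerprints with subset count >= min_count, how many
    of the subset's ZnFs do they account for?

    Ranking and the min_count filter both use within-subset counts.
    """
    if len(gene_subset) == 0:
        raise ValueError("gene_subset is empty")
    missing = [g for g in gene_subset if g not in matrix.index]
    if missing:
        raise KeyError(f"genes not in matrix: {missing}")
    sub = matrix.loc[list(gene_subset)]
    totals = sub.sum(axis=0).sort_values(ascending=False)
    totals = totals[totals > 0]
    ranked = sorted(totals.index, key=lambda c: (-totals[c], c))
    species = tuple(c for c in ranked[:top_k] if totals[c] >= min_count)
    total = int(sub.to_numpy().sum())
    covered = int(totals[list(species)].sum()) if species else 0
    fraction = covered / total if total else 0.0
    return TopSpeciesStats(total, covered, fraction, species)


def fingerprint_exclusivity(
    matrix: pd.DataFrame, clusters: Iterable[Cluster]
) -> pd.DataFrame:
    """Per (fingerprint, cluster): on-cluster count, genome-wide count, and
    the exclusivity fraction on/genome-wide."""
    clusters = list(clusters)
    for cl in clusters:
        missing = [g for g in cl.members if g not in matrix.index]
        if missing:
            raise KeyError(f"cluster {cl.cluster_id} genes not in matrix: {missing}")
    genome_totals = matrix.sum(axis=0)
    rows = []
    for cl in clusters:
        on = matrix.loc[list(cl.members)].sum(axis=0)
        for fp in matrix.columns:
            gw = int(genome_totals[fp])
            rows.append(
                {
                    "fingerprint": fp,
                    "cluster_id": cl.cluster_id,
                    "on_cluster": int(on[fp]),
                    "genome_wide": gw,
                    "exclusivity": int(on[fp]) / gw if gw else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["fingerprint", "cluster_id", "on_cluster", "genome_wide",
                       "exclusivity"]
    )


def write_matrix(matrix: pd.DataFrame, wide_path: str | Path, long_path: str | Path | None = None) -> None:
    """Export the matrix wide (genes x fingerprints) and, optionally, tidy long."""
    matrix.to_csv(wide_path, sep="\t", index_label="gene_id")
    if long_path is not None:
        long = (
            matrix.stack()
            .rename_axis(["gene_id", "fingerprint"])
            .rename("count")
            .reset_index()
        )
        long = long[long["count"] > 0]
        long.to_csv(long_path, sep="\t", index=False)
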