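"""TPM-threshold gene selection and per-cluster expressed/total ratios.

TPM values are consumed as given (no re-normalisation); the high-expression
threshold is inclusive (TPM >= t). A cluster counts as "highly expressed"
in a sample when more than half of its members pass the threshold, the
cutoff being configurable.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .clusters import Cluster


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Tab-separated genes x samples TPM table, first column = gene_id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene_id(s) in expression table: {dupes}")
    if (df.to_numpy() < 0).any():
        raise ValueError("negative TPM values")
    return df


def write_expression_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id", float_format="%.4f")


def select_highly_expressed(
    table: pd.DataFrame, sample: str, threshold: float
) -> list[str]:
    """Genes with TPM >= threshold (inclusive) in the given sample."""
    if sample not in table.columns:
        raise KeyError(f"unknown sample {sample!r}")
    col = table[sample]
    return col.index[col >= threshold].tolist()


def cluster_expression_ratios(
    selected: Iterable[str], clusters: Sequence[Cluster]
) -> pd.DataFrame:
    """Per cluster: members selected, total members, and their ratio."""
    chosen = set(selected)
    rows = []
    for cl in clusters:
        n_sel = sum(1 for g in cl.members if g in chosen)
        rows.append(
            {
                "cluster_id": cl.cluster_id,
                "n_selected": n_sel,
                "n_total": len(cl.members),
                "ratio": n_sel / len(cl.members),
            }
        )
    return pd.DataFrame(rows, columns=["cluster_id", "n_selected", "n_total", "ratio"])


def highly_expressed_clusters(
    ratios: pd.DataFrame, cutoff: float = 0.5
) -> list[int]:
    """Clusters whose expressed/total ratio strictly exceeds the cutoff."""
    return ratios.loc[ratios["ratio"] > cutoff, "cluster_id"].astype(int).tolist()
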