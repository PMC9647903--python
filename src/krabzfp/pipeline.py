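"""End-to-end orchestration: load/simulate -> annotate -> cluster ->
fingerprints -> conservation (+PAM discovery) -> expression -> sgRNA design.

Stages communicate via files in the output directory so a run is
inspectable and each artifact re-loadable by the package's own readers.
The machine-readable run report contains counts, parameters and the seed
but no timestamps, so identical config+seed gives byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .annotation import PatternConfig, annotate_table, tile_census, write_tile_table
from .clusters import ClusterParams, call_clusters, cluster_census, write_cluster_table
from .conservation import find_conserved_pams, profile_levels, write_profile
from .expression import (
    cluster_expression_ratios,
    highly_expressed_clusters,
    read_expression_table,
    select_highly_expressed,
)
from .fingerprints import build_fingerprint_matrix, write_matrix
from .io import bind_sequences, read_gene_table, write_bed
from .sgrna import (
    DesignLog,
    enumerate_candidates,
    select_top,
    specificity_report,
    write_candidate_table,
    write_specificity,
)
from .simulate import FamilyConfig, generate_family, write_family

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    # either the three input paths, or a simulate config
    genes: str | None = None
    protein_fasta: str | None = None
    cds_fasta: str | None = None
    expression_table: str | None = None
    simulate: FamilyConfig | None = None
    species_filter: str | None = None

    cluster_params: ClusterParams = field(default_factory=ClusterParams)
    pattern: PatternConfig = field(default_factory=PatternConfig)

    top_k: int = 11
    max_mismatches: int = 0
    both_strands: bool = True
    min_g_freq: float = 0.8

    sample: str | None = None  # expression sample to select on
    tpm_threshold: float = 25.0
    cluster_ratio_cutoff: float = 0.5

    out_dir: str = "krabzfp_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        if "simulate" in data and data["simulate"] is not None:
            data["simulate"] = FamilyConfig.from_dict(data["simulate"])
        if "cluster_params" in data:
            data["cluster_params"] = ClusterParams(**data["cluster_params"])
        if "pattern" in data:
            p = data["pattern"]
            data["pattern"] = PatternConfig(
                tuple(p.get("cc_spacer", (2, 2))),
                tuple(p.get("ch_spacer", (12, 12))),
                tuple(p.get("hh_spacer", (3, 3))),
            )
        return cls(**data)


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage; returns (and writes) the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "max_gap": config.cluster_params.max_gap,
            "min_size": config.cluster_params.min_size,
            "gap_metric": config.cluster_params.gap_metric,
            "top_k": config.top_k,
            "max_mismatches": config.max_mismatches,
            "tpm_threshold": config.tpm_threshold,
            "min_g_freq": config.min_g_freq,
        },
        "stages": {},
    }

    # --- load or simulate -------------------------------------------------
    expression = None
    if config.simulate is not None:
        sim = dataclasses.replace(config.simulate, seed=config.seed)
        bundle = generate_family(sim)
        write_family(bundle, out / "family")
        table = bundle.table
        expression = bundle.expression
        report["stages"]["simulate"] = {"n_genes": len(table)}
    else:
        if not (config.genes and config.protein_fasta and config.cds_fasta):
            raise StageError("load", "need genes/protein_fasta/cds_fasta or a simulate block")
        try:
            table = read_gene_table(config.genes, config.species_filter)
        except Exception as exc:
            raise StageError("read_gene_table", str(exc)) from exc
        try:
            table = bind_sequences(table, config.protein_fasta, config.cds_fasta)
        except Exception as exc:
            raise StageError("bind_sequences", str(exc)) from exc
        if config.expression_table:
            expression = read_expression_table(config.expression_table)
        report["stages"]["load"] = {
            "n_genes": len(table),
            "n_sequenced": len(table.sequenced_records()),
        }

    # --- annotate ---------------------------------------------------------
    annotations = annotate_table(table, config.pattern)
    write_tile_table(annotations, out / "tiles.tsv")
    census = tile_census(annotations)
    report["stages"]["annotate"] = {
        "total_znfs": census["total_znfs"],
        "distinct_fingerprints": census["distinct_fingerprints"],
    }

    # --- clusters ---------------------------------------------------------
    clusters = call_clusters(table, config.cluster_params)
    write_cluster_table(clusters, out / "clusters.tsv")
    write_bed(clusters, out / "clusters.bed")
    ccensus = cluster_census(clusters, table)
    report["stages"]["clusters"] = {
        "n_clusters": ccensus["n_clusters"],
        "n_clustered_genes": ccensus["n_clustered_genes"],
        "n_total_genes": ccensus["n_total_genes"],
    }

    # --- fingerprints -----------------------------------------------------
    matrix = build_fingerprint_matrix(annotations)
    write_matrix(matrix, out / "fingerprint_matrix.tsv", out / "fingerprint_long.tsv")
    report["stages"]["fingerprints"] = {"n_distinct": int(matrix.shape[1])}

    # --- conservation + PAM discovery -------------------------------------
    pam_by_cluster = {}
    if annotations:
        for tile_type in ("znf", "linker"):
            for alphabet in ("aa", "nt"):
                prof = profile_levels(annotations, clusters, "genome", tile_type, alphabet)
                write_profile(prof, out / f"profile_genome_{tile_type}_{alphabet}.tsv")
        for cl in clusters:
            members_annotated = [g for g in cl.members if g in annotations]
            if not members_annotated:
                continue
            prof = profile_levels(
                annotations, clusters, f"cluster:{cl.cluster_id}", "linker", "nt"
            )
            write_profile(prof, out / f"profile_cluster{cl.cluster_id}_linker_nt.tsv")
            pams = find_conserved_pams(prof, config.min_g_freq)
            pam_by_cluster[cl.cluster_id] = list(pams.pam_offsets)
        with (out / "pam_sites.json").open("w") as fh:
            json.dump(pam_by_cluster, fh, indent=1, sort_keys=True)
    report["stages"]["conservation"] = {
        "pam_sites_per_cluster": {str(k): v for k, v in sorted(pam_by_cluster.items())}
    }

    # --- expression selection ----------------------------------------------
    target_clusters = [cl.cluster_id for cl in clusters]
    if expression is not None:
        sample = config.sample or expression.columns[0]
        selected = select_highly_expressed(expression, sample, config.tpm_threshold)
        ratios = cluster_expression_ratios(selected, clusters)
        ratios.to_csv(out / "expression_ratios.tsv", sep="\t", index=False)
        target_clusters = highly_expressed_clusters(ratios, config.cluster_ratio_cutoff)
        report["stages"]["expression"] = {
            "sample": sample,
            "n_selected": len(selected),
            "highly_expressed_clusters": target_clusters,
        }

    # --- sgRNA design -----------------------------------------------------
    by_id = {cl.cluster_id: cl for cl in clusters}
    target_genes = [
        g
        for cid in target_clusters
        for g in by_id[cid].members
        if g in annotations
    ]
    if target_genes:
        log = DesignLog()
        candidates = enumerate_candidates(
            annotations, table, target_genes, tuple(target_clusters), log
        )
        top = select_top(candidates, config.top_k)
        write_candidate_table(top, out / "sgrna_candidates.tsv")
        spec = specificity_report(
            top, table, clusters, config.max_mismatches, config.both_strands
        )
        write_specificity(spec, out / "sgrna_specificity.tsv")
        report["stages"]["design"] = {
            "n_candidates": len(candidates),
            "n_selected": len(top),
            "n_windows": log.n_windows,
            "n_skipped_short": log.n_skipped_short,
            "top_design_frequency": top[0].design_frequency if top else 0,
            "on_target_fractions": {
                p: (None if f != f else round(float(f), 6))
                for p, f in spec.on_target_fraction.items()
            },
        }

    with (out / "report.json").open("w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
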