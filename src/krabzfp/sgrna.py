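"""Multi-target sgRNA design against cluster-specific linker sequences.

Candidates are the 20-nt windows immediately 5' of every NGG whose triplet
lies inside a linker tile, read on the coding strand (linker tiles are
defined on the coding frame). Identical protospacers are merged and ranked
by their within-target design frequency — a guide that recurs across many
linkers of a cluster cleaves many sites at once, which is the point of the
strategy. Cut-site prediction then searches every gene's CDS on both
strands for protospacer+NGG (exact match by default), and the specificity
report aggregates predicted sites by the harbouring gene's cluster.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import ZnFArrayAnnotation
from .clusters import Cluster, membership
from .io import GeneTable

PROTOSPACER_LEN = 20
PAM_LEN = 3

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SgRNACandidate:
    protospacer: str  # 20 nt
    pam: str  # 3 nt, NGG; most frequent observed PAM among merged windows
    target_clusters: tuple[int, ...]
    design_frequency: int  # number of source windows within the target genes

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if self.pam[1:3] != "GG":
            raise ValueError("PAM must match NGG")


@dataclass
class CutSite:
    gene_id: str
    strand: str  # +/- relative to the CDS as given
    position: int  # 0-based protospacer start in the searched (strand) sequence
    mismatches: int


@dataclass
class SpecificityReport:
    matrix: pd.DataFrame  # candidates x (cluster columns + "unclustered")
    total_sites: pd.Series
    on_target_fraction: pd.Series  # NaN where total_sites == 0
    target_clusters: dict[str, tuple[int, ...]]


@dataclass
class DesignLog:
    n_windows: int = 0
    n_skipped_short: int = 0  # PAMs with < 20 nt of upstream CDS
    skipped: list[tuple[str, int]] = field(default_factory=list)


def enumerate_candidates(
    annotations: Mapping[str, ZnFArrayAnnotation],
    table: GeneTable,
    target_genes: Sequence[str],
    target_clusters: Sequence[int] = (),
    log: DesignLog | None = None,
) -> list[SgRNACandidate]:
    """All 20-mer-before-NGG candidates from the target genes' linkers, ranked.

    The window is anchored by PAM position within the gene's full CDS, so it
    may extend 5' of the linker into the preceding ZnF tile. Candidates are
    merged on protospacer identity and ranked by design frequency
    (descending), ties broken lexicographically.
    """
    log = log if log is not None else DesignLog()
    windows: Counter[str] = Counter()
    pams: dict[str, Counter] = {}
    for gene_id in target_genes:
        ann = annotations[gene_id]
        cds = table.get(gene_id).cds_seq
        if cds is None:
            raise ValueError(f"{gene_id}: no CDS bound")
        for linker in ann.linkers:
            linker_nt_start = 3 * (linker.aa_span[0] - 1)  # 0-based in CDS
            for o in linker.pam_offsets:
                pam_start = linker_nt_start + o
                if pam_start < PROTOSPACER_LEN:
                    log.n_skipped_short += 1
                    log.skipped.append((gene_id, pam_start))
                    continue
                proto = cds[pam_start - PROTOSPACER_LEN : pam_start]
                pam = cds[pam_start : pam_start + PAM_LEN]
                if len(pam) < PAM_LEN:  # PAM truncated at CDS end
                    log.n_skipped_short += 1
                    log.skipped.append((gene_id, pam_start))
                    continue
                windows[proto] += 1
                pams.setdefault(proto, Counter())[pam] += 1
                log.n_windows += 1

    ranked = sorted(windows, key=lambda p: (-windows[p], p))
    out = []
    for proto in ranked:
        pam_counts = pams[proto]
        pam = sorted(pam_counts, key=lambda p: (-pam_counts[p], p))[0]
        out.append(
            SgRNACandidate(
                protospacer=proto,
                pam=pam,
                target_clusters=tuple(target_clusters),
                design_frequency=windows[proto],
            )
        )
    return out


def select_top(
    candidates: Sequence[SgRNACandidate], k: int = 11
) -> list[SgRNACandidate]:
    """First k candidates by the deterministic rank (frequency desc, then lex)."""
    ranked = sorted(candidates, key=lambda c: (-c.design_frequency, c.protospacer))
    return list(ranked[:k])


def _hamming_at_most(a: str, b: str, limit: int) -> int | None:
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return None
    return mm


def _scan_strand(seq: str, proto: str, max_mismatches: int) -> list[tuple[int, int]]:
    """(position, mismatches) of every protospacer+NGG hit in one strand."""
    hits = []
    span = PROTOSPACER_LEN + PAM_LEN
    if max_mismatches == 0:
        start = 0
        while True:
            p = seq.find(proto, start)
            if p < 0:
                break
            if p + span <= len(seq) and seq[p + 21 : p + 23] == "GG":
                hits.append((p, 0))
            start = p + 1
        return hits
    for p in range(len(seq) - span + 1):
        if seq[p + 21 : p + 23] != "GG":
            continue
        mm = _hamming_at_most(seq[p : p + PROTOSPACER_LEN], proto, max_mismatches)
        if mm is not None:
            hits.append((p, mm))
    return hits


def predict_cut_sites(
    candidate: SgRNACandidate,
    table: GeneTable,
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> list[CutSite]:
    """Every protospacer+NGG occurrence across the gene set's CDS.

    Mismatches (up to ``max_mismatches``) are allowed in the protospacer
    only; the PAM must be an exact NGG. Minus-strand positions are 0-based
    offsets within the reverse-complemented CDS.
    """
    sites = []
    for rec in table.sequenced_records():
        assert rec.cds_seq is not None
        for p, mm in _scan_strand(rec.cds_seq, candidate.protospacer, max_mismatches):
            sites.append(CutSite(rec.gene_id, "+", p, mm))
        if both_strands:
            rc = revcomp(rec.cds_seq)
            for p, mm in _scan_strand(rc, candidate.protospacer, max_mismatches):
                sites.append(CutSite(rec.gene_id, "-", p, mm))
    return sites


def specificity_report(
    candidates: Sequence[SgRNACandidate],
    table: GeneTable,
    clusters: Sequence[Cluster],
    max_mismatches: int = 0,
    both_strands: bool = True,
) -> SpecificityReport:
    """Candidate x cluster predicted-cut-site matrix with on-target fractions."""
    member_of = membership(clusters)
    cols = [cl.cluster_id for cl in clusters] + ["unclustered"]
    rows = {}
    fractions = {}
    targets = {}
    for cand in candidates:
        counts = Counter()
        for site in predict_cut_sites(cand, table, max_mismatches, both_strands):
            counts[member_of.get(site.gene_id, "unclustered")] += 1
        rows[cand.protospacer] = [counts.get(c, 0) for c in cols]
        total = sum(counts.values())
        on = sum(counts.get(c, 0) for c in cand.target_clusters)
        fractions[cand.protospacer] = on / total if total else float("nan")
        targets[cand.protospacer] = cand.target_clusters
    matrix = pd.DataFrame.from_dict(rows, orient="index", columns=[str(c) for c in cols])
    matrix.index.name = "protospacer"
    total_sites = matrix.sum(axis=1).rename("total_sites")
    return SpecificityReport(
        matrix=matrix,
        total_sites=total_sites,
        on_target_fraction=pd.Series(fractions, name="on_target_fraction"),
        target_clusters=targets,
    )


def write_candidate_table(
    candidates: Sequence[SgRNACandidate], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "protospacer": c.protospacer,
                "pam": c.pam,
                "target_clusters": ",".join(map(str, c.target_clusters)),
                "design_frequency": c.design_frequency,
            }
            for c in candidates
        ],
        columns=["protospacer", "pam", "target_clusters", "design_frequency"],
    ).to_csv(path, sep="\t", index=False)


def write_specificity(report: SpecificityReport, path: str | Path) -> None:
    df = report.matrix.copy()
    df["total_sites"] = report.total_sites
    df["on_target_fraction"] = report.on_target_fraction
    df["target_clusters"] = [
        ",".join(map(str, report.target_clusters[p])) for p in df.index
    ]
    df.to_csv(path, sep="\t")
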