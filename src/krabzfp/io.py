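"""Readers and writers for gene tables, FASTA sequence binding, and BED export.

Gene coordinates are 1-based inclusive on input (genome-browser convention);
BED output converts to 0-based half-open. Stop codons ('*' on proteins, a
terminal stop triplet on CDS) are stripped at load so downstream length
arithmetic is uniform: a bound record always satisfies
``len(cds_seq) == 3 * len(protein_seq)``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from ._codons import AA_ALPHABET, STOP_CODONS

logger = logging.getLogger(__name__)

GENE_TABLE_COLUMNS = ("gene_id", "species", "chromosome", "start", "end", "strand")

_STRAND_MAP = {"+": "+", "-": "-", "−": "-", ".": "unknown", "unknown": "unknown"}


class SchemaError(ValueError):
    """A table is missing a required column."""


class RowValidationError(ValueError):
    """A table row failed validation; carries the 1-based line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


@dataclass
class GeneRecord:
    """One gene: coordinates plus optionally bound protein/CDS sequence."""

    gene_id: str
    species: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str = "unknown"
    protein_seq: str | None = None
    cds_seq: str | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def sequenced(self) -> bool:
        return self.protein_seq is not None and self.cds_seq is not None


class GeneTable:
    """An ordered, id-unique collection of :class:`GeneRecord`."""

    def __init__(self, records: Iterable[GeneRecord], provenance: str = "synthetic"):
        self.records: list[GeneRecord] = list(records)
        self.provenance = provenance
        ids = [r.gene_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene_id(s): {dupes}")
        self._index = {r.gene_id: r for r in self.records}

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def get(self, gene_id: str) -> GeneRecord:
        return self._index[gene_id]

    def sorted_by_position(self) -> "GeneTable":
        recs = sorted(self.records, key=lambda r: (r.chromosome, r.start, r.end))
        return GeneTable(recs, provenance=self.provenance)

    def sequenced_records(self) -> list[GeneRecord]:
        return [r for r in self.records if r.sequenced]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "species": r.species,
                    "chromosome": r.chromosome,
                    "start": r.start,
                    "end": r.end,
                    "strand": r.strand,
                }
                for r in self.records
            ],
            columns=list(GENE_TABLE_COLUMNS),
        )


def read_gene_table(path: str | Path, species_filter: str | None = None) -> GeneTable:
    """Read a tab-separated gene table with the six required columns.

    Row order is preserved; rows not matching ``species_filter`` are dropped.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file") from None
        header = [h.strip() for h in header]
        for col in GENE_TABLE_COLUMNS:
            if col not in header:
                raise SchemaError(f"{path}: missing required column {col!r}")
        idx = {col: header.index(col) for col in GENE_TABLE_COLUMNS}
        records = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            values = {col: row[idx[col]].strip() for col in GENE_TABLE_COLUMNS}
            if species_filter is not None and values["species"] != species_filter:
                continue
            try:
                start = int(values["start"])
                end = int(values["end"])
            except ValueError:
                raise RowValidationError(
                    f"non-integer coordinate for {values['gene_id']}", lineno
                ) from None
            strand = _STRAND_MAP.get(values["strand"], None)
            if strand is None:
                raise RowValidationError(
                    f"bad strand {values['strand']!r} for {values['gene_id']}", lineno
                )
            try:
                rec = GeneRecord(
                    gene_id=values["gene_id"],
                    species=values["species"],
                    chromosome=values["chromosome"],
                    start=start,
                    end=end,
                    strand=strand,
                )
            except ValueError as exc:
                raise RowValidationError(str(exc), lineno) from None
            records.append(rec)
    return GeneTable(records, provenance=str(path))


def write_gene_table(table: GeneTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(GENE_TABLE_COLUMNS)
        for r in table:
            writer.writerow(
                [r.gene_id, r.species, r.chromosome, r.start, r.end, r.strand]
            )


def _read_fasta_unique(path: str | Path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def _strip_protein(seq: str) -> str:
    return seq[:-1] if seq.endswith("*") else seq


def _strip_cds(cds: str, protein_len: int) -> str:
    if len(cds) == 3 * protein_len + 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


def bind_sequences(
    table: GeneTable,
    protein_fasta: str | Path,
    cds_fasta: str | Path,
    strict_alphabet: bool = True,
) -> GeneTable:
    """Attach protein and CDS sequences (keyed by gene_id) to a gene table.

    Genes absent from either FASTA are kept but flagged ``unsequenced`` and
    excluded from sequence-dependent stages. Terminal stops are stripped.
    A CDS whose length is neither 3L nor 3L+3 (with stop) for protein length
    L raises a per-gene error.
    """
    proteins = _read_fasta_unique(protein_fasta)
    cdss = _read_fasta_unique(cds_fasta)
    out: list[GeneRecord] = []
    problems: list[str] = []
    n_unsequenced = 0
    for rec in table:
        prot = proteins.get(rec.gene_id)
        cds = cdss.get(rec.gene_id)
        if prot is None or cds is None:
            n_unsequenced += 1
            out.append(replace(rec, flags=rec.flags + ("unsequenced",)))
            continue
        prot = _strip_protein(prot)
        if strict_alphabet:
            bad = set(prot) - set(AA_ALPHABET)
            if bad:
                problems.append(
                    f"{rec.gene_id}: non-standard amino acid(s) {sorted(bad)}"
                )
                continue
        cds = _strip_cds(cds, len(prot))
        if len(cds) != 3 * len(prot):
            problems.append(
                f"{rec.gene_id}: CDS length {len(cds)} inconsistent with "
                f"protein length {len(prot)}"
            )
            continue
        out.append(replace(rec, protein_seq=prot, cds_seq=cds))
    if problems:
        raise ValueError("sequence binding failed:\n" + "\n".join(problems))
    if n_unsequenced:
        logger.warning(
            "%d of %d genes lack sequences and are excluded from "
            "sequence-dependent stages",
            n_unsequenced,
            len(table),
        )
    return GeneTable(out, provenance=table.provenance)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(clusters, path: str | Path) -> None:
    """Export clusters as BED6 (0-based half-open; score = member count)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# cluster export: chrom, start(0-based), end, name, n_members, strand\n")
        for cl in sorted(clusters, key=lambda c: (c.chromosome, c.span_start)):
            fh.write(
                f"{cl.chromosome}\t{cl.span_start - 1}\t{cl.span_end}"
                f"\tcluster_{cl.cluster_id}\t{len(cl.members)}\t.\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, int]]:
    """Minimal BED reader used for round-trip checks: (chrom, start, end, name, score)."""
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], int(f[4])))
    return rows
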