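"""C2H2 zinc-finger array annotation: overlapping ZnF and Linker tiles.

A KRAB-ZFP's tandem array is decomposed into two overlapping tile sets:

* **ZnF tiles** run from the first zinc-coordinating cysteine pair to the
  histidine pair, CXXC ... HXXXH (default spacing C-X2-C-X12-H-X3-H,
  21 residues).
* **Linker tiles** run from one ZnF's HXXXH through the inter-finger linker
  into the next ZnF's CXXC, so consecutive tiles overlap and together the
  two sets cover the whole array.

Each ZnF carries a three-residue *fingerprint* — the DNA-contacting residues
at alpha-helix positions -1, +3 and +6. With the first zinc-coordinating
histidine at helix position +7, those sit at offsets H1-8, H1-4 and H1-1
of the tile, which is the convention implemented (and shared by the
synthetic generator) since His-anchoring stays valid for any spacer length.

Matching is a greedy leftmost non-overlapping scan; within a variable
spacer range the shortest spacer is preferred (deterministic tie-break).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .io import GeneRecord


@dataclass(frozen=True)
class PatternConfig:
    """Spacer ranges of the C2H2 pattern C-X{a}-C-X{b}-H-X{c}-H.

    Defaults are the exact C-X2-C-X12-H-X3-H tiling; real-data runs can
    widen to e.g. (2,4)/(10,14)/(3,5).
    """

    cc_spacer: tuple[int, int] = (2, 2)
    ch_spacer: tuple[int, int] = (12, 12)
    hh_spacer: tuple[int, int] = (3, 3)

    def __post_init__(self) -> None:
        for lo, hi in (self.cc_spacer, self.ch_spacer, self.hh_spacer):
            if not (0 <= lo <= hi):
                raise ValueError("spacer ranges must satisfy 0 <= lo <= hi")
        if self.ch_spacer[0] < 8:
            # fingerprint offsets H1-8 .. H1-1 must fall inside the tile
            raise ValueError("C..H spacer must be at least 8 for fingerprints")

    @property
    def regex(self) -> re.Pattern:
        (a0, a1), (b0, b1), (c0, c1) = self.cc_spacer, self.ch_spacer, self.hh_spacer
        # lazy quantifiers -> shortest spacer preferred at each leftmost start
        return re.compile(
            f"C(.{{{a0},{a1}}}?)C(.{{{b0},{b1}}}?)H(.{{{c0},{c1}}}?)H"
        )


@dataclass
class ZnFUnit:
    gene_id: str
    ordinal: int  # >= 1 from the N terminus
    aa_span: tuple[int, int]  # protein positions, 1-based inclusive
    aa_seq: str
    nt_seq: str
    fingerprint: str
    h1_offset: int  # 0-based offset of the first His within aa_seq
    c2_offset: int  # 0-based offset of the second Cys within aa_seq


@dataclass
class LinkerUnit:
    gene_id: str
    ordinal: int  # linker i joins ZnF i and ZnF i+1
    aa_span: tuple[int, int]
    aa_seq: str
    nt_seq: str
    pam_offsets: tuple[int, ...]  # 0-based NGG starts within nt_seq, coding strand


@dataclass
class ZnFArrayAnnotation:
    gene_id: str
    znfs: list[ZnFUnit] = field(default_factory=list)
    linkers: list[LinkerUnit] = field(default_factory=list)
    unmatched_tail_aa: int = 0
    warnings: tuple[str, ...] = ()

    @property
    def n_znfs(self) -> int:
        return len(self.znfs)

    @property
    def fingerprints(self) -> list[str]:
        return [z.fingerprint for z in self.znfs]


def find_pam_offsets(nt_seq: str) -> tuple[int, ...]:
    """All 0-based offsets o with nt_seq[o+1:o+3] == 'GG' (NGG motif)."""
    return tuple(
        o for o in range(len(nt_seq) - 2) if nt_seq[o + 1 : o + 3] == "GG"
    )


def _nt_slice(cds: str, aa_start: int, aa_end: int) -> str:
    """CDS slice covering 1-based inclusive protein positions [aa_start, aa_end]."""
    lo, hi = 3 * (aa_start - 1), 3 * aa_end
    if hi > len(cds):
        raise ValueError(
            f"protein span {aa_start}-{aa_end} maps past CDS end ({len(cds)} nt)"
        )
    return cds[lo:hi]


def _fingerprint_from_match(aa_seq: str, h1_offset: int) -> str:
    return aa_seq[h1_offset - 8] + aa_seq[h1_offset - 4] + aa_seq[h1_offset - 1]


def extract_fingerprint(znf_aa: str, pattern: PatternConfig | None = None) -> str:
    """Fingerprint (helix -1/+3/+6 residues) of one ZnF tile.

    The tile must match the configured C2H2 pattern exactly.
    """
    pattern = pattern or PatternConfig()
    m = pattern.regex.fullmatch(znf_aa)
    if m is None:
        raise ValueError(f"sequence does not match the C2H2 pattern: {znf_aa!r}")
    h1_offset = m.start(3) - 1  # group 3 = H..H spacer; H1 right before it
    return _fingerprint_from_match(znf_aa, h1_offset)


def annotate_znf_array(
    gene: GeneRecord, pattern: PatternConfig | None = None
) -> ZnFArrayAnnotation:
    """Tile one gene's protein (and CDS) into ZnF and Linker units."""
    pattern = pattern or PatternConfig()
    if not gene.sequenced:
        raise ValueError(f"{gene.gene_id}: protein/CDS not bound")
    protein, cds = gene.protein_seq, gene.cds_seq
    assert protein is not None and cds is not None
    if len(cds) != 3 * len(protein):
        raise ValueError(
            f"{gene.gene_id}: CDS length {len(cds)} != 3 x protein length"
        )

    znfs: list[ZnFUnit] = []
    for m in pattern.regex.finditer(protein):
        aa_start, aa_end = m.start() + 1, m.end()  # 1-based inclusive
        aa_seq = m.group(0)
        h1_offset = m.start(3) - 1 - m.start()
        c2_offset = m.end(1) - m.start()
        znfs.append(
            ZnFUnit(
                gene_id=gene.gene_id,
                ordinal=len(znfs) + 1,
                aa_span=(aa_start, aa_end),
                aa_seq=aa_seq,
                nt_seq=_nt_slice(cds, aa_start, aa_end),
                fingerprint=_fingerprint_from_match(aa_seq, h1_offset),
                h1_offset=h1_offset,
                c2_offset=c2_offset,
            )
        )

    linkers: list[LinkerUnit] = []
    for i in range(len(znfs) - 1):
        left, right = znfs[i], znfs[i + 1]
        # from the first His of ZnF i's HXXXH to the last Cys of ZnF i+1's CXXC
        aa_start = left.aa_span[0] + left.h1_offset
        aa_end = right.aa_span[0] + right.c2_offset
        aa_seq = protein[aa_start - 1 : aa_end]
        nt_seq = _nt_slice(cds, aa_start, aa_end)
        linkers.append(
            LinkerUnit(
                gene_id=gene.gene_id,
                ordinal=i + 1,
                aa_span=(aa_start, aa_end),
                aa_seq=aa_seq,
                nt_seq=nt_seq,
                pam_offsets=find_pam_offsets(nt_seq),
            )
        )

    warnings = () if znfs else ("no C2H2 pattern match",)
    tail = len(protein) - znfs[-1].aa_span[1] if znfs else 0
    return ZnFArrayAnnotation(
        gene_id=gene.gene_id,
        znfs=znfs,
        linkers=linkers,
        unmatched_tail_aa=tail,
        warnings=warnings,
    )


def annotate_table(
    records: Iterable[GeneRecord], pattern: PatternConfig | None = None
) -> dict[str, ZnFArrayAnnotation]:
    """Annotate every sequenced record; returns gene_id -> annotation."""
    pattern = pattern or PatternConfig()
    return {
        rec.gene_id: annotate_znf_array(rec, pattern)
        for rec in records
        if rec.sequenced
    }


def tile_census(annotations: Iterable[ZnFArrayAnnotation] | Mapping[str, ZnFArrayAnnotation]):
    """Totals over a set of annotations: ZnF count, distinct fingerprints, per-gene counts."""
    if isinstance(annotations, Mapping):
        annotations = annotations.values()
    anns = list(annotations)
    per_gene = pd.Series(
        {a.gene_id: a.n_znfs for a in anns}, dtype=int, name="n_znfs"
    )
    fingerprints = [fp for a in anns for fp in a.fingerprints]
    return {
        "total_znfs": len(fingerprints),
        "distinct_fingerprints": len(set(fingerprints)),
        "per_gene_znf_counts": per_gene,
    }


def write_tile_table(
    annotations: Mapping[str, ZnFArrayAnnotation], path: str | Path
) -> None:
    """Tab-separated tile export (both tile types, ordered per gene)."""
    rows = []
    for gene_id in sorted(annotations):
        ann = annotations[gene_id]
        for z in ann.znfs:
            rows.append(
                (gene_id, "ZnF", z.ordinal, f"{z.aa_span[0]}-{z.aa_span[1]}",
                 z.aa_seq, z.nt_seq, z.fingerprint, "")
            )
        for l in ann.linkers:
            rows.append(
                (gene_id, "Linker", l.ordinal, f"{l.aa_span[0]}-{l.aa_span[1]}",
                 l.aa_seq, l.nt_seq, "", ",".join(map(str, l.pam_offsets)))
            )
    df = pd.DataFrame(
        rows,
        columns=["gene_id", "tile_type", "ordinal", "aa_span", "aa_seq",
                 "nt_seq", "fingerprint", "pam_offsets"],
    )
    df.to_csv(path, sep="\t", index=False)
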