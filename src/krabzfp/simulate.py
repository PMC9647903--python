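"""Synthetic KRAB-ZFP gene families with planted, machine-checkable truth.

The generator emits a cross-consistent bundle — gene coordinate table,
protein/CDS FASTA, TPM expression table and a ground-truth record — that
emulates the structures seen in real KRAB-ZFP families:

* genes laid out in same-chromosome clusters whose neighbour gaps fall
  below the 200 kb clustering threshold, plus isolated genes placed far
  from everything else;
* per-cluster fingerprint pools reused at high, weighted frequency
  (cluster-private, so exclusivity statistics have an exact answer);
* near-identical cluster-specific linker sequences whose nucleotide
  consensus carries exactly two NGG motifs usable as Cas9 PAM sites, with
  the 20-nt protospacer windows of both PAMs lying wholly inside the
  linker;
* CDS consistent codon-for-codon with the protein;
* an expression table in which designated clusters are coherently high in
  one sample.

Noise knobs: ``synonymous_wobble_rate`` varies codons in ZnF tiles and
flanks (linker nucleotide identity is preserved, mirroring the strong
nucleotide-level linker conservation of real families), and
``linker_mutation_rate`` substitutes linker codons synonymously under
constraints that preserve the reading frame and the planted GG set, so the
two PAMs survive while protospacer identity and per-position information
content erode. All randomness comes from one ``numpy`` Generator seeded
once, and every draw is made unconditionally, so the mutation sets produced
at different rates from the same seed are nested — higher rates strictly
add noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._codons import PREFERRED_CODON, SYNONYMOUS_CODONS
from .annotation import find_pam_offsets
from .io import GeneRecord, GeneTable, write_fasta, write_gene_table
from .expression import write_expression_table

PROTOSPACER_LEN = 20

# Base linker consensus: HXXXH (of ZnF i) + inter-finger spacer + CXXC (of
# ZnF i+1), 14 aa / 42 nt. Codons are fixed so the nucleotide consensus
# carries exactly two GG dinucleotides: TGG (Trp, spacer) giving a PAM at
# offset 24 and CGG (Arg, inside CXXC) giving a PAM at offset 33. Both
# 20-nt protospacer windows then sit entirely within the linker.
_BASE_LINKER_AA = "HQRTHTNEWPCRKC"
_BASE_LINKER_CODONS = (
    "CAC", "CAA", "AGA", "ACA", "CAT", "ACT", "AAC",
    "GAA", "TGG", "CCA", "TGC", "CGG", "AAA", "TGT",
)
_PLANTED_CODON_IDX = (8, 11)  # TGG / CGG; never mutated
_VARIABLE_IDX = (1, 2, 3, 5, 6)  # cluster-identity positions (0-based aa)
_PLANTED_GG = (25, 34)  # GG dinucleotide starts in the 42-nt consensus

# G-free codon choices for the variable positions (no C/H/W, which would
# disturb the C2H2 pattern, and no G anywhere, so no stray NGG can arise).
_VARIANT_CODONS: dict[str, tuple[str, ...]] = {
    "N": ("AAC", "AAT"),
    "T": ("ACA", "ACT", "ACC"),
    "Q": ("CAA",),
    "S": ("TCA", "TCT", "TCC"),
    "I": ("ATT", "ATC", "ATA"),
    "L": ("CTT", "CTC", "CTA", "TTA"),
    "K": ("AAA",),
    "F": ("TTT", "TTC"),
    "Y": ("TAT", "TAC"),
    "P": ("CCA", "CCT", "CCC"),
}
_VARIANT_CHOICES = tuple(
    (aa, codon) for aa in sorted(_VARIANT_CODONS) for codon in _VARIANT_CODONS[aa]
)

# amino acids allowed in flanks, ZnF interiors and fingerprints: everything
# except Cys/His, which would perturb the C2H2 scan
INTERIOR_AA = "ADEFGIKLMNPQRSTVWY"


def _gg_positions(nt: str) -> tuple[int, ...]:
    return tuple(i for i in range(len(nt) - 1) if nt[i : i + 2] == "GG")


@dataclass(frozen=True)
class ClusterSpec:
    n_members: int
    gap_range: tuple[int, int] = (5_000, 150_000)  # bp between neighbours

    def __post_init__(self) -> None:
        if self.n_members < 2:
            raise ValueError("planted clusters need at least 2 members")
        lo, hi = self.gap_range
        if not (0 < lo <= hi):
            raise ValueError("gap_range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class ExpressionSpec:
    sample: str
    mean_tpm: float = 50.0
    penetrance: float = 0.6  # per-member probability of being "high"

    def __post_init__(self) -> None:
        if not (0.0 <= self.penetrance <= 1.0):
            raise ValueError("penetrance must be in [0,1]")


@dataclass(frozen=True)
class FamilyConfig:
    """Study conditions for one synthetic family.

    Defaults: three clusters of 5/4/3 members plus two isolated genes on
    three chromosomes, 4-8 ZnFs per gene, six-fingerprint cluster pools
    with geometric-ish weights, mild linker divergence (1% per-nucleotide)
    and moderate synonymous ZnF wobble (10%), each cluster coherently high
    (60% penetrance, ~50 TPM) in one sample.
    """

    seed: int = 42
    n_chromosomes: int = 3
    clusters: tuple[ClusterSpec, ...] = (
        ClusterSpec(5), ClusterSpec(4), ClusterSpec(3),
    )
    isolated_genes: int = 2
    znf_per_gene: tuple[int, int] = (4, 8)
    fingerprint_pool_size: int = 6
    pool_weights: tuple[float, ...] = (0.35, 0.25, 0.15, 0.12, 0.08, 0.05)
    linker_mutation_rate: float = 0.01
    synonymous_wobble_rate: float = 0.10
    samples: tuple[str, ...] = ("mESC", "forebrain", "gut")
    expression: tuple[ExpressionSpec, ...] | None = None  # per cluster; default cycles samples
    high_tpm: float = 50.0
    penetrance: float = 0.6
    background_tpm: tuple[float, float] = (0.0, 3.0)

    def __post_init__(self) -> None:
        for rate in (self.linker_mutation_rate, self.synonymous_wobble_rate):
            if not (0.0 <= rate <= 1.0):
                raise ValueError("rates must be in [0,1]")
        if len(self.pool_weights) != self.fingerprint_pool_size:
            raise ValueError("pool_weights must match fingerprint_pool_size")
        if abs(sum(self.pool_weights) - 1.0) > 1e-9:
            raise ValueError("pool_weights must sum to 1")
        lo, hi = self.znf_per_gene
        if not (2 <= lo <= hi):
            raise ValueError("znf_per_gene range must be >= 2")
        if self.expression is not None and len(self.expression) != len(self.clusters):
            raise ValueError("expression specs must align with clusters")

    def expression_specs(self) -> tuple[ExpressionSpec, ...]:
        if self.expression is not None:
            return self.expression
        return tuple(
            ExpressionSpec(
                sample=self.samples[i % len(self.samples)],
                mean_tpm=self.high_tpm,
                penetrance=self.penetrance,
            )
            for i in range(len(self.clusters))
        )

    @classmethod
    def from_dict(cls, data: dict) -> "FamilyConfig":
        data = dict(data)
        if "clusters" in data:
            data["clusters"] = tuple(
                ClusterSpec(**c) if isinstance(c, dict) else ClusterSpec(int(c))
                for c in data["clusters"]
            )
        if data.get("expression") is not None:
            data["expression"] = tuple(
                ExpressionSpec(**e) for e in data["expression"]
            )
        for key in ("znf_per_gene", "pool_weights", "samples", "background_tpm"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class LinkerConsensus:
    """One unit's cluster-identity linker: aa, codons, planted guides."""

    aa: str
    codons: tuple[str, ...]

    @property
    def nt(self) -> str:
        return "".join(self.codons)

    @property
    def pam_offsets(self) -> tuple[int, ...]:
        return find_pam_offsets(self.nt)

    def protospacers(self) -> tuple[tuple[str, str], ...]:
        """(protospacer, pam) for each planted PAM with a full in-linker window."""
        nt = self.nt
        return tuple(
            (nt[o - PROTOSPACER_LEN : o], nt[o : o + 3])
            for o in self.pam_offsets
            if o >= PROTOSPACER_LEN
        )


@dataclass
class PlantedCluster:
    cluster_id: int
    chromosome: str
    gene_ids: tuple[str, ...]
    span: tuple[int, int]
    linker_consensus_nt: str
    pam_offsets: tuple[int, ...]
    protospacers: tuple[tuple[str, str], ...]
    n_linkers: int
    protospacer_counts: dict[str, int]  # intact windows actually emitted


@dataclass
class GroundTruth:
    clusters: list[PlantedCluster]
    isolated_genes: tuple[str, ...]
    fingerprints: dict[str, tuple[str, ...]]  # gene -> planted triplets in order
    fingerprint_pools: dict[int, tuple[str, ...]]  # cluster_id -> private pool
    high_expression: dict[str, tuple[str, ...]]  # sample -> planted high genes


@dataclass
class FamilyBundle:
    table: GeneTable
    proteins: dict[str, str]
    cds: dict[str, str]  # no stop codon
    expression: pd.DataFrame
    truth: GroundTruth
    config: FamilyConfig


def _make_linker_variant(
    rng: np.random.Generator, used_keys: set[tuple[str, ...]]
) -> LinkerConsensus:
    """Draw a cluster-identity linker variant with a unique signature.

    Uniqueness is keyed on the *amino acids* at the two variable positions
    that fall inside both protospacer windows (spacer positions 6 and 7).
    Distinct amino acids always differ at the nucleotide level, so no
    synonymous mutation can ever turn one unit's guide into another's.
    """
    for _ in range(1000):
        codons = list(_BASE_LINKER_CODONS)
        aa = list(_BASE_LINKER_AA)
        picks = rng.integers(0, len(_VARIANT_CHOICES), size=len(_VARIABLE_IDX))
        for idx, pick in zip(_VARIABLE_IDX, picks):
            aa[idx], codons[idx] = _VARIANT_CHOICES[int(pick)]
        key = (aa[5], aa[6])
        if key in used_keys:
            continue
        cons = LinkerConsensus("".join(aa), tuple(codons))
        if _gg_positions(cons.nt) != _PLANTED_GG:  # pragma: no cover - by construction
            continue
        used_keys.add(key)
        return cons
    raise RuntimeError("could not draw a fresh linker variant")


def _safe_synonymous_alts(
    codons: tuple[str, ...], idx: int, aa: str
) -> list[str]:
    """Synonymous alternatives at ``idx`` that leave the GG set untouched.

    Validated against the pristine consensus neighbours (not previously
    mutated ones), which keeps the accept/reject decision independent of
    mutation order and hence nested across rates.
    """
    prev_last = codons[idx - 1][-1] if idx > 0 else ""
    next_first = codons[idx + 1][0] if idx < len(codons) - 1 else ""
    out = []
    for alt in SYNONYMOUS_CODONS[aa]:
        if alt == codons[idx] or "GG" in alt:
            continue
        if alt.endswith("G") and next_first == "G":
            continue
        if alt.startswith("G") and prev_last == "G":
            continue
        out.append(alt)
    return out


def _mutate_linker(
    rng: np.random.Generator, cons: LinkerConsensus, rate: float
) -> list[str]:
    """One linker instance: synonymous divergence at per-nt rate ``rate``.

    Draws are made for every codon regardless of outcome so the random
    stream is identical across rates.
    """
    p_codon = 1.0 - (1.0 - rate) ** 3
    out = list(cons.codons)
    for idx, aa in enumerate(cons.aa):
        u = rng.random()
        j = int(rng.integers(0, 2**16))
        if idx in _PLANTED_CODON_IDX or u >= p_codon:
            continue
        alts = _safe_synonymous_alts(cons.codons, idx, aa)
        if alts:
            out[idx] = alts[j % len(alts)]
    return out


def _wobble_codon(rng: np.random.Generator, aa: str, codon: str, rate: float) -> str:
    u = rng.random()
    j = int(rng.integers(0, 2**16))
    syn = [c for c in SYNONYMOUS_CODONS[aa] if c != codon]
    if u < rate and syn:
        return syn[j % len(syn)]
    return codon


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(INTERIOR_AA[int(i)] for i in rng.integers(0, len(INTERIOR_AA), n))


def _draw_fingerprint_pools(
    rng: np.random.Generator, n_pools: list[int]
) -> list[tuple[str, ...]]:
    """Globally disjoint fingerprint pools (so planted pools are private)."""
    seen: set[str] = set()
    pools = []
    for size in n_pools:
        pool = []
        while len(pool) < size:
            fp = _random_aa(rng, 3)
            if fp not in seen:
                seen.add(fp)
                pool.append(fp)
        pools.append(tuple(pool))
    return pools


class _GeneBuilder:
    """Assembles one gene's protein/CDS from planted parts."""

    def __init__(self, rng: np.random.Generator, config: FamilyConfig):
        self.rng = rng
        self.config = config

    def build(
        self,
        cons: LinkerConsensus,
        pool: tuple[str, ...],
        weights: tuple[float, ...],
    ) -> tuple[str, str, tuple[str, ...], list[list[str]]]:
        """Returns (protein, cds, fingerprints, emitted linker codon lists)."""
        rng, cfg = self.rng, self.config
        lo, hi = cfg.znf_per_gene
        n_znf = int(rng.integers(lo, hi + 1))
        fps = tuple(
            pool[int(i)]
            for i in rng.choice(len(pool), size=n_znf, p=np.asarray(weights))
        )
        aa_parts: list[str] = []
        codon_parts: list[str] = []

        def emit_wobble(aa_seq: str, codons: tuple[str, ...] | None = None) -> None:
            for k, aa in enumerate(aa_seq):
                base = codons[k] if codons is not None else PREFERRED_CODON[aa]
                codon_parts.append(
                    _wobble_codon(rng, aa, base, cfg.synonymous_wobble_rate)
                )
            aa_parts.append(aa_seq)

        hxxxh_aa, hxxxh_codons = cons.aa[:5], cons.codons[:5]
        cxxc_aa, cxxc_codons = cons.aa[10:], cons.codons[10:]

        emit_wobble(_random_aa(rng, int(rng.integers(15, 31))))  # N flank
        emit_wobble(cxxc_aa, cxxc_codons)  # first ZnF's CXXC (not in a linker)
        linkers_emitted: list[list[str]] = []
        for j in range(n_znf):
            interior = list(_random_aa(rng, 12))
            interior[4], interior[8], interior[11] = fps[j]  # helix -1/+3/+6
            emit_wobble("".join(interior))
            if j < n_znf - 1:
                mut = _mutate_linker(rng, cons, cfg.linker_mutation_rate)
                linkers_emitted.append(mut)
                codon_parts.extend(mut)
                aa_parts.append(cons.aa)
            else:
                emit_wobble(hxxxh_aa, hxxxh_codons)  # last ZnF's HXXXH
        emit_wobble(_random_aa(rng, int(rng.integers(5, 16))))  # C flank

        protein = "".join(aa_parts)
        cds = "".join(codon_parts)
        return protein, cds, fps, linkers_emitted


def _count_intact_windows(
    linkers: list[list[str]], cons: LinkerConsensus
) -> dict[str, int]:
    counts = {proto: 0 for proto, _ in cons.protospacers()}
    for codon_list in linkers:
        nt = "".join(codon_list)
        for o in cons.pam_offsets:
            if o < PROTOSPACER_LEN:
                continue
            proto = nt[o - PROTOSPACER_LEN : o]
            if proto in counts and nt[o + 1 : o + 3] == "GG":
                counts[proto] += 1
    return counts


def generate_family(config: FamilyConfig | None = None) -> FamilyBundle:
    """Generate one synthetic family bundle. Deterministic given the seed."""
    config = config or FamilyConfig()
    rng = np.random.default_rng(config.seed)
    builder = _GeneBuilder(rng, config)

    n_clusters = len(config.clusters)
    n_units = n_clusters + config.isolated_genes  # isolated genes get own variants
    used: set[tuple[str, ...]] = set()
    variants = [_make_linker_variant(rng, used) for _ in range(n_units)]
    pool_sizes = [config.fingerprint_pool_size] * n_clusters + [3] * config.isolated_genes
    pools = _draw_fingerprint_pools(rng, pool_sizes)
    iso_weights = (0.5, 0.3, 0.2)

    chrom_names = [f"chr{i + 1:02d}" for i in range(config.n_chromosomes)]
    cursors = {c: 1_000_000 for c in chrom_names}

    records: list[GeneRecord] = []
    proteins: dict[str, str] = {}
    cds_map: dict[str, str] = {}
    fingerprints: dict[str, tuple[str, ...]] = {}
    gene_counter = 0
    planted: list[dict] = []

    def next_gene_id() -> str:
        nonlocal gene_counter
        gene_counter += 1
        return f"sZfp{gene_counter:03d}"

    for ci, spec in enumerate(config.clusters):
        chrom = chrom_names[ci % len(chrom_names)]
        cons, pool = variants[ci], pools[ci]
        pos = cursors[chrom]
        member_ids = []
        n_linkers = 0
        counts = {proto: 0 for proto, _ in cons.protospacers()}
        for m in range(spec.n_members):
            gid = next_gene_id()
            protein, cds, fps, linkers = builder.build(cons, pool, config.pool_weights)
            for proto, c in _count_intact_windows(linkers, cons).items():
                counts[proto] += c
            n_linkers += len(linkers)
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos
            end = start + len(cds) - 1
            records.append(
                GeneRecord(gid, "synthetic", chrom, start, end, strand,
                           protein_seq=protein, cds_seq=cds)
            )
            proteins[gid], cds_map[gid] = protein, cds
            fingerprints[gid] = fps
            member_ids.append(gid)
            gap = int(rng.integers(spec.gap_range[0], spec.gap_range[1] + 1))
            pos = end + gap
        span = (records[-len(member_ids)].start, records[-1].end)
        cursors[chrom] = records[-1].end + 2_000_000
        planted.append(
            dict(chromosome=chrom, gene_ids=tuple(member_ids), span=span,
                 cons=cons, n_linkers=n_linkers, counts=counts, pool=pool)
        )

    isolated_ids = []
    for k in range(config.isolated_genes):
        chrom = chrom_names[(n_clusters + k) % len(chrom_names)]
        cons, pool = variants[n_clusters + k], pools[n_clusters + k]
        gid = next_gene_id()
        protein, cds, fps, _ = builder.build(cons, pool, iso_weights)
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom]
        end = start + len(cds) - 1
        records.append(
            GeneRecord(gid, "synthetic", chrom, start, end, strand,
                       protein_seq=protein, cds_seq=cds)
        )
        proteins[gid], cds_map[gid] = protein, cds
        fingerprints[gid] = fps
        isolated_ids.append(gid)
        cursors[chrom] = end + 2_000_000

    # cluster ids as the caller will assign them: (chromosome lex, span start)
    order = sorted(range(len(planted)),
                   key=lambda i: (planted[i]["chromosome"], planted[i]["span"][0]))
    truth_clusters = []
    id_of_planted = {}
    for cid, i in enumerate(order, start=1):
        p = planted[i]
        id_of_planted[i] = cid
        truth_clusters.append(
            PlantedCluster(
                cluster_id=cid,
                chromosome=p["chromosome"],
                gene_ids=p["gene_ids"],
                span=p["span"],
                linker_consensus_nt=p["cons"].nt,
                pam_offsets=p["cons"].pam_offsets,
                protospacers=p["cons"].protospacers(),
                n_linkers=p["n_linkers"],
                protospacer_counts=p["counts"],
            )
        )

    # expression: backgrounds first, then planted highs, one stream order
    all_ids = [r.gene_id for r in records]
    tpm = pd.DataFrame(
        rng.uniform(config.background_tpm[0], config.background_tpm[1],
                    size=(len(all_ids), len(config.samples))),
        index=pd.Index(all_ids, name="gene_id"),
        columns=list(config.samples),
    )
    high_sets: dict[str, list[str]] = {s: [] for s in config.samples}
    for i, espec in enumerate(config.expression_specs()):
        for gid in planted[i]["gene_ids"]:
            u = rng.random()
            v = rng.uniform(0.8 * espec.mean_tpm, 1.2 * espec.mean_tpm)
            if u < espec.penetrance:
                tpm.loc[gid, espec.sample] = v
                high_sets[espec.sample].append(gid)

    truth = GroundTruth(
        clusters=truth_clusters,
        isolated_genes=tuple(isolated_ids),
        fingerprints=fingerprints,
        fingerprint_pools={
            id_of_planted[i]: planted[i]["pool"] for i in range(len(planted))
        },
        high_expression={s: tuple(sorted(v)) for s, v in high_sets.items()},
    )
    table = GeneTable(records, provenance="synthetic")
    return FamilyBundle(table, proteins, cds_map, tpm, truth, config)


@dataclass
class TruthReport:
    ok: bool
    failures: list[str]


def truth_check(bundle: FamilyBundle) -> TruthReport:
    """Cross-consistency audit of an emitted bundle against its ground truth.

    Uses an independent translation route (Biopython) rather than the
    generator's own codon table.
    """
    failures: list[str] = []
    for rec in bundle.table:
        assert rec.cds_seq is not None and rec.protein_seq is not None
        translated = str(Seq(rec.cds_seq).translate())
        if translated != rec.protein_seq:
            failures.append(f"{rec.gene_id}: CDS does not translate to protein")
        if rec.start > rec.end:
            failures.append(f"{rec.gene_id}: start > end")

    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in bundle.table:
        by_chrom.setdefault(rec.chromosome, []).append(rec)
    for chrom, recs in by_chrom.items():
        starts = [r.start for r in recs]
        if starts != sorted(starts):
            failures.append(f"{chrom}: coordinates not emitted in sorted order")
        for a, b in zip(recs, recs[1:]):
            if b.start <= a.end:
                failures.append(f"{chrom}: {a.gene_id}/{b.gene_id} overlap")

    for cl in bundle.truth.clusters:
        member_cds = [bundle.cds[g] for g in cl.gene_ids]
        other_cds = [
            bundle.cds[g]
            for g in bundle.cds
            if g not in cl.gene_ids
        ]
        for proto, pam in cl.protospacers:
            expected = cl.protospacer_counts[proto]
            found = sum(s.count(proto) for s in member_cds)
            if found != expected:
                failures.append(
                    f"cluster {cl.cluster_id}: protospacer {proto} found "
                    f"{found}x, expected {expected}x"
                )
            leaked = sum(s.count(proto) for s in other_cds)
            if leaked:
                failures.append(
                    f"cluster {cl.cluster_id}: protospacer {proto} leaks "
                    f"into {leaked} non-member site(s)"
                )

    for sample, genes in bundle.truth.high_expression.items():
        for g in genes:
            if bundle.expression.loc[g, sample] < 25.0:
                failures.append(f"{g}: planted high but TPM < 25 in {sample}")

    return TruthReport(ok=not failures, failures=failures)


def write_family(bundle: FamilyBundle, outdir: str | Path) -> dict[str, Path]:
    """Write genes.tsv, protein.fa, cds.fa (with stop), tpm.tsv, truth.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": outdir / "genes.tsv",
        "protein": outdir / "protein.fa",
        "cds": outdir / "cds.fa",
        "tpm": outdir / "tpm.tsv",
        "truth": outdir / "truth.json",
    }
    write_gene_table(bundle.table, paths["genes"])
    write_fasta(bundle.proteins, paths["protein"])
    write_fasta({g: s + "TAA" for g, s in bundle.cds.items()}, paths["cds"])
    write_expression_table(bundle.expression, paths["tpm"])
    truth = asdict(bundle.truth)
    with paths["truth"].open("w") as fh:
        json.dump(truth, fh, indent=1, default=list)
    return paths
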