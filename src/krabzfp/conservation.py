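"""Position-frequency / information-content profiles for tile sets.

These are the data behind sequence logos: for a stack of same-length tiles
(amino-acid or nucleotide), per-position letter frequencies and information
content ic[p] = log2(|alphabet|) - H(freqs[p]) in bits, with no small-sample
correction. Variable-length tile sets are reduced to the modal length (no
alignment is attempted); the discarded fraction is reported. Conserved NGG
PAM candidates are positions where both G columns of a nucleotide profile
exceed a frequency threshold.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._codons import AA_ALPHABET, NT_ALPHABET
from .annotation import ZnFArrayAnnotation
from .clusters import Cluster

ALPHABETS = {"aa": AA_ALPHABET, "nt": NT_ALPHABET}


@dataclass
class ConservationProfile:
    alphabet: str  # "aa" or "nt"
    freqs: pd.DataFrame  # positions x letters, rows sum to 1
    ic: np.ndarray  # bits, one per position
    n_sequences: int
    n_discarded: int
    provenance: str = ""

    @property
    def length(self) -> int:
        return len(self.freqs)

    @property
    def max_bits(self) -> float:
        return float(np.log2(len(ALPHABETS[self.alphabet])))

    def mean_ic(self) -> float:
        return float(self.ic.mean())


@dataclass
class PamSiteReport:
    pam_offsets: tuple[int, ...]  # 0-based start of each conserved NGG
    g_frequency: dict[int, float] = field(default_factory=dict)  # min G freq per site


def modal_length(seqs: Sequence[str]) -> int:
    """Most common length; ties broken toward the shorter length."""
    counts = Counter(len(s) for s in seqs)
    return min(counts, key=lambda l: (-counts[l], l))


def build_profile(
    tiles: Sequence[str], alphabet: str, provenance: str = ""
) -> ConservationProfile:
    """Frequency/IC profile of a same-type tile stack.

    Tiles off the modal length are excluded and counted in ``n_discarded``.
    """
    if alphabet not in ALPHABETS:
        raise ValueError(f"alphabet must be one of {sorted(ALPHABETS)}")
    tiles = [t.upper() for t in tiles if t]
    if not tiles:
        raise ValueError("no sequences to profile")
    L = modal_length(tiles)
    kept = [t for t in tiles if len(t) == L]
    letters = ALPHABETS[alphabet]
    bad = set("".join(kept)) - set(letters)
    if bad:
        raise ValueError(f"letters outside {alphabet} alphabet: {sorted(bad)}")

    counts = np.zeros((L, len(letters)), dtype=float)
    col = {c: j for j, c in enumerate(letters)}
    for t in kept:
        for p, c in enumerate(t):
            counts[p, col[c]] += 1.0
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    ic = np.log2(len(letters)) - entropy
    return ConservationProfile(
        alphabet=alphabet,
        freqs=pd.DataFrame(freqs, columns=list(letters)),
        ic=ic,
        n_sequences=len(kept),
        n_discarded=len(tiles) - len(kept),
        provenance=provenance,
    )


def _gather_tiles(
    annotations: Mapping[str, ZnFArrayAnnotation],
    gene_ids: Iterable[str],
    tile_type: str,
    alphabet: str,
) -> list[str]:
    attr = {"znf": "znfs", "linker": "linkers"}[tile_type.lower()]
    seq_attr = {"aa": "aa_seq", "nt": "nt_seq"}[alphabet]
    tiles = []
    for g in gene_ids:
        for unit in getattr(annotations[g], attr):
            tiles.append(getattr(unit, seq_attr))
    return tiles


def profile_levels(
    annotations: Mapping[str, ZnFArrayAnnotation],
    clusters: Sequence[Cluster],
    level: str,
    tile_type: str,
    alphabet: str,
) -> ConservationProfile:
    """Profile tiles at genome / cluster / gene level.

    ``level`` is "genome", "cluster:3" (comma list allowed, e.g.
    "cluster:4,5" to pool neighbouring clusters), or "gene:<gene_id>".
    """
    if level == "genome":
        gene_ids: list[str] = sorted(annotations)
    elif level.startswith("cluster:"):
        wanted = {int(x) for x in level.split(":", 1)[1].split(",")}
        by_id = {cl.cluster_id: cl for cl in clusters}
        unknown = wanted - set(by_id)
        if unknown:
            raise KeyError(f"unknown cluster id(s): {sorted(unknown)}")
        gene_ids = [g for cid in sorted(wanted) for g in by_id[cid].members]
    elif level.startswith("gene:"):
        gid = level.split(":", 1)[1]
        if gid not in annotations:
            raise KeyError(f"unknown gene id {gid!r}")
        gene_ids = [gid]
    else:
        raise ValueError(f"bad level {level!r}")
    missing = [g for g in gene_ids if g not in annotations]
    if missing:
        raise KeyError(f"genes without annotations: {missing}")
    tiles = _gather_tiles(annotations, gene_ids, tile_type, alphabet)
    return build_profile(
        tiles, alphabet, provenance=f"{level}/{tile_type}/{alphabet}"
    )


def find_conserved_pams(
    profile: ConservationProfile, min_g_freq: float = 0.8
) -> PamSiteReport:
    """Offsets o where the G frequency at o+1 and o+2 both reach min_g_freq.

    The N position is unconstrained; overlapping sites are all reported.
    """
    if profile.alphabet != "nt":
        raise ValueError("PAM discovery requires a nucleotide profile")
    g = profile.freqs["G"].to_numpy()
    offsets = []
    g_freq = {}
    for o in range(profile.length - 2):
        lo = min(g[o + 1], g[o + 2])
        if lo >= min_g_freq:
            offsets.append(o)
            g_freq[o] = float(lo)
    return PamSiteReport(pam_offsets=tuple(offsets), g_frequency=g_freq)


def write_profile(profile: ConservationProfile, path: str | Path) -> None:
    """Per-position table: position, one column per letter, ic."""
    df = profile.freqs.copy()
    df.insert(0, "position", range(len(df)))
    df["ic"] = profile.ic
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
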