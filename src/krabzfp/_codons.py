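"""Standard-code codon tables used for reverse translation.

The synthetic generator needs reverse translation that is reproducible
codon-for-codon, so a fixed preference table ships with the package instead
of sampling codon usage. The first codon listed for each amino acid is the
preferred one; it was picked to avoid 'GG' dinucleotides wherever the amino
acid allows it, so that NGG protospacer-adjacent motifs appear in generated
coding sequence only where the generator plants them.
"""

from __future__ import annotations

SYNONYMOUS_CODONS: dict[str, tuple[str, ...]] = {
    "A": ("GCA", "GCT", "GCC", "GCG"),
    "C": ("TGT", "TGC"),
    "D": ("GAT", "GAC"),
    "E": ("GAA", "GAG"),
    "F": ("TTT", "TTC"),
    "G": ("GGT", "GGC", "GGA", "GGG"),
    "H": ("CAT", "CAC"),
    "I": ("ATT", "ATC", "ATA"),
    "K": ("AAA", "AAG"),
    "L": ("CTT", "CTC", "CTA", "TTA", "TTG", "CTG"),
    "M": ("ATG",),
    "N": ("AAC", "AAT"),
    "P": ("CCA", "CCT", "CCC", "CCG"),
    "Q": ("CAA", "CAG"),
    "R": ("AGA", "CGT", "CGC", "CGA", "AGG", "CGG"),
    "S": ("TCA", "TCT", "TCC", "AGT", "AGC", "TCG"),
    "T": ("ACA", "ACT", "ACC", "ACG"),
    "V": ("GTA", "GTT", "GTC", "GTG"),
    "W": ("TGG",),
    "Y": ("TAT", "TAC"),
}

PREFERRED_CODON: dict[str, str] = {
    aa: codons[0] for aa, codons in SYNONYMOUS_CODONS.items()
}

CODON_TO_AA: dict[str, str] = {
    codon: aa for aa, codons in SYNONYMOUS_CODONS.items() for codon in codons
}

STOP_CODONS: tuple[str, ...] = ("TAA", "TAG", "TGA")

AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET: str = "ACGT"


def translate_codons(cds: str) -> str:
    """Translate an in-frame CDS (no stop) under the standard code."""
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))
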