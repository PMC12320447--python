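"""Codon-level utilities: genetic code, human codon usage, degenerate codons.

Translation itself defers to :mod:`Bio.Seq`; what lives here is the small
amount of codon bookkeeping the library designer needs — ranked codon choice
by usage frequency, synonymous-codon selection, and IUPAC degenerate-codon
expansion.
"""

from __future__ import annotations

from itertools import product

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

STANDARD_AAS = "ACDEFGHIKLMNPQRSTVWY"

STOP_CODONS = tuple(sorted(standard_dna_table.stop_codons))  # TAA, TAG, TGA

#: Codon → amino acid (one-letter); stop codons map to "*".
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
CODON_TO_AA.update({c: "*" for c in STOP_CODONS})

#: Amino acid (or "*") → sorted tuple of codons.
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] += (_codon,)

# Human codon usage, frequency per 1000 codons (standard GenBank-derived
# table as distributed by Kazusa/GenScript). Used only for ranking.
HUMAN_CODON_USAGE: dict[str, float] = {
    "TTT": 17.6, "TTC": 20.3, "TTA": 7.7, "TTG": 12.9,
    "CTT": 13.2, "CTC": 19.6, "CTA": 7.2, "CTG": 39.6,
    "ATT": 16.0, "ATC": 20.8, "ATA": 7.5, "ATG": 22.0,
    "GTT": 11.0, "GTC": 14.5, "GTA": 7.1, "GTG": 28.1,
    "TCT": 15.2, "TCC": 17.7, "TCA": 12.2, "TCG": 4.4,
    "AGT": 12.1, "AGC": 19.5,
    "CCT": 17.5, "CCC": 19.8, "CCA": 16.9, "CCG": 6.9,
    "ACT": 13.1, "ACC": 18.9, "ACA": 15.1, "ACG": 6.1,
    "GCT": 18.4, "GCC": 27.7, "GCA": 15.8, "GCG": 7.4,
    "TAT": 12.2, "TAC": 15.3, "TAA": 1.0, "TAG": 0.8,
    "CAT": 10.9, "CAC": 15.1, "CAA": 12.3, "CAG": 34.2,
    "AAT": 17.0, "AAC": 19.1, "AAA": 24.4, "AAG": 31.9,
    "GAT": 21.8, "GAC": 25.1, "GAA": 29.0, "GAG": 39.6,
    "TGT": 10.6, "TGC": 12.6, "TGA": 1.6, "TGG": 13.2,
    "CGT": 4.5, "CGC": 10.4, "CGA": 6.2, "CGG": 11.4,
    "AGA": 12.2, "AGG": 12.0,
    "GGT": 10.8, "GGC": 22.2, "GGA": 16.5, "GGG": 16.5,
}

CODON_USAGE_TABLES: dict[str, dict[str, float]] = {"human": HUMAN_CODON_USAGE}

IUPAC_DNA: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def translate(dna: str) -> str:
    """Translate a DNA string (length divisible by 3); stops become '*'."""
    if len(dna) % 3 != 0:
        raise ValueError(f"sequence length {len(dna)} not divisible by 3")
    return str(Seq(dna).translate())


def codons_by_usage(aa: str, usage: dict[str, float] | str = "human") -> list[str]:
    """Codons encoding ``aa``, most-used first (ties broken alphabetically)."""
    if isinstance(usage, str):
        usage = CODON_USAGE_TABLES[usage]
    if aa not in AA_TO_CODONS:
        raise ValueError(f"unknown amino acid {aa!r}")
    return sorted(AA_TO_CODONS[aa], key=lambda c: (-usage.get(c, 0.0), c))


def expand_degenerate_codon(scheme: str) -> list[str]:
    """Expand an IUPAC degenerate codon (e.g. NNN, NNK) to concrete codons.

    Returns codons in lexicographic order; NNN yields 64, NNK yields 32.
    """
    scheme = scheme.upper()
    if len(scheme) != 3 or any(b not in IUPAC_DNA for b in scheme):
        raise ValueError(f"invalid degenerate codon scheme {scheme!r}")
    return ["".join(bases) for bases in product(*(IUPAC_DNA[b] for b in scheme))]


def reverse_complement(dna: str) -> str:
    return str(Seq(dna).reverse_complement())
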