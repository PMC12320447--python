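"""Scanning- and saturation-mutagenesis knock-in library design.

The scanning design substitutes individual residues across a window of a
receptor domain.  At each scanned position the substitution set is alanine
plus the top-scoring (least disruptive) alternatives from a BLOSUM80
substitution matrix — five matrix picks when the native residue is itself
alanine — augmented with any residue observed at that position in an
alignment of homologous proteins.  Each substitution is synthesized with up
to two different codons; per-position controls are one synonymous codon
swap, a single-residue deletion, and (at a configured subset of positions)
a stop codon.

The saturation design expands a degenerate codon (NNN by default, NNK
supported) at a single residue, yielding one library member per concrete
codon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Align import substitution_matrices

from .codons import (
    CODON_TO_AA,
    STANDARD_AAS,
    codons_by_usage,
    expand_degenerate_codon,
    translate,
)

MEMBER_COLUMNS = [
    "member_id",
    "position",
    "native_aa",
    "variant_aa",
    "codon",
    "control_class",
    "oligo_sequence",
]


def load_blosum(name_or_path: str = "BLOSUM80"):
    """Load a substitution matrix by name (biopython registry) or NCBI text file."""
    try:
        return substitution_matrices.load(name_or_path)
    except FileNotFoundError:
        return substitution_matrices.read(name_or_path)


@dataclass(frozen=True)
class ScanConfig:
    """Design parameters for a scanning-mutagenesis library.

    ``window`` is inclusive and in domain numbering; ``first_residue_number``
    maps the first residue of the supplied segment onto that numbering.
    """

    window: tuple[int, int] = (101, 150)
    first_residue_number: int = 101
    n_blosum_nonala: int = 4
    n_blosum_ala: int = 5
    codons_per_sub: int = 2
    synonymous_per_position: int = 1
    deletion_at_every_position: bool = True
    stop_positions: tuple[int, ...] = ()
    codon_usage_table: str = "human"

    def __post_init__(self) -> None:
        if self.window[0] > self.window[1]:
            raise ValueError("empty scan window")
        for name in ("n_blosum_nonala", "n_blosum_ala", "codons_per_sub",
                     "synonymous_per_position"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def positions(self) -> range:
        return range(self.window[0], self.window[1] + 1)


def pick_blosum_substitutions(native_aa: str, matrix, n: int) -> list[str]:
    """Choose the ``n`` least-disruptive substitutions for ``native_aa``.

    For a non-alanine native the returned list is alanine plus the top-``n``
    other residues by matrix score (length ``n + 1``); for alanine it is the
    top-``n`` residues outright.  Candidates are ranked by descending score
    with ties broken alphabetically, which makes the design reproducible.
    """
    if native_aa not in STANDARD_AAS:
        raise ValueError(f"nonstandard residue {native_aa!r}")
    exclude = {native_aa, "A"}
    candidates = [aa for aa in STANDARD_AAS if aa not in exclude]
    ranked = sorted(candidates, key=lambda aa: (-matrix[native_aa, aa], aa))
    if native_aa == "A":
        return ranked[:n]
    chosen = set(ranked[:n]) | {"A"}
    return sorted(chosen, key=lambda aa: (-matrix[native_aa, aa], aa))


def augment_from_homologs(
    position: int,
    homolog_alignment_column,
    already_chosen: set[str],
    native_aa: str,
) -> set[str]:
    """Residues seen in homologs at this position and not yet in the library.

    Gap and ambiguity characters are ignored; the native residue and any
    residue in ``already_chosen`` are excluded.
    """
    column = list(homolog_alignment_column)
    if not column:
        raise ValueError(f"empty homolog column at position {position}")
    observed = {aa.upper() for aa in column}
    return {
        aa
        for aa in observed
        if aa in STANDARD_AAS and aa != native_aa and aa not in already_chosen
    }


def assign_codons(aa: str, usage_table: str | dict, k: int) -> list[str]:
    """Up to ``k`` distinct codons for ``aa``, most-used first."""
    return codons_by_usage(aa, usage_table)[:k]


def synonymous_codon(ref_codon: str, usage_table: str | dict) -> str | None:
    """Highest-usage codon encoding the same residue but differing from the
    reference codon; None for single-codon amino acids (M, W)."""
    aa = CODON_TO_AA[ref_codon.upper()]
    for codon in codons_by_usage(aa, usage_table):
        if codon != ref_codon.upper():
            return codon
    return None


@dataclass
class Segment:
    """The mutagenized segment: protein window plus its reference DNA."""

    protein: str
    reference_dna: str

    def __post_init__(self) -> None:
        self.reference_dna = self.reference_dna.upper()
        if translate(self.reference_dna) != self.protein:
            raise ValueError("segment protein does not match reference DNA translation")

    def codon_at(self, index: int) -> str:
        return self.reference_dna[3 * index : 3 * index + 3]


def _oligo_with_codon(segment: Segment, index: int, codon: str) -> str:
    return segment.reference_dna[: 3 * index] + codon + segment.reference_dna[3 * index + 3 :]


def _oligo_with_deletion(segment: Segment, index: int) -> str:
    return segment.reference_dna[: 3 * index] + segment.reference_dna[3 * index + 3 :]


def substitutions_per_position(
    segment: Segment,
    config: ScanConfig,
    matrix,
    homologs: list[str] | None = None,
) -> dict[int, list[str]]:
    """The substitution amino-acid set at each scanned position.

    ``homologs`` is an optional list of aligned sequences, each exactly as
    long as the segment.  Matrix picks come first in rank order, then
    homolog-only additions alphabetically.
    """
    if homologs:
        for h in homologs:
            if len(h) != len(segment.protein):
                raise ValueError("homolog alignment length does not match segment")
    out: dict[int, list[str]] = {}
    for pos in config.positions:
        idx = pos - config.first_residue_number
        if not 0 <= idx < len(segment.protein):
            raise ValueError(f"position {pos} outside segment")
        native = segment.protein[idx]
        n = config.n_blosum_ala if native == "A" else config.n_blosum_nonala
        picks = pick_blosum_substitutions(native, matrix, n)
        if homologs:
            extra = augment_from_homologs(
                pos, [h[idx] for h in homologs], set(picks), native
            )
            picks = picks + sorted(extra)
        out[pos] = picks
    return out


def design_scanning_library(
    segment: Segment,
    config: ScanConfig,
    matrix=None,
    homologs: list[str] | None = None,
) -> pd.DataFrame:
    """Design the full scanning library as a member table.

    Members per position: each substitution × up to ``codons_per_sub``
    codons, one synonymous codon swap (where the native codon has a
    synonym), one deletion, and a stop codon at configured positions.
    The oligo of every member is the reference DNA with only the designed
    codon altered (or removed).
    """
    if matrix is None:
        matrix = load_blosum()
    subs = substitutions_per_position(segment, config, matrix, homologs)
    usage = config.codon_usage_table
    rows: list[dict] = []

    def add(pos, native, variant, codon, control_class, oligo):
        rows.append(
            {
                "member_id": f"p{pos}_{native}>{variant or 'del'}"
                + (f"_{codon}" if codon else ""),
                "position": pos,
                "native_aa": native,
                "variant_aa": variant,
                "codon": codon,
                "control_class": control_class,
                "oligo_sequence": oligo,
            }
        )

    for pos in config.positions:
        idx = pos - config.first_residue_number
        native = segment.protein[idx]
        for aa in subs[pos]:
            for codon in assign_codons(aa, usage, config.codons_per_sub):
                add(pos, native, aa, codon, "substitution",
                    _oligo_with_codon(segment, idx, codon))
        if config.synonymous_per_position:
            syn = synonymous_codon(segment.codon_at(idx), usage)
            if syn is not None:
                add(pos, native, native, syn, "synonymous",
                    _oligo_with_codon(segment, idx, syn))
        if config.deletion_at_every_position:
            add(pos, native, "", "", "deletion", _oligo_with_deletion(segment, idx))
        if pos in config.stop_positions:
            stop = "TGA"
            add(pos, native, "*", stop, "stop", _oligo_with_codon(segment, idx, stop))

    table = pd.DataFrame(rows, columns=MEMBER_COLUMNS)
    if table["member_id"].duplicated().any():
        raise ValueError("duplicate member ids in design")
    return table


def design_saturation_library(
    segment: Segment,
    position: int,
    scheme: str = "NNN",
    first_residue_number: int = 101,
) -> pd.DataFrame:
    """One member per concrete codon of a degenerate scheme at one residue.

    Stop codons are flagged ``control_class="stop"``; codons encoding the
    native residue are ``"synonymous"`` (the reference codon included), all
    others ``"substitution"``.
    """
    idx = position - first_residue_number
    if not 0 <= idx < len(segment.protein):
        raise ValueError(f"position {position} outside segment")
    native = segment.protein[idx]
    rows = []
    for codon in expand_degenerate_codon(scheme):
        aa = CODON_TO_AA[codon]
        if aa == "*":
            cls = "stop"
        elif aa == native:
            cls = "synonymous"
        else:
            cls = "substitution"
        rows.append(
            {
                "member_id": f"p{position}_{native}>{aa}_{codon}",
                "position": position,
                "native_aa": native,
                "variant_aa": aa,
                "codon": codon,
                "control_class": cls,
                "oligo_sequence": _oligo_with_codon(segment, idx, codon),
            }
        )
    return pd.DataFrame(rows, columns=MEMBER_COLUMNS)


def expected_member_count(
    subs: dict[int, list[str]],
    config: ScanConfig,
    segment: Segment,
) -> int:
    """Closed-form member count for a scanning design (cross-check for the
    enumerated table)."""
    total = 0
    for pos, aas in subs.items():
        idx = pos - config.first_residue_number
        for aa in aas:
            total += min(config.codons_per_sub, len(codons_by_usage(aa, config.codon_usage_table)))
        if config.synonymous_per_position and synonymous_codon(
            segment.codon_at(idx), config.codon_usage_table
        ):
            total += 1
        if config.deletion_at_every_position:
            total += 1
        if pos in config.stop_positions:
            total += 1
    return total


def validate_member_table(table: pd.DataFrame, segment: Segment,
                          first_residue_number: int = 101) -> pd.DataFrame:
    """Validate an externally supplied oligo table against the reference.

    Checks that each oligo realizes exactly its annotated change: the
    translated oligo differs from the native protein only at the designed
    residue (or is the native protein for synonymous members, or one residue
    shorter for deletions).  Returns the table with a boolean ``valid``
    column; raises on structural problems (duplicate ids).
    """
    if table["member_id"].duplicated().any():
        raise ValueError("duplicate member ids")
    native_protein = segment.protein
    valid = []
    for row in table.itertuples(index=False):
        idx = int(row.position) - first_residue_number
        aa = translate(row.oligo_sequence) if len(row.oligo_sequence) % 3 == 0 else None
        if aa is None:
            ok = False
        elif row.control_class == "deletion":
            ok = aa == native_protein[:idx] + native_protein[idx + 1 :]
        elif row.control_class == "synonymous":
            ok = aa == native_protein and row.oligo_sequence != segment.reference_dna
        elif row.control_class == "stop":
            ok = aa[idx] == "*" and aa[:idx] == native_protein[:idx]
        else:
            ok = (
                aa[idx] == row.variant_aa
                and aa[:idx] == native_protein[:idx]
                and aa[idx + 1 :] == native_protein[idx + 1 :]
            )
        valid.append(ok)
    out = table.copy()
    out["valid"] = valid
    return out
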