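"""Sort-seq enrichment analysis and antibody-epitope mapping.

A pooled receptor-variant library is sorted into an antibody-bound bin and
an antibody-unbound bin, and each bin is sequenced alongside the unsorted
input library.  Per member, fold enrichment is the abundance in a sorted
bin over the abundance in the input library.  The conservation score of a
variant is the *bin ratio*: enrichment in the bound bin divided by
enrichment in the unbound bin.  Variants that preserve the epitope stay
antibody-bound (ratio > 1, "conservative"); variants that disrupt it
escape into the unbound bin (ratio < 1).  Codon-level scores are averaged
per amino acid, and positions where most substitutions escape are called
as epitope contact positions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .quant import AbundanceTable


def default_pseudocount(selected: AbundanceTable, input_lib: AbundanceTable) -> float:
    """One read on the abundance scale of the shallower sample.

    Keeps zero-count members finite without dominating well-covered ones.
    """
    smallest = min(selected.noncontrol_mapped, input_lib.noncontrol_mapped)
    if smallest == 0:
        raise ValueError("a sample has no non-control mapped reads")
    return 1.0 / smallest


def fold_enrichment(
    selected: AbundanceTable,
    input_lib: AbundanceTable,
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-member fold enrichment of a sorted bin versus the input library.

    score(m) = (abund_sel(m) + eps) / (abund_in(m) + eps).  With
    ``pseudocount=None`` the default data-driven epsilon is used; pass 0 for
    the raw ratio (which requires every input abundance to be non-zero).
    """
    sel = selected.abundances()
    inp = input_lib.abundances()
    if set(sel.index) != set(inp.index):
        raise ValueError("member sets of the two samples differ")
    inp = inp.reindex(sel.index)
    eps = default_pseudocount(selected, input_lib) if pseudocount is None else pseudocount
    denom = inp + eps
    if (denom == 0).any():
        raise ValueError("zero input abundance without pseudocount")
    score = (sel + eps) / denom
    out = selected.table[
        ~selected.table["control_class"].isin(("stop", "deletion"))
    ][["member_id", "position", "native_aa", "variant_aa", "codon", "control_class"]].copy()
    out["fold_enrichment"] = score.loc[out["member_id"]].to_numpy()
    out["log2_enrichment"] = np.log2(out["fold_enrichment"])
    return out


def conservation_ratio(
    bin_pos: pd.DataFrame, bin_neg: pd.DataFrame
) -> pd.DataFrame:
    """Bin ratio per member: enrichment in the antibody-positive bin over
    enrichment in the antibody-negative bin, ranked least → most conservative.

    Both inputs are ``fold_enrichment`` tables computed against the same
    input library.  Ties in the ratio break by positive-bin enrichment and
    then member_id; ``rank_within_position`` is 1 for the least conservative
    member at its position.
    """
    if set(bin_pos["member_id"]) != set(bin_neg["member_id"]):
        raise ValueError("member sets of the two bins differ")
    neg = bin_neg.set_index("member_id")["fold_enrichment"]
    out = bin_pos.rename(columns={"fold_enrichment": "enrichment_pos",
                                  "log2_enrichment": "log2_enrichment_pos"}).copy()
    out["enrichment_neg"] = neg.loc[out["member_id"]].to_numpy()
    if (out["enrichment_neg"] == 0).any():
        raise ValueError("zero negative-bin enrichment; use a pseudocount")
    out["bin_ratio"] = out["enrichment_pos"] / out["enrichment_neg"]
    out["log2_bin_ratio"] = np.log2(out["bin_ratio"])
    out = out.sort_values(
        ["bin_ratio", "enrichment_pos", "member_id"], kind="mergesort"
    ).reset_index(drop=True)
    out["rank_within_position"] = (
        out.groupby("position").cumcount().add(1)
    )
    return out


def aggregate_by_amino_acid(records: pd.DataFrame,
                            score: str = "bin_ratio") -> pd.DataFrame:
    """Unweighted mean of member scores over codons per (position, amino acid).

    Synonymous members contribute to the native amino acid's profile; empty
    groups simply do not appear.
    """
    if score not in records.columns:
        raise ValueError(f"no {score!r} column in records")
    grouped = (
        records.groupby(["position", "native_aa", "variant_aa"], as_index=False)
        .agg(mean_score=(score, "mean"), n_codons=("member_id", "size"))
        .rename(columns={"variant_aa": "amino_acid"})
    )
    grouped["log2_mean_score"] = np.log2(grouped["mean_score"])
    return grouped


def call_epitope_positions(
    aa_profiles: pd.DataFrame,
    effect_threshold: float = 1.0,
    min_fraction_escaping: float = 0.5,
) -> set[int]:
    """Positions where most substitutions escape antibody binding.

    A substitution escapes when its log2 mean bin ratio is at or below
    ``-effect_threshold``; a position is called when at least
    ``min_fraction_escaping`` of its non-native substitutions escape.
    """
    if effect_threshold <= 0:
        raise ValueError("effect threshold must be positive")
    if not 0 < min_fraction_escaping <= 1:
        raise ValueError("min_fraction_escaping must be in (0, 1]")
    subs = aa_profiles[aa_profiles["amino_acid"] != aa_profiles["native_aa"]]
    called = set()
    for pos, group in subs.groupby("position"):
        escaping = (group["log2_mean_score"] <= -effect_threshold).mean()
        if escaping >= min_fraction_escaping:
            called.add(int(pos))
    return called
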