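"""Exact-match quantification of pooled-library amplicon reads.

Reads are scanned for fixed anchor sequences flanking the library region;
reads lacking either anchor (no mismatches permitted) are discarded, the
region between the anchors is extracted, and regions are mapped to library
members by exact sequence identity.  Member abundance is the mapped read
count divided by total mapped reads, with designated controls (stop codons
and deletions) excluded from the totals.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from .codons import reverse_complement

CONTROL_CLASSES_EXCLUDED = ("stop", "deletion")


@dataclass(frozen=True)
class AnchorSpec:
    """Conserved sequences immediately flanking the library region."""

    upstream: str
    downstream: str
    min_length: int = 10

    def __post_init__(self) -> None:
        if not self.upstream or not self.downstream:
            raise ValueError("both anchors must be non-empty")
        object.__setattr__(self, "upstream", self.upstream.upper())
        object.__setattr__(self, "downstream", self.downstream.upper())
        if min(len(self.upstream), len(self.downstream)) < self.min_length:
            raise ValueError(
                f"anchors shorter than {self.min_length} nt are too unspecific"
            )


@dataclass
class AbundanceTable:
    """Per-member counts and control-excluded abundances for one sample."""

    sample_id: str
    table: pd.DataFrame  # member_id, control_class, raw_count, abundance
    reads_in: int
    reads_anchored: int
    reads_mapped: int
    reads_control: int
    controls_excluded: bool = True

    def stats(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "reads_in": self.reads_in,
            "reads_anchored": self.reads_anchored,
            "reads_mapped": self.reads_mapped,
            "reads_control": self.reads_control,
        }

    @property
    def noncontrol_mapped(self) -> int:
        return self.reads_mapped - self.reads_control

    def abundances(self) -> pd.Series:
        """Abundance over non-control members, indexed by member_id."""
        t = self.table[~self.table["control_class"].isin(CONTROL_CLASSES_EXCLUDED)]
        return t.set_index("member_id")["abundance"]

    def write(self, counts_path, stats_path=None) -> None:
        self.table.to_csv(counts_path, sep="\t", index=False)
        if stats_path:
            Path(stats_path).write_text(json.dumps(self.stats(), indent=2) + "\n")


def extract_library_region(read: str, anchors: AnchorSpec) -> str | None:
    """The substring strictly between the first upstream-anchor occurrence
    and the subsequent downstream anchor, or None (discard)."""
    read = read.upper()
    up_at = read.find(anchors.upstream)
    if up_at == -1:
        return None
    start = up_at + len(anchors.upstream)
    down_at = read.find(anchors.downstream, start)
    if down_at == -1:
        return None
    return read[start:down_at]


def extract_oriented(read: str, anchors: AnchorSpec) -> str | None:
    """Try extraction on the read as given, then on its reverse complement."""
    region = extract_library_region(read, anchors)
    if region is None:
        region = extract_library_region(reverse_complement(read), anchors)
    return region


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(path):
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fastq"):
            yield str(record.seq)


def build_member_index(members: pd.DataFrame) -> dict[str, str]:
    """Map library-region sequence → member_id; duplicate sequences are a
    design error and rejected at load."""
    index: dict[str, str] = {}
    for row in members.itertuples(index=False):
        seq = row.oligo_sequence.upper()
        if seq in index:
            raise ValueError(
                f"duplicate member sequence: {index[seq]} and {row.member_id}"
            )
        index[seq] = row.member_id
    return index


def count_members(regions, members: pd.DataFrame) -> tuple[dict[str, int], int]:
    """Exact-match counts per member plus the number of unmapped regions."""
    index = build_member_index(members)
    counts = {mid: 0 for mid in members["member_id"]}
    unmapped = 0
    for region in regions:
        mid = index.get(region)
        if mid is None:
            unmapped += 1
        else:
            counts[mid] += 1
    return counts, unmapped


def compute_abundance(
    counts: dict[str, int],
    members: pd.DataFrame,
    sample_id: str = "sample",
    reads_in: int | None = None,
    reads_anchored: int | None = None,
) -> AbundanceTable:
    """Control-excluded abundances from raw counts.

    abundance(m) = count(m) / Σ counts over non-control members; controls
    (stop, deletion) keep raw counts but no abundance.
    """
    if any(c < 0 for c in counts.values()):
        raise ValueError("negative counts")
    table = members[["member_id", "position", "native_aa", "variant_aa", "codon",
                     "control_class"]].copy()
    table["raw_count"] = table["member_id"].map(counts).fillna(0).astype(int)
    is_control = table["control_class"].isin(CONTROL_CLASSES_EXCLUDED)
    denom = int(table.loc[~is_control, "raw_count"].sum())
    if denom == 0:
        raise ValueError("no usable reads: all mapped reads are on controls")
    table["abundance"] = table["raw_count"] / denom
    table.loc[is_control, "abundance"] = float("nan")
    mapped = int(table["raw_count"].sum())
    control = int(table.loc[is_control, "raw_count"].sum())
    return AbundanceTable(
        sample_id=sample_id,
        table=table,
        reads_in=reads_in if reads_in is not None else mapped,
        reads_anchored=reads_anchored if reads_anchored is not None else mapped,
        reads_mapped=mapped,
        reads_control=control,
    )


def quantify_fastq(
    r1_path,
    members: pd.DataFrame,
    anchors: AnchorSpec,
    r2_path=None,
    sample_id: str = "sample",
) -> AbundanceTable:
    """Full FASTQ → abundance pipeline for one sample.

    Single-end: each read is tried forward then reverse-complemented.
    Paired-end: a fragment counts at most once — R1 is tried first (both
    orientations), then R2; read pairing follows file order.
    """
    regions = []
    reads_in = 0
    if r2_path is None:
        for read in iter_fastq(r1_path):
            reads_in += 1
            region = extract_oriented(read, anchors)
            if region is not None:
                regions.append(region)
    else:
        for read1, read2 in zip(iter_fastq(r1_path), iter_fastq(r2_path)):
            reads_in += 1
            region = extract_oriented(read1, anchors)
            if region is None:
                region = extract_oriented(read2, anchors)
            if region is not None:
                regions.append(region)
    counts, unmapped = count_members(regions, members)
    table = compute_abundance(
        counts, members, sample_id=sample_id,
        reads_in=reads_in, reads_anchored=len(regions),
    )
    # conservation: reads_in = no-anchor discards + unmapped + Σ member counts
    assert table.reads_mapped + unmapped == table.reads_anchored
    return table


def load_members(path) -> pd.DataFrame:
    members = pd.read_csv(path, sep="\t", dtype={"codon": str, "variant_aa": str})
    for col in ("variant_aa", "codon"):
        members[col] = members[col].fillna("")
    build_member_index(members)  # validates uniqueness
    return members
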