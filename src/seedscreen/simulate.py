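"""Synthetic data generation for every stage of the pipeline.

Generates toy target loci, homolog alignments, and — the core piece — a
full pooled sort-seq screen with recorded ground truth: each library member
gets a binding-loss probability (the chance that a cell expressing it
escapes antibody binding), cells are allocated multinomially to members and
routed to the antibody-negative bin with that probability, and amplicon
reads carrying fixed flanking anchors are emitted per bin with optional
substitution sequencing error.  The recorded truth lets recovery of planted
epitope positions be tested end to end without any external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .codons import AA_TO_CODONS, STANDARD_AAS, translate
from .construct import TargetLocus
from .library_design import Segment, ScanConfig, design_scanning_library
from .quant import AnchorSpec

DNA = "ACGT"

#: Fixed amplicon anchors used by the simulator (20 nt each).
DEFAULT_ANCHORS = AnchorSpec(
    upstream="TCGATCACGCGTCAAGGTCA",
    downstream="GACCTGTTCGTTGCAACAAA",
)

DEFAULT_READ_LENGTH = 250


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(DNA), size=length))


def _random_sense_codons(rng: np.random.Generator, n: int) -> str:
    """n random non-stop codons, no two adjacent codons identical.

    Adjacent identical codons would make single-codon deletion oligos at
    neighboring positions indistinguishable, which the exact-match counter
    rejects by design.
    """
    sense = sorted(set(
        c for aa, codons in AA_TO_CODONS.items() if aa != "*" for c in codons
    ))
    codons: list[str] = []
    while len(codons) < n:
        c = str(rng.choice(sense))
        if codons and codons[-1] == c:
            continue
        codons.append(c)
    return "".join(codons)


def make_synthetic_locus(
    seed: int,
    n_exons: int = 3,
    payload_length: int = 36,
    exon_codons: tuple[int, int] = (40, 70),
    intron_length: int = 400,
    padding: int = 600,
) -> tuple[TargetLocus, str]:
    """A toy surface-protein locus plus a payload open reading frame.

    The coding sequence (ATG ... stop) is generated first and then split
    into ``n_exons`` exons at random codon-unaligned points, so exon phases
    exercise all values.  A signal peptide is annotated near the start of
    exon 1, a transmembrane segment in the last exon, and the cut site sits
    mid-way through intron 1 — a valid SEED integration site by
    construction.
    """
    if n_exons < 2:
        raise ValueError("need at least 2 exons to have an intron")
    if payload_length <= 0 or payload_length % 3:
        raise ValueError("payload length must be a positive multiple of 3")
    rng = np.random.default_rng(seed)
    n_codons = int(rng.integers(*exon_codons)) * n_exons
    cds = "ATG" + _random_sense_codons(rng, n_codons - 2) + "TAA"
    # exon boundaries at arbitrary (codon-unaligned) nucleotide offsets
    cuts = sorted(rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1,
                             replace=False))
    pieces = np.split(np.frombuffer(cds.encode(), dtype="S1"), cuts)
    exon_seqs = [b"".join(p).decode() for p in pieces]

    sequence = _random_dna(rng, padding)
    exons: list[tuple[int, int]] = []
    phases: list[int] = []
    cum = 0
    for i, exon in enumerate(exon_seqs):
        if i > 0:
            intron = "GT" + _random_dna(rng, intron_length - 4) + "AG"
            sequence += intron
        exons.append((len(sequence), len(sequence) + len(exon)))
        phases.append(cum % 3)
        cum += len(exon)
        sequence += exon
    sequence += _random_dna(rng, padding)

    exon1 = exons[0]
    sp = (exon1[0] + 3, exon1[0] + 3 + 45)  # ~15-aa signal peptide
    last = exons[-1]
    tm = (last[1] - 69, last[1] - 3)  # ~22-aa transmembrane segment
    cut = (exons[0][1] + exons[1][0]) // 2  # middle of intron 1

    locus = TargetLocus(
        locus_id=f"synthetic_locus_{seed}",
        sequence=sequence,
        exons=exons,
        cds_phase_per_exon=phases,
        intron_cut_site=cut,
        signal_peptide_interval=sp,
        transmembrane_interval=tm,
    )
    payload = _random_sense_codons(rng, payload_length // 3)
    return locus, payload


def make_synthetic_segment(
    seed: int, length: int = 50, first_residue_number: int = 101
) -> Segment:
    """A random protein segment with a matching reference DNA."""
    rng = np.random.default_rng(seed)
    dna = _random_sense_codons(rng, length)
    return Segment(protein=translate(dna), reference_dna=dna)


def make_synthetic_homologs(
    segment: str, n: int = 38, divergence: float = 0.1, seed: int = 0
) -> list[str]:
    """n aligned homolog sequences with expected per-site substitution rate
    ``divergence`` relative to the segment (no indels)."""
    if not 0 <= divergence <= 1:
        raise ValueError("divergence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    homologs = []
    for _ in range(n):
        chars = list(segment)
        for i, aa in enumerate(chars):
            if rng.random() < divergence:
                choices = [x for x in STANDARD_AAS if x != aa]
                chars[i] = choices[int(rng.integers(len(choices)))]
        homologs.append("".join(chars))
    return homologs


def write_homologs_fasta(homologs: list[str], path) -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(homologs):
            fh.write(f">homolog_{i + 1}\n{seq}\n")


@dataclass
class ScreenTruth:
    """Ground truth of a simulated sort-seq screen."""

    rng_seed: int
    binding_loss: dict[str, float]
    escape_positions: list[int]
    composition: dict[str, float]
    n_cells: int
    read_depth: int
    error_rate: float
    read_length: int = DEFAULT_READ_LENGTH

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "ScreenTruth":
        return cls(**json.loads(Path(path).read_text()))


def make_screen_truth(
    members: pd.DataFrame,
    seed: int = 42,
    escape_positions: list[int] | None = None,
    n_escape_positions: int = 3,
    baseline_loss: tuple[float, float] = (0.0, 0.2),
    escape_loss: tuple[float, float] = (0.8, 0.95),
    n_cells: int = 50_000,
    read_depth: int = 100_000,
    error_rate: float = 0.001,
) -> ScreenTruth:
    """Plant escape positions and draw per-member binding-loss effects.

    Substitutions at escape positions lose antibody binding with high
    probability; substitutions elsewhere get a small baseline loss; members
    carrying the native residue (synonymous) lose nothing; deletions and
    stops (controls, excluded from analysis) lose everything.
    """
    rng = np.random.default_rng(seed)
    positions = sorted(members.loc[members["control_class"] == "substitution",
                                   "position"].unique())
    if escape_positions is None:
        escape_positions = sorted(
            int(p) for p in rng.choice(positions, size=n_escape_positions,
                                       replace=False)
        )
    composition = rng.dirichlet(np.full(len(members), 50.0))
    binding_loss: dict[str, float] = {}
    for row in members.itertuples(index=False):
        if row.control_class in ("deletion", "stop"):
            loss = 1.0
        elif row.control_class == "synonymous" or row.variant_aa == row.native_aa:
            loss = 0.0
        elif int(row.position) in escape_positions:
            loss = float(rng.uniform(*escape_loss))
        else:
            loss = float(rng.uniform(*baseline_loss))
        binding_loss[row.member_id] = loss
    return ScreenTruth(
        rng_seed=int(seed),
        binding_loss=binding_loss,
        escape_positions=[int(p) for p in escape_positions],
        composition={m: float(c) for m, c in zip(members["member_id"], composition)},
        n_cells=n_cells,
        read_depth=read_depth,
        error_rate=error_rate,
    )


def _emit_reads(
    rng: np.random.Generator,
    members: pd.DataFrame,
    read_counts: np.ndarray,
    anchors: AnchorSpec,
    error_rate: float,
    read_length: int,
    path,
) -> None:
    oligos = list(members["oligo_sequence"])
    fragments = []
    for oligo, count in zip(oligos, read_counts):
        if count:
            fragments.extend([anchors.upstream + oligo + anchors.downstream] * int(count))
    order = rng.permutation(len(fragments))
    bases = np.frombuffer(DNA.encode(), dtype="S1")
    with open(path, "w") as fh:
        for i, j in enumerate(order):
            frag = fragments[j]
            pad = read_length - len(frag)
            if pad > 0:  # center the library region in the read
                left = _random_dna(rng, pad // 2)
                frag = left + frag + _random_dna(rng, pad - len(left))
            if error_rate > 0:
                n_err = rng.binomial(len(frag), error_rate)
                if n_err:
                    arr = np.frombuffer(frag.encode(), dtype="S1").copy()
                    sites = rng.choice(len(frag), size=n_err, replace=False)
                    for s in sites:
                        alt = [b for b in bases if b != arr[s]]
                        arr[s] = alt[int(rng.integers(3))]
                    frag = b"".join(arr).decode()
            fh.write(f"@read_{i}\n{frag}\n+\n{'I' * len(frag)}\n")


def simulate_sort_screen(
    members: pd.DataFrame,
    truth: ScreenTruth,
    outdir,
    anchors: AnchorSpec = DEFAULT_ANCHORS,
) -> dict[str, Path]:
    """Emit input / antibody-negative / antibody-positive bin FASTQs.

    Cells are allocated to members multinomially from the library
    composition; each cell routes to the antibody-negative bin with its
    member's binding-loss probability.  Reads sample the corresponding bin
    composition and carry anchor + library region + anchor, centered in a
    fixed-length read, with independent per-base substitution errors.
    """
    if truth.read_depth <= 0:
        raise ValueError("read depth must be positive")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(truth.rng_seed)

    comp = np.array([truth.composition[m] for m in members["member_id"]])
    comp = comp / comp.sum()
    loss = np.array([truth.binding_loss[m] for m in members["member_id"]])

    cells = rng.multinomial(truth.n_cells, comp)
    neg_cells = rng.binomial(cells, loss)
    pos_cells = cells - neg_cells
    if pos_cells.sum() == 0 or neg_cells.sum() == 0:
        raise ValueError("a sort bin received no cells; adjust effects or depth")

    paths = {}
    for bin_name, weights in (
        ("input", comp),
        ("bin_neg", neg_cells / neg_cells.sum()),
        ("bin_pos", pos_cells / pos_cells.sum()),
    ):
        counts = rng.multinomial(truth.read_depth, weights)
        path = outdir / f"{bin_name}_R1.fastq"
        _emit_reads(rng, members, counts, anchors, truth.error_rate,
                    truth.read_length, path)
        paths[bin_name] = path

    members.to_csv(outdir / "members.tsv", sep="\t", index=False)
    truth.to_json(outdir / "truth.json")
    paths["members"] = outdir / "members.tsv"
    paths["truth"] = outdir / "truth.json"
    return paths


def default_scan_config(first_residue_number: int = 101,
                        window_length: int = 50) -> ScanConfig:
    """The default screen design: a 50-residue window with stop-codon
    controls at five evenly spaced positions."""
    lo = first_residue_number
    hi = first_residue_number + window_length - 1
    stops = tuple(lo + k for k in (5, 15, 25, 35, 45) if lo + k <= hi)
    return ScanConfig(window=(lo, hi), first_residue_number=lo,
                      stop_positions=stops)


def default_screen_members(seed: int = 42) -> tuple[Segment, pd.DataFrame]:
    """Scanning library on a synthetic segment with 38 synthetic homologs."""
    segment = make_synthetic_segment(seed)
    homologs = make_synthetic_homologs(segment.protein, n=38, divergence=0.08,
                                       seed=seed + 1)
    config = default_scan_config()
    members = design_scanning_library(segment, config, homologs=homologs)
    return segment, members


def simulate_ddpcr(
    true_fraction: float,
    n_droplets_fam_assay: int = 20_000,
    n_droplets_ref: int = 20_000,
    seed: int = 42,
    ref_occupancy: float = 0.2,
) -> tuple:
    """Simulated droplet counts for a translocation assay well.

    The reference (HEX) channel is positive with probability
    ``ref_occupancy``; the translocation (FAM) channel with probability
    ``true_fraction * ref_occupancy`` — i.e. translocated templates are a
    ``true_fraction`` of reference templates, at low occupancy.
    """
    from .ddpcr import DdpcrWell

    if not 0 <= true_fraction <= 1:
        raise ValueError("true fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    total = max(n_droplets_fam_assay, n_droplets_ref)
    fam = int(rng.binomial(n_droplets_fam_assay, true_fraction * ref_occupancy))
    hex_ = int(rng.binomial(n_droplets_ref, ref_occupancy))
    return DdpcrWell(fam_positive=fam, hex_positive=hex_, total_droplets=total)
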