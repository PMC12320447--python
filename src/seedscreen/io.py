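"""File-format ingress/egress: GFF3 + FASTA loci, GenBank cassettes.

Loci are strand-normalized on ingest: for a minus-strand gene the locus
sequence is reverse-complemented and all intervals are flipped, so every
downstream module sees the coding strand on the forward string.
"""

from __future__ import annotations

from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .construct import SeedCassette, TargetLocus


def locus_from_gff(
    gff_path,
    fasta_path,
    cut_site: int,
    locus_id: str | None = None,
    signal_peptide_interval: tuple[int, int] | None = None,
    transmembrane_interval: tuple[int, int] | None = None,
) -> TargetLocus:
    """Build a strand-normalized :class:`TargetLocus` from a gene model.

    ``cut_site`` and the optional intervals are given in coordinates of the
    supplied (forward) FASTA sequence and are flipped along with it for
    minus-strand genes.  Exon phases are recomputed from cumulative exon
    lengths, assuming the CDS starts at the first exon base.
    """
    db = gffutils.create_db(str(gff_path), ":memory:", force=True,
                            merge_strategy="merge")
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    sequence = str(record.seq).upper()

    exon_feats = sorted(db.features_of_type("exon"), key=lambda f: f.start)
    if not exon_feats:
        raise ValueError("no exon features in GFF3")
    strand = exon_feats[0].strand or "+"
    # GFF3 is 1-based inclusive → 0-based half-open
    exons = [(f.start - 1, f.end) for f in exon_feats]

    def flip(iv: tuple[int, int]) -> tuple[int, int]:
        return (len(sequence) - iv[1], len(sequence) - iv[0])

    if strand == "-":
        sequence = str(Seq(sequence).reverse_complement())
        exons = sorted(flip(iv) for iv in exons)
        cut_site = len(sequence) - cut_site
        if signal_peptide_interval:
            signal_peptide_interval = flip(signal_peptide_interval)
        if transmembrane_interval:
            transmembrane_interval = flip(transmembrane_interval)

    phases = []
    cum = 0
    for start, end in exons:
        phases.append(cum % 3)
        cum += end - start

    return TargetLocus(
        locus_id=locus_id or record.id,
        sequence=sequence,
        exons=exons,
        cds_phase_per_exon=phases,
        intron_cut_site=cut_site,
        strand="+",  # normalized
        signal_peptide_interval=signal_peptide_interval,
        transmembrane_interval=transmembrane_interval,
    )


def write_locus(locus: TargetLocus, gff_path, fasta_path) -> None:
    """Emit a locus as GFF3 + FASTA (already strand-normalized)."""
    with open(fasta_path, "w") as fh:
        fh.write(f">{locus.locus_id}\n")
        for i in range(0, len(locus.sequence), 80):
            fh.write(locus.sequence[i : i + 80] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(
            f"{locus.locus_id}\tseedscreen\tgene\t1\t{len(locus.sequence)}\t.\t+\t.\t"
            f"ID=gene:{locus.locus_id}\n"
        )
        for i, (start, end) in enumerate(locus.exons, 1):
            fh.write(
                f"{locus.locus_id}\tseedscreen\texon\t{start + 1}\t{end}\t.\t+\t.\t"
                f"ID=exon:{locus.locus_id}.{i};Parent=gene:{locus.locus_id}\n"
            )


def cassette_to_record(cassette: SeedCassette) -> SeqRecord:
    record = SeqRecord(
        Seq(cassette.sequence),
        id=f"SEED_{cassette.locus_id}"[:16],
        name=f"SEED_{cassette.locus_id}"[:16],
        description=f"SEED cassette for {cassette.locus_id}, "
        f"3' variant {cassette.three_prime_variant}",
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    for label, (start, end) in cassette.annotations:
        record.features.append(
            SeqFeature(
                SimpleLocation(start, end, strand=1),
                type="misc_feature",
                qualifiers={"label": [label]},
            )
        )
    return record


def write_cassette(cassette: SeedCassette, path, fmt: str | None = None) -> None:
    """Write a cassette as GenBank (.gb) or FASTA (.fa)."""
    path = Path(path)
    if fmt is None:
        fmt = "genbank" if path.suffix in (".gb", ".gbk", ".genbank") else "fasta"
    SeqIO.write(cassette_to_record(cassette), str(path), fmt)


def read_cassette_record(path) -> SeqRecord:
    return next(SeqIO.parse(str(path), "genbank"))
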