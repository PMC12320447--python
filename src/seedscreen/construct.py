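"""Design and in-silico validation of synthetic-exon knock-in cassettes.

A SEED (synthetic exon expression disruptor) is a homology-directed repair
template that integrates into an intron of a surface-expressed target gene.
Its insert behaves as a synthetic exon: a splice acceptor captures the
upstream endogenous exons, a P2A peptide truncates the target protein, a
transgene payload follows, and one of four 3' architectures decides how the
transcript ends:

``P2A_SD``
    a second P2A followed by the splice donor of the interrupted exon; the
    endogenous downstream exons and poly(A) are reused.
``OPEN_READTHROUGH``
    no second P2A; the payload open reading frame is completed in-frame by
    the endogenous downstream exons (receptor chains built on endogenous
    constant domains use this form).
``POLYA``
    a stop codon and an exogenous poly(A) signal terminate the transcript
    inside the insert; no splice donor.
``EXOGENOUS_PROMOTER_STOP``
    the spliced target transcript is terminated by an in-frame stop right
    after the splice acceptor, and the payload is expressed from its own
    promoter within the insert.

Because the insert splices into the host transcript, every element boundary
must respect reading frame.  ``frame_fill`` computes the 0-2 nt fillers that
close the frame on both sides, and ``simulate_splice`` is the validation
engine: it rebuilds the mature mRNA the spliceosome would produce and checks
that the payload translation survives intact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .codons import STOP_CODONS, translate

THREE_PRIME_VARIANTS = (
    "P2A_SD",
    "OPEN_READTHROUGH",
    "POLYA",
    "EXOGENOUS_PROMOTER_STOP",
)


class FrameError(ValueError):
    """Raised when a cassette breaks the reading frame of the spliced transcript."""


# --------------------------------------------------------------------------
# Default cassette elements.
#
# The splice-element block (polypyrimidine tract + branchpoint + acceptor AG)
# is a synthetic minimal acceptor; real designs substitute the acceptor
# region of a validated chimeric intron via CassetteElements.  The P2A is the
# canonical GSG-linked porcine teschovirus 2A.
# --------------------------------------------------------------------------

DEFAULT_SA_BLOCK = "TACTAACATCTCTTTTTTTTTCCTTCCTGCAG"  # BP .. polyY .. 3'AG
DEFAULT_SD = "GTAAGTATCTGACCTTGGGCTTAG"  # 5' GT donor + intronic tail
DEFAULT_P2A = "GGAAGCGGAGCTACTAACTTCAGCCTGCTGAAGCAGGCTGGAGACGTGGAGGAGAACCCTGGACCT"
P2A_AA = translate(DEFAULT_P2A)  # GSGATNFSLLKQAGDVEENPGP
DEFAULT_POLYA = "AATAAAAGATCTTTATTTTCATTAGATCTGTGTGTTGGTTTTTTGTGTG"  # minimal signal
DEFAULT_PROMOTER = "TAGTTATTAATAGTAATCAATTACGGGGTCATTAGTTCATAGCCCATAT"  # synthetic minimal
DEFAULT_STOP = "TAA"


@dataclass(frozen=True)
class CassetteElements:
    """Sequences for the synthetic splice/expression elements of a cassette."""

    sa_block: str = DEFAULT_SA_BLOCK
    sd: str = DEFAULT_SD
    p2a: str = DEFAULT_P2A
    polya: str = DEFAULT_POLYA
    promoter: str = DEFAULT_PROMOTER
    stop_codon: str = DEFAULT_STOP

    def __post_init__(self) -> None:
        if len(self.p2a) % 3 != 0:
            raise ValueError("P2A length must be divisible by 3")
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(f"{self.stop_codon!r} is not a stop codon")
        if not self.sa_block.endswith("AG"):
            raise ValueError("splice-acceptor block must end with the 3' AG")
        if not self.sd.startswith("GT"):
            raise ValueError("splice donor must start with the 5' GT")


@dataclass
class TargetLocus:
    """A strand-normalized target locus (coding strand on the forward string).

    ``exons`` are 0-based half-open intervals on ``sequence``; the coding
    sequence is assumed to start at ``exons[0][0] + cds_start`` and the exon
    intervals to be fully coding thereafter.  ``cds_phase_per_exon[i]`` is
    the cumulative coding length upstream of exon *i*, mod 3.
    """

    locus_id: str
    sequence: str
    exons: list[tuple[int, int]]
    cds_phase_per_exon: list[int]
    intron_cut_site: int
    strand: str = "+"
    cds_start: int = 0
    signal_peptide_interval: tuple[int, int] | None = None
    transmembrane_interval: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end <= len(self.sequence)):
                raise ValueError(f"exon ({start}, {end}) outside locus bounds")
            if start <= prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end
        if len(self.cds_phase_per_exon) != len(self.exons):
            raise ValueError("one CDS phase required per exon")
        cum = 0
        for i, (start, end) in enumerate(self.exons):
            if self.cds_phase_per_exon[i] != cum % 3:
                raise ValueError(
                    f"phase of exon {i} inconsistent with cumulative CDS length"
                )
            cum += (end - start) - (self.cds_start if i == 0 else 0)

    # -- intron/exon geometry helpers ------------------------------------

    def exon_containing(self, pos: int) -> int | None:
        for i, (start, end) in enumerate(self.exons):
            if start <= pos < end:
                return i
        return None

    def is_intronic(self, pos: int) -> bool:
        """True if ``pos`` lies strictly inside an intron between two exons."""
        if self.exon_containing(pos) is not None:
            return False
        return self.exons[0][1] <= pos < self.exons[-1][0]

    def upstream_exons(self, cut: int) -> list[tuple[int, int]]:
        return [e for e in self.exons if e[1] <= cut]

    def downstream_exons(self, cut: int) -> list[tuple[int, int]]:
        return [e for e in self.exons if e[0] >= cut]

    def mature_mrna(self) -> str:
        return "".join(self.sequence[s:e] for s, e in self.exons)


@dataclass
class SeedCassette:
    """An assembled SEED repair template with per-element annotations."""

    locus_id: str
    cut_site: int
    three_prime_variant: str
    left_homology_arm: str
    right_homology_arm: str
    sa_block: str
    five_prime_filler: str
    p2a_5: str
    payload_orf: str
    three_prime_filler: str
    elements: CassetteElements
    annotations: list[tuple[str, tuple[int, int]]] = field(default_factory=list)
    parts: list[tuple[str, str]] = field(default_factory=list)

    @property
    def sequence(self) -> str:
        return "".join(seq for _, seq in self.parts)

    @property
    def insert(self) -> str:
        """The integrated payload region, i.e. the cassette minus its arms."""
        return self.sequence[
            len(self.left_homology_arm) : len(self.sequence) - len(self.right_homology_arm)
        ]


@dataclass
class SplicedTranscript:
    """Predicted mature mRNA, CDS and protein of an edited allele."""

    mature_mrna: str
    cds: str
    protein: str
    p2a_cleavage_offsets: list[int]
    payload_transcript: str | None = None


def frame_fill(
    upstream_leftover_nt: int, downstream_required_phase: int
) -> tuple[int, int]:
    """Filler lengths closing the reading frame across the synthetic exon.

    ``upstream_leftover_nt`` is the cumulative coding length of the retained
    upstream exons mod 3 (the bases of the codon interrupted by the splice
    acceptor).  ``downstream_required_phase`` is the phase of the endogenous
    exon that resumes after the splice donor.  The 5' filler completes the
    interrupted codon; since every internal element (P2A, payload) is a
    multiple of 3, the 3' filler simply re-creates the downstream phase.
    """
    if not 0 <= upstream_leftover_nt <= 2:
        raise ValueError("upstream leftover must be 0-2")
    if not 0 <= downstream_required_phase <= 2:
        raise ValueError("downstream phase must be 0-2")
    five_prime = (-upstream_leftover_nt) % 3
    three_prime = downstream_required_phase % 3
    return five_prime, three_prime


def validate_integration_site(locus: TargetLocus) -> tuple[bool, str]:
    """Check that the cut site can disrupt surface expression of the target.

    Passes iff the cut is intronic and, when signal-peptide/transmembrane
    annotations exist, lies strictly between them (so the truncated protein
    retains its signal peptide but loses the membrane anchor).
    """
    cut = locus.intron_cut_site
    if cut is None:
        raise ValueError("locus has no cut site")
    if not 0 <= cut <= len(locus.sequence):
        return False, f"cut site {cut} outside locus bounds"
    if not locus.is_intronic(cut):
        return False, "not intronic"
    if locus.signal_peptide_interval is not None and cut < locus.signal_peptide_interval[1]:
        return False, "upstream of signal peptide; truncation would abolish targeting"
    if locus.transmembrane_interval is not None and cut >= locus.transmembrane_interval[0]:
        return False, "disruption would not remove surface expression"
    return True, "cut site between signal peptide and transmembrane domain"


def _check_payload(payload: str) -> None:
    if len(payload) % 3 != 0:
        raise ValueError(f"payload length {len(payload)} not divisible by 3")
    aa = translate(payload)
    if "*" in aa:
        raise ValueError("payload contains an in-frame stop codon")


def assemble_seed(
    locus: TargetLocus,
    payload: str,
    variant: str = "P2A_SD",
    arm_length: int = 500,
    elements: CassetteElements | None = None,
    strict: bool = False,
) -> SeedCassette:
    """Assemble a SEED cassette inserting ``payload`` at the locus cut site.

    ``arm_length`` nt of genomic sequence on each side of the cut become the
    homology arms.  In ``strict`` mode the splice elements must be supplied
    explicitly rather than defaulted.
    """
    if variant not in THREE_PRIME_VARIANTS:
        raise ValueError(f"unknown 3' variant {variant!r}; choose from {THREE_PRIME_VARIANTS}")
    if strict and elements is None:
        raise ValueError("strict mode requires explicit cassette elements")
    el = elements or CassetteElements()
    payload = payload.upper()
    _check_payload(payload)

    ok, reason = validate_integration_site(locus)
    if not ok:
        raise ValueError(f"invalid integration site: {reason}")
    cut = locus.intron_cut_site
    if arm_length <= 0:
        raise ValueError("arm length must be positive")
    if cut - arm_length < 0 or cut + arm_length > len(locus.sequence):
        raise ValueError("homology arms extend past the locus sequence")

    upstream_leftover = sum(e - s for s, e in locus.upstream_exons(cut)) - locus.cds_start
    downstream = locus.downstream_exons(cut)
    downstream_phase = (
        locus.cds_phase_per_exon[len(locus.exons) - len(downstream)] if downstream else 0
    )
    f5_len, f3_len = frame_fill(upstream_leftover % 3, downstream_phase)
    # fillers drawn from a fixed neutral alphabet; any non-splice-site base works
    filler5 = "GCCACC"[:f5_len]
    filler3 = "GGCGCC"[:f3_len]

    parts: list[tuple[str, str]] = [
        ("left_homology_arm", locus.sequence[cut - arm_length : cut]),
        ("sa_block", el.sa_block),
        ("five_prime_filler", filler5),
    ]
    if variant == "P2A_SD":
        parts += [
            ("p2a_5", el.p2a),
            ("payload_orf", payload),
            ("p2a_3", el.p2a),
            ("three_prime_filler", filler3),
            ("sd", el.sd),
        ]
    elif variant == "OPEN_READTHROUGH":
        parts += [
            ("p2a_5", el.p2a),
            ("payload_orf", payload),
            ("three_prime_filler", filler3),
            ("sd", el.sd),
        ]
    elif variant == "POLYA":
        parts += [
            ("p2a_5", el.p2a),
            ("payload_orf", payload),
            ("stop", el.stop_codon),
            ("polya", el.polya),
        ]
    else:  # EXOGENOUS_PROMOTER_STOP
        parts += [
            ("stop", el.stop_codon),
            ("polya", el.polya),
            ("promoter", el.promoter),
            ("payload_orf", payload),
            ("payload_stop", el.stop_codon),
            ("payload_polya", el.polya),
        ]
    parts.append(("right_homology_arm", locus.sequence[cut : cut + arm_length]))

    annotations: list[tuple[str, tuple[int, int]]] = []
    pos = 0
    for label, seq in parts:
        if seq:
            annotations.append((label, (pos, pos + len(seq))))
        pos += len(seq)

    return SeedCassette(
        locus_id=locus.locus_id,
        cut_site=cut,
        three_prime_variant=variant,
        left_homology_arm=parts[0][1],
        right_homology_arm=parts[-1][1],
        sa_block=el.sa_block,
        five_prime_filler=filler5,
        p2a_5=el.p2a if variant != "EXOGENOUS_PROMOTER_STOP" else "",
        payload_orf=payload,
        three_prime_filler=filler3 if variant in ("P2A_SD", "OPEN_READTHROUGH") else "",
        elements=el,
        annotations=annotations,
        parts=parts,
    )


def _translate_to_stop(mrna: str, cds_start: int) -> tuple[str, str]:
    """(cds, protein) from ``cds_start`` to the first in-frame stop (inclusive)."""
    coding = mrna[cds_start:]
    coding = coding[: len(coding) - len(coding) % 3]
    aa = translate(coding)
    stop = aa.find("*")
    if stop == -1:
        raise FrameError("no in-frame stop codon in spliced transcript")
    cds = coding[: 3 * (stop + 1)]
    return cds, aa[:stop]


def simulate_splice(locus: TargetLocus, cassette: SeedCassette) -> SplicedTranscript:
    """Rebuild the mature mRNA of the edited allele and validate its frame.

    The splicing model honors exactly one synthetic acceptor/donor pair: the
    endogenous upstream exons are joined to the synthetic exon (everything
    between the acceptor AG and the donor GT, or up to the poly(A) signal),
    followed by the endogenous downstream exons when a donor is present.
    Raises :class:`FrameError` if the payload translation is not contained
    intact in the predicted protein or the downstream exons fall out of
    frame — which is precisely what a corrupted filler or payload causes.
    """
    if cassette.locus_id != locus.locus_id:
        raise ValueError("cassette was assembled for a different locus")
    cut = cassette.cut_site
    insert = cassette.insert
    variant = cassette.three_prime_variant
    el = cassette.elements

    sa_at = insert.find(el.sa_block)
    if sa_at == -1:
        raise FrameError("splice-acceptor block not found in insert")
    exon_start = sa_at + len(el.sa_block)

    upstream = "".join(locus.sequence[s:e] for s, e in locus.upstream_exons(cut))
    downstream_exons = locus.downstream_exons(cut)
    downstream = "".join(locus.sequence[s:e] for s, e in downstream_exons)
    payload_aa = translate(cassette.payload_orf)
    payload_transcript = None

    if variant in ("P2A_SD", "OPEN_READTHROUGH"):
        sd_at = insert.find(el.sd, exon_start)
        if sd_at == -1:
            raise FrameError("splice donor not found in insert")
        mrna = upstream + insert[exon_start:sd_at] + downstream
    elif variant == "POLYA":
        pa_at = insert.find(el.polya, exon_start)
        if pa_at == -1:
            raise FrameError("poly(A) signal not found in insert")
        mrna = upstream + insert[exon_start:pa_at]
    else:  # EXOGENOUS_PROMOTER_STOP
        pa_at = insert.find(el.polya, exon_start)
        if pa_at == -1:
            raise FrameError("poly(A) signal not found in insert")
        mrna = upstream + insert[exon_start:pa_at]
        prom_at = insert.find(el.promoter, pa_at)
        if prom_at == -1:
            raise FrameError("payload promoter not found in insert")
        tx_start = prom_at + len(el.promoter)
        pa2_at = insert.find(el.polya, tx_start)
        payload_transcript = insert[tx_start:pa2_at if pa2_at != -1 else len(insert)]

    cds, protein = _translate_to_stop(mrna, locus.cds_start)

    if variant == "EXOGENOUS_PROMOTER_STOP":
        # the truncated target transcript must stop right after the filler;
        # the payload is translated from its own promoter-driven transcript
        assert payload_transcript is not None
        pl_cds, pl_protein = _translate_to_stop(
            payload_transcript + el.stop_codon, 0
        )
        if pl_protein != payload_aa:
            raise FrameError("payload ORF corrupted in promoter-driven transcript")
        return SplicedTranscript(
            mature_mrna=mrna,
            cds=pl_cds,
            protein=pl_protein,
            p2a_cleavage_offsets=[],
            payload_transcript=payload_transcript,
        )

    if payload_aa not in protein:
        raise FrameError("payload translation not contained in spliced protein")

    if variant in ("P2A_SD", "OPEN_READTHROUGH") and downstream:
        # downstream endogenous exons must resume in their original phase
        phase = locus.cds_phase_per_exon[len(locus.exons) - len(downstream_exons)]
        skip = (3 - phase) % 3
        ds_coding = downstream[skip:]
        ds_coding = ds_coding[: len(ds_coding) - len(ds_coding) % 3]
        ds_aa = translate(ds_coding)
        ds_stop = ds_aa.find("*")
        expected_tail = ds_aa[:ds_stop] if ds_stop != -1 else ds_aa
        if expected_tail and not protein.endswith(expected_tail):
            raise FrameError("endogenous downstream exons are out of frame")

    p2a_aa = translate(cassette.p2a_5) if cassette.p2a_5 else ""
    offsets = []
    if p2a_aa:
        at = protein.find(p2a_aa)
        while at != -1:
            offsets.append(at + len(p2a_aa) - 1)  # terminal proline of 2A
            at = protein.find(p2a_aa, at + 1)

    return SplicedTranscript(
        mature_mrna=mrna,
        cds=cds,
        protein=protein,
        p2a_cleavage_offsets=offsets,
    )
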