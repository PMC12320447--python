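"""Cassette assembly, reading-frame arithmetic and splice validation."""

import itertools

import pytest

from seedscreen import construct as c
from seedscreen import io as sio
from seedscreen import simulate as sim
from seedscreen.codons import translate


def enumerate_frame_fillers(leftover, phase):
    """Independent oracle: all (f5, f3) in 0..2 satisfying mod-3 closure.

    The 5' filler must complete the interrupted upstream codon; since every
    internal element is a multiple of 3, the 3' filler alone must re-create
    the downstream exon's phase.
    """
    return [
        (f5, f3)
        for f5, f3 in itertools.product(range(3), range(3))
        if (leftover + f5) % 3 == 0 and f3 % 3 == phase
    ]


@pytest.mark.parametrize("leftover,phase", list(itertools.product(range(3), range(3))))
def test_frame_fill_matches_enumeration_oracle(leftover, phase):
    result = c.frame_fill(leftover, phase)
    solutions = enumerate_frame_fillers(leftover, phase)
    assert len(solutions) == 1  # fillers < 3 nt make the solution unique
    assert result == solutions[0]


def test_frame_fill_frozen_examples():
    assert c.frame_fill(0, 0) == (0, 0)
    assert c.frame_fill(1, 0) == (2, 0)
    assert c.frame_fill(2, 1) == (1, 1)


def test_frame_fill_rejects_out_of_range():
    with pytest.raises(ValueError):
        c.frame_fill(3, 0)
    with pytest.raises(ValueError):
        c.frame_fill(0, -1)


class TestIntegrationSite:
    def test_valid_site_between_sp_and_tm(self):
        locus, _ = sim.make_synthetic_locus(3)
        ok, reason = c.validate_integration_site(locus)
        assert ok, reason

    def test_exonic_cut_fails(self):
        locus, _ = sim.make_synthetic_locus(3)
        locus.intron_cut_site = locus.exons[0][0] + 5
        ok, reason = c.validate_integration_site(locus)
        assert not ok and "not intronic" in reason

    def test_cut_downstream_of_tm_fails(self):
        locus, _ = sim.make_synthetic_locus(4)
        # move the cut to the last intron but annotate the TM upstream of it
        last_intron_mid = (locus.exons[-2][1] + locus.exons[-1][0]) // 2
        locus.intron_cut_site = last_intron_mid
        locus.transmembrane_interval = (locus.exons[1][0], locus.exons[1][1])
        ok, reason = c.validate_integration_site(locus)
        assert not ok and "surface expression" in reason

    def test_missing_cut_site_errors(self):
        locus, _ = sim.make_synthetic_locus(3)
        locus.intron_cut_site = None
        with pytest.raises(ValueError):
            c.validate_integration_site(locus)


@pytest.mark.parametrize("variant", c.THREE_PRIME_VARIANTS)
@pytest.mark.parametrize("seed", [1, 7, 23])
def test_assemble_splice_round_trip(variant, seed):
    """For every 3' architecture the simulated spliced CDS is in frame and
    carries the payload translation verbatim."""
    locus, payload = sim.make_synthetic_locus(seed)
    cassette = c.assemble_seed(locus, payload, variant=variant, arm_length=300)
    tx = c.simulate_splice(locus, cassette)
    assert len(tx.cds) % 3 == 0
    assert translate(payload) in tx.protein


def test_annotations_cover_cassette_contiguously():
    locus, payload = sim.make_synthetic_locus(5)
    for variant in c.THREE_PRIME_VARIANTS:
        cassette = c.assemble_seed(locus, payload, variant=variant, arm_length=200)
        pos = 0
        for _, (start, end) in cassette.annotations:
            assert start == pos and end > start
            pos = end
        assert pos == len(cassette.sequence)


def test_open_readthrough_completed_by_endogenous_exons():
    """Without a 3' P2A the payload is completed by the downstream exons:
    the fusion protein ends with the endogenous C-terminal peptide."""
    locus, payload = sim.make_synthetic_locus(11)
    cassette = c.assemble_seed(locus, payload, variant="OPEN_READTHROUGH",
                               arm_length=300)
    tx = c.simulate_splice(locus, cassette)
    original_protein = translate(
        locus.mature_mrna()[: len(locus.mature_mrna()) // 3 * 3]
    ).split("*")[0]
    # the last residues of the edited protein come from the original C-terminus
    assert tx.protein[-10:] == original_protein[-10:]
    payload_at = tx.protein.find(translate(payload))
    assert payload_at >= 0


def test_polya_variant_has_stop_and_no_donor():
    locus, payload = sim.make_synthetic_locus(9)
    cassette = c.assemble_seed(locus, payload, variant="POLYA", arm_length=200)
    labels = [label for label, _ in cassette.annotations]
    assert "stop" in labels and "polya" in labels and "sd" not in labels
    tx = c.simulate_splice(locus, cassette)
    # transcript ends inside the insert: no downstream exon sequence
    downstream = locus.downstream_exons(locus.intron_cut_site)
    assert locus.sequence[slice(*downstream[0])] not in tx.mature_mrna


def test_exogenous_promoter_variant_truncates_target():
    locus, payload = sim.make_synthetic_locus(13)
    cassette = c.assemble_seed(locus, payload,
                               variant="EXOGENOUS_PROMOTER_STOP", arm_length=200)
    tx = c.simulate_splice(locus, cassette)
    assert tx.payload_transcript is not None
    assert tx.protein == translate(payload)


def test_payload_frame_violations_rejected():
    locus, payload = sim.make_synthetic_locus(3)
    with pytest.raises(ValueError):
        c.assemble_seed(locus, payload + "AC", arm_length=200)  # len % 3 != 0
    with pytest.raises(ValueError):
        c.assemble_seed(locus, payload[:-3] + "TGA", arm_length=200)  # stop
    with pytest.raises(ValueError):
        c.assemble_seed(locus, payload, arm_length=10**6)  # arms past locus


def test_corrupt_cassette_breaks_frame():
    """A 1-nt deletion inside the payload (or filler) must be caught."""
    locus, payload = sim.make_synthetic_locus(3)
    for variant in c.THREE_PRIME_VARIANTS:
        cassette = c.assemble_seed(locus, payload, variant=variant, arm_length=200)
        corrupted = [
            (label, seq[1:] if label == "payload_orf" else seq)
            for label, seq in cassette.parts
        ]
        cassette.parts = corrupted
        with pytest.raises(c.FrameError):
            c.simulate_splice(locus, cassette)


def test_genbank_round_trip(tmp_path):
    locus, payload = sim.make_synthetic_locus(17)
    cassette = c.assemble_seed(locus, payload, variant="P2A_SD", arm_length=250)
    path = tmp_path / "cassette.gb"
    sio.write_cassette(cassette, path)
    record = sio.read_cassette_record(path)
    assert str(record.seq) == cassette.sequence
    parsed = [
        (f.qualifiers["label"][0], (int(f.location.start), int(f.location.end)))
        for f in record.features
    ]
    assert parsed == cassette.annotations


def test_gff_round_trip(tmp_path):
    locus, _ = sim.make_synthetic_locus(19)
    sio.write_locus(locus, tmp_path / "l.gff3", tmp_path / "l.fa")
    loaded = sio.locus_from_gff(tmp_path / "l.gff3", tmp_path / "l.fa",
                                cut_site=locus.intron_cut_site)
    assert loaded.sequence == locus.sequence
    assert loaded.exons == locus.exons
    assert loaded.cds_phase_per_exon == locus.cds_phase_per_exon


def test_minus_strand_locus_is_normalized(tmp_path):
    """A minus-strand gene model yields the same locus as its plus-strand twin."""
    from Bio.Seq import Seq

    locus, _ = sim.make_synthetic_locus(19)
    n = len(locus.sequence)
    rc = str(Seq(locus.sequence).reverse_complement())
    with open(tmp_path / "rc.fa", "w") as fh:
        fh.write(f">rc\n{rc}\n")
    with open(tmp_path / "rc.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for i, (s, e) in enumerate(reversed(locus.exons), 1):
            fh.write(f"rc\ttest\texon\t{n - e + 1}\t{n - s}\t.\t-\t.\tID=exon{i}\n")
    loaded = sio.locus_from_gff(
        tmp_path / "rc.gff3", tmp_path / "rc.fa",
        cut_site=n - locus.intron_cut_site,
    )
    assert loaded.sequence == locus.sequence
    assert loaded.exons == locus.exons
    assert loaded.intron_cut_site == locus.intron_cut_site


def test_strict_mode_requires_explicit_elements():
    locus, payload = sim.make_synthetic_locus(3)
    with pytest.raises(ValueError):
        c.assemble_seed(locus, payload, arm_length=200, strict=True)
    cassette = c.assemble_seed(locus, payload, arm_length=200, strict=True,
                               elements=c.CassetteElements())
    assert cassette.sequence
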