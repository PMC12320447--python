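"""Scanning and saturation library design rules."""

import pytest
from hypothesis import given, settings, strategies as st

from seedscreen import library_design as lib
from seedscreen.codons import CODON_TO_AA, STANDARD_AAS, translate
from seedscreen.simulate import make_synthetic_segment


def brute_force_ranking(native, matrix):
    """Oracle: all candidate substitutions sorted by (-score, aa)."""
    pool = [aa for aa in STANDARD_AAS if aa not in {native, "A"}]
    return sorted(pool, key=lambda aa: (-matrix[native, aa], aa))


class TestBlosumPicks:
    def test_alanine_native_gets_five_matrix_picks(self, blosum):
        picks = lib.pick_blosum_substitutions("A", blosum, 5)
        assert len(picks) == 5 and "A" not in picks
        assert picks == brute_force_ranking("A", blosum)[:5]

    def test_non_alanine_native_gets_alanine_plus_four(self, blosum):
        picks = lib.pick_blosum_substitutions("D", blosum, 4)
        assert len(picks) == 5 and "A" in picks and "D" not in picks
        assert set(brute_force_ranking("D", blosum)[:4]) <= set(picks)

    def test_tie_breaks_alphabetically(self):
        # synthetic matrix where every substitution scores the same
        flat = {(a, b): 0 for a in STANDARD_AAS for b in STANDARD_AAS}
        picks = lib.pick_blosum_substitutions("A", flat, 3)
        assert picks == ["C", "D", "E"]

    def test_nonstandard_residue_rejected(self, blosum):
        with pytest.raises(ValueError):
            lib.pick_blosum_substitutions("B", blosum, 4)


class TestHomologAugmentation:
    def test_column_all_native_adds_nothing(self):
        assert lib.augment_from_homologs(101, "DDDD", set(), "D") == set()

    def test_set_difference_by_hand(self):
        out = lib.augment_from_homologs(101, ["D", "D", "E", "A"], {"A"}, "D")
        assert out == {"E"}

    def test_gap_characters_ignored(self):
        assert lib.augment_from_homologs(101, ["-", ".", "D"], set(), "D") == set()

    def test_empty_column_errors(self):
        with pytest.raises(ValueError):
            lib.augment_from_homologs(101, [], set(), "D")


class TestCodonAssignment:
    @pytest.mark.parametrize("aa,expected", [("M", ["ATG"]), ("W", ["TGG"])])
    def test_single_codon_amino_acids(self, aa, expected):
        assert lib.assign_codons(aa, "human", 2) == expected

    def test_leucine_gets_two_distinct_codons_by_usage(self):
        codons = lib.assign_codons("L", "human", 2)
        assert len(set(codons)) == 2
        assert all(CODON_TO_AA[c] == "L" for c in codons)
        assert codons == ["CTG", "CTC"]  # human usage 39.6 > 19.6 per mille

    def test_synonymous_codon_differs_from_reference(self):
        syn = lib.synonymous_codon("GAT", "human")
        assert syn != "GAT" and CODON_TO_AA[syn] == "D"
        assert lib.synonymous_codon("ATG", "human") is None


class TestScanningDesign:
    def test_toy_three_residue_window_has_37_members(self, toy_segment, blosum):
        """3 positions x 5 substitutions x 2 codons + 3 synonymous +
        3 deletions + 1 stop = 37 (all natives non-alanine, all chosen
        substitutions multi-codon)."""
        config = lib.ScanConfig(window=(101, 103), first_residue_number=101,
                                stop_positions=(102,))
        table = lib.design_scanning_library(toy_segment, config, matrix=blosum)
        assert len(table) == 37
        subs = lib.substitutions_per_position(toy_segment, config, blosum)
        assert len(table) == lib.expected_member_count(subs, config, toy_segment)

    def test_homolog_only_residues_are_added(self, toy_segment, blosum):
        config = lib.ScanConfig(window=(101, 103), first_residue_number=101)
        base = lib.design_scanning_library(toy_segment, config, matrix=blosum)
        # homologs carry W at position 1, which BLOSUM picks never include
        homologs = ["WDK", "WDK"]
        table = lib.design_scanning_library(toy_segment, config, matrix=blosum,
                                            homologs=homologs)
        added = table[(table.position == 101) & (table.variant_aa == "W")]
        assert len(added) == 1  # W has a single codon
        assert len(table) == len(base) + 1

    def test_every_oligo_realizes_its_designed_change(self, toy_segment, blosum):
        config = lib.ScanConfig(window=(101, 103), first_residue_number=101,
                                stop_positions=(101, 103))
        table = lib.design_scanning_library(toy_segment, config, matrix=blosum)
        validated = lib.validate_member_table(table, toy_segment)
        assert validated["valid"].all()

    def test_design_is_reproducible(self, toy_segment, blosum):
        config = lib.ScanConfig(window=(101, 103), first_residue_number=101)
        t1 = lib.design_scanning_library(toy_segment, config, matrix=blosum)
        t2 = lib.design_scanning_library(toy_segment, config, matrix=blosum)
        assert t1.equals(t2)

    def test_window_outside_segment_errors(self, toy_segment, blosum):
        config = lib.ScanConfig(window=(101, 110), first_residue_number=101)
        with pytest.raises(ValueError):
            lib.design_scanning_library(toy_segment, config, matrix=blosum)

    def test_homolog_length_mismatch_errors(self, toy_segment, blosum):
        config = lib.ScanConfig(window=(101, 103), first_residue_number=101)
        with pytest.raises(ValueError):
            lib.design_scanning_library(toy_segment, config, matrix=blosum,
                                        homologs=["LD"])


class TestSaturationDesign:
    def test_nnn_expansion_counts(self, toy_segment):
        table = lib.design_saturation_library(toy_segment, 102, "NNN")
        assert len(table) == 64
        assert (table.control_class == "stop").sum() == 3
        assert (table.control_class != "stop").sum() == 61
        non_native = table[(table.control_class == "substitution")]
        assert non_native.variant_aa.nunique() == 19

    def test_nnk_expansion_counts(self, toy_segment):
        table = lib.design_saturation_library(toy_segment, 103, "NNK")
        assert len(table) == 32
        assert all(c[2] in "GT" for c in table.codon)

    def test_invalid_scheme_errors(self, toy_segment):
        with pytest.raises(ValueError):
            lib.design_saturation_library(toy_segment, 102, "NZ")
        with pytest.raises(ValueError):
            lib.design_saturation_library(toy_segment, 999, "NNN")

    def test_oligos_realize_annotated_codons(self, toy_segment):
        table = lib.design_saturation_library(toy_segment, 102, "NNN")
        for row in table.itertuples(index=False):
            aa = translate(row.oligo_sequence)
            assert aa[1] == row.variant_aa


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), length=st.integers(3, 8))
def test_count_formula_equals_enumeration_on_random_segments(seed, length):
    """Property: the closed-form member count matches the enumerated table
    for random segments and windows."""
    segment = make_synthetic_segment(seed, length=length)
    matrix = lib.load_blosum()
    config = lib.ScanConfig(
        window=(101, 101 + length - 1), first_residue_number=101,
        stop_positions=(101,),
    )
    table = lib.design_scanning_library(segment, config, matrix=matrix)
    subs = lib.substitutions_per_position(segment, config, matrix)
    assert len(table) == lib.expected_member_count(subs, config, segment)
    assert table.member_id.is_unique
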