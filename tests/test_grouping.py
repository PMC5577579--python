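import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from venomhmm.grouping import (
    ICK_PATTERN,
    RangePattern,
    SpacingSignature,
    extract_framework,
    group_sequences,
    match_pattern,
    spacing_signature,
    synthesize_from_signature,
    trim_msa_to_core,
)
from venomhmm.io_formats import Msa

from conftest import seq


class TestFrameworkAndSignature:
    def test_huwentoxin_like_pattern(self):
        s = seq("CAAAAAACAAAAACCAAAACAAAAAAAAC")
        assert extract_framework(s).render() == "C-C-CC-C-C"
        assert spacing_signature(s).gaps == (6, 5, 0, 4, 8)

    def test_no_cysteines(self):
        s = seq("MKWG")
        assert extract_framework(s).tokens == ()
        assert spacing_signature(s).gaps == ()

    def test_adjacent_cysteines_share_token(self):
        s = seq("CC")
        assert extract_framework(s).render() == "CC"
        assert spacing_signature(s).gaps == (0,)

    def test_framework_conserves_cysteine_count(self):
        s = seq("ACCACACCCA")
        fw = extract_framework(s)
        assert fw.cysteine_count == s.residues.count("C")

    def test_signature_rendering(self):
        assert SpacingSignature((6, 5, 0, 4, 8)).render() == \
            "C-X(6)-C-X(5)-C-C-X(4)-C-X(8)-C"

    @settings(max_examples=100, deadline=None)
    @given(gaps=st.lists(st.integers(0, 20), min_size=0, max_size=9))
    def test_synthesis_round_trip(self, gaps):
        signature = SpacingSignature(tuple(gaps))
        residues = synthesize_from_signature(signature)
        back = spacing_signature(seq(residues))
        assert back == signature
        assert len(spacing_signature(seq(residues)).gaps) + 1 == \
            residues.count("C")


class TestMatchPattern:
    def test_ick_positive(self):
        residues = synthesize_from_signature(
            SpacingSignature((4, 4, 0, 2, 3)), leading=6, trailing=1)
        assert match_pattern(seq(residues), ICK_PATTERN)

    def test_wrong_cysteine_count(self):
        residues = synthesize_from_signature(
            SpacingSignature((4, 4, 0, 2)), leading=6, trailing=1)
        assert not match_pattern(seq(residues), ICK_PATTERN)

    def test_gap_out_of_range(self):
        # fourth gap 11 violates its (2, 10) range
        residues = synthesize_from_signature(
            SpacingSignature((4, 4, 0, 11, 3)), leading=6, trailing=1)
        assert not match_pattern(seq(residues), ICK_PATTERN)

    def test_flank_constraint(self):
        residues = synthesize_from_signature(
            SpacingSignature((4, 4, 0, 2, 3)), leading=5, trailing=1)
        assert not match_pattern(seq(residues), ICK_PATTERN)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            RangePattern(gap_ranges=((5, 2),))


class TestGroupSequences:
    def test_distinct_spacings_split(self):
        a = [seq(synthesize_from_signature(
            SpacingSignature((6, 5, 0, 4, 8))), f"a{i}") for i in range(3)]
        b = [seq(synthesize_from_signature(
            SpacingSignature((6, 6, 0, 4, 6))), f"b{i}") for i in range(3)]
        groups = group_sequences(a + b)
        assert len(groups) == 2
        assert sorted(len(g.members) for g in groups) == [3, 3]

    def test_identical_sequences_one_group(self):
        seqs = [seq("CAACAA", f"s{i}") for i in range(4)]
        groups = group_sequences(seqs)
        assert len(groups) == 1

    def test_linear_peptides_form_no_framework_group(self):
        seqs = [seq("KRKRAGLIS", "lin1"), seq("KKRRAGLIS", "lin2"),
                seq("CAACAA", "cys1")]
        groups = group_sequences(seqs)
        keys = {g.key() for g in groups}
        assert "no-framework" in keys
        linear = next(g for g in groups if g.key() == "no-framework")
        assert sorted(linear.members) == ["lin1", "lin2"]

    def test_output_is_a_partition(self):
        seqs = [seq("CAACAAC", "x1"), seq("CAACAAC", "x2"),
                seq("CCAAC", "y1"), seq("KRKR", "z1")]
        groups = group_sequences(seqs)
        all_members = [m for g in groups for m in g.members]
        assert sorted(all_members) == sorted(s.seq_id for s in seqs)

    def test_property_split_around_double_cysteine(self):
        # same framework/spacing; polar vs hydrophobic context around CC
        polar = [seq("CAACSNQCCSNQCAAC", f"p{i}") for i in range(2)]
        hydro = [seq("CAACMWMCCMWMCAAC", f"h{i}") for i in range(2)]
        merged = group_sequences(polar + hydro, split_on_properties=False)
        split = group_sequences(polar + hydro, split_on_properties=True)
        assert len(merged) == 1
        assert len(split) == 2


class TestTrimMsa:
    def test_span_is_inclusive_between_conserved_cysteines(self):
        # conserved C columns at positions 4 and 20 (1-based) -> width 17
        left = "AAA"
        right = "GG"
        core = "C" + "W" * 15 + "C"
        rows = [(f"r{i}", left + core + right) for i in range(3)]
        trimmed = trim_msa_to_core(Msa("t", rows))
        assert trimmed.width == 17
        assert len(trimmed.rows) == 1  # identical rows collapse too

    def test_duplicate_mature_peptides_collapse(self):
        rows = [("a", "CWWC"), ("b", "CWWC"), ("c", "CWYC")]
        trimmed = trim_msa_to_core(Msa("t", rows))
        assert [sid for sid, _ in trimmed.rows] == ["a", "c"]

    def test_fragment_rows_dropped(self):
        rows = [("full1", "CWWWC"), ("full2", "CWWWC".replace("W", "Y")),
                ("frag", "C---C")]
        trimmed = trim_msa_to_core(Msa("t", rows))
        assert "frag" not in [sid for sid, _ in trimmed.rows]

    def test_linear_family_raises_instructive_error(self):
        rows = [("a", "KRKR"), ("b", "KRKR")]
        with pytest.raises(ValueError, match="skip trimming"):
            trim_msa_to_core(Msa("t", rows))
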