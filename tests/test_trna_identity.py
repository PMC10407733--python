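"""Identity-element matching, host-recognition screening, and acceptor-stem
mutation design for the pSer suppressor tRNA."""

import numpy as np
import pytest

from otskit import (
    IdentityElement,
    RecognitionProfile,
    TRNASeq,
    element_matches,
    flip_base_pair,
    overlap_elements,
    propose_orthogonalizing_mutations,
    screen_host_recognition,
)
from otskit.trna_identity import write_trna_fasta

C2_G71 = IdentityElement(kind="base_pair", pos5="2", pos3="71", required="C:G")
G1_C72 = IdentityElement(kind="base_pair", pos5="1", pos3="72", required="G:C")
U73 = IdentityElement(kind="base", pos5="73", required="U")
EXT_VLOOP = IdentityElement(kind="structural", feature="variable_loop", threshold=10)


def cognate_profile():
    """Essential recognition elements of the pSer synthetase: G1:C72 + U73."""
    return RecognitionProfile(aars="pSerRS", elements=[G1_C72, U73], flag_threshold=2)


class TestElementMatches:
    def test_acceptor_stem_pair_present(self, pser_trna):
        assert element_matches(pser_trna, C2_G71)
        assert element_matches(pser_trna, G1_C72)
        assert element_matches(pser_trna, U73)

    def test_extended_variable_loop_absent(self, pser_trna):
        assert not element_matches(pser_trna, EXT_VLOOP)

    def test_missing_position_raises(self, pser_trna):
        bad = IdentityElement(kind="base", pos5="99", required="A")
        with pytest.raises(KeyError):
            element_matches(pser_trna, bad)


class TestOverlap:
    def test_glyrs_overlap_is_exactly_the_shared_triple(
        self, pser_trna, element_catalog
    ):
        gly = next(p for p in element_catalog if p.aars == "GlyRS")
        matched = overlap_elements(pser_trna, gly)
        assert {e.describe() for e in matched} == {"G1:C72", "C2:G71", "U73"}

    def test_flipped_variant_loses_c2_g71(self, pser_trna, element_catalog):
        gly = next(p for p in element_catalog if p.aars == "GlyRS")
        opt = flip_base_pair(pser_trna, (2, 71))
        matched = overlap_elements(opt, gly)
        assert "C2:G71" not in {e.describe() for e in matched}
        assert {e.describe() for e in matched} == {"G1:C72", "U73"}

    def test_overlap_is_subset_and_monotone(self, pser_trna, element_catalog):
        gly = next(p for p in element_catalog if p.aars == "GlyRS")
        full = overlap_elements(pser_trna, gly)
        assert full <= set(gly.elements)
        smaller = RecognitionProfile(aars="GlyRS", elements=gly.elements[:-1])
        assert overlap_elements(pser_trna, smaller) <= full


class TestScreen:
    def test_fixture_flags_gly_and_thr_but_not_ser(self, pser_trna, element_catalog):
        entries = screen_host_recognition(pser_trna, element_catalog)
        flagged = {e.aars for e in entries if e.flagged}
        assert flagged == {"GlyRS", "ThrRS"}
        ser = next(e for e in entries if e.aars == "SerRS")
        assert ser.structural_unmet

    def test_structural_veto_holds_at_threshold_one(self, pser_trna, element_catalog):
        lowered = [
            RecognitionProfile(aars=p.aars, elements=p.elements, flag_threshold=1)
            for p in element_catalog
        ]
        entries = screen_host_recognition(pser_trna, lowered)
        ser = next(e for e in entries if e.aars == "SerRS")
        assert not ser.flagged

    def test_no_matches_no_flags(self, element_catalog):
        bases = {str(i): "A" for i in range(1, 77)}
        for p5, p3 in ((1, 72), (2, 71), (3, 70), (4, 69), (5, 68), (6, 67), (7, 66)):
            bases[str(p5)], bases[str(p3)] = "A", "U"
        bases["73"] = "A"
        seq = TRNASeq(name="blank", bases=bases, variable_loop_len=5)
        entries = screen_host_recognition(seq, element_catalog)
        assert not any(e.flagged for e in entries)

    def test_sorted_by_match_count_then_name(self, pser_trna, element_catalog):
        entries = screen_host_recognition(pser_trna, element_catalog)
        assert [e.aars for e in entries] == ["GlyRS", "ThrRS", "SerRS"]


class TestFlip:
    def test_flip_2_71(self, pser_trna):
        opt = flip_base_pair(pser_trna, (2, 71))
        assert opt.base_at(2) == "G" and opt.base_at(71) == "C"

    def test_involution(self, pser_trna):
        back = flip_base_pair(flip_base_pair(pser_trna, (2, 71)), (2, 71))
        assert back.bases == pser_trna.bases

    def test_other_positions_untouched(self, pser_trna):
        opt = flip_base_pair(pser_trna, (2, 71))
        for pos in pser_trna.bases:
            if pos not in ("2", "71"):
                assert opt.bases[pos] == pser_trna.bases[pos]

    def test_non_acceptor_pair_rejected(self, pser_trna):
        with pytest.raises(ValueError):
            flip_base_pair(pser_trna, (10, 25))


class TestProposeMutations:
    def test_contains_the_2_71_flip(self, pser_trna, element_catalog):
        candidates = propose_orthogonalizing_mutations(
            pser_trna, cognate_profile(), element_catalog
        )
        assert any("flip(2,71)" in c.description for c in candidates)

    def test_excludes_the_1_72_flip(self, pser_trna, element_catalog):
        candidates = propose_orthogonalizing_mutations(
            pser_trna, cognate_profile(), element_catalog
        )
        assert not any("flip(1,72)" in c.description for c in candidates)

    def test_cognate_still_matches_every_candidate(self, pser_trna, element_catalog):
        for c in propose_orthogonalizing_mutations(
            pser_trna, cognate_profile(), element_catalog
        ):
            assert all(element_matches(c.mutant, e) for e in cognate_profile().elements)

    def test_already_orthogonal_sequence_gives_empty_list(self, element_catalog):
        bases = {str(i): "A" for i in range(1, 77)}
        for p5, p3 in ((1, 72), (2, 71), (3, 70), (4, 69), (5, 68), (6, 67), (7, 66)):
            bases[str(p5)], bases[str(p3)] = "A", "U"
        bases["73"] = "A"
        seq = TRNASeq(name="blank", bases=bases, variable_loop_len=5)
        cognate = RecognitionProfile(
            aars="x", elements=[IdentityElement(kind="base", pos5="73", required="A")]
        )
        assert propose_orthogonalizing_mutations(seq, cognate, element_catalog) == []


class TestValidationAndIO:
    def test_wobble_pair_warns_but_allowed(self):
        bases = {str(i): "A" for i in range(1, 77)}
        for p5, p3 in ((1, 72), (2, 71), (3, 70), (4, 69), (5, 68), (6, 67), (7, 66)):
            bases[str(p5)], bases[str(p3)] = "G", "C"
        bases["1"], bases["72"] = "G", "U"
        bases["73"] = "U"
        with pytest.warns(UserWarning, match="G:U"):
            seq = TRNASeq(name="wob", bases=bases, variable_loop_len=5)
        assert (1, 72) in seq.wobble_pairs

    def test_non_complementary_pair_rejected(self):
        bases = {str(i): "A" for i in range(1, 77)}
        for p5, p3 in ((1, 72), (2, 71), (3, 70), (4, 69), (5, 68), (6, 67), (7, 66)):
            bases[str(p5)], bases[str(p3)] = "G", "C"
        bases["2"], bases["71"] = "A", "A"
        with pytest.raises(ValueError, match="not complementary"):
            TRNASeq(name="bad", bases=bases)

    def test_fasta_writer(self, pser_trna, tmp_path):
        out = tmp_path / "trnas.fa"
        write_trna_fasta([pser_trna, flip_base_pair(pser_trna, (2, 71))], out)
        text = out.read_text()
        assert text.count(">") == 2
        assert "tRNA-pSer" in text

    def test_sequence_length_preserved_by_flip(self, pser_trna):
        opt = flip_base_pair(pser_trna, (2, 71))
        assert len(opt.sequence()) == len(pser_trna.sequence())
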