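"""Edit application, translation edge rules, consequences and QC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haploprot.proteoforms import (
    FRAMESHIFT,
    INFRAME_DELETION,
    INFRAME_INSERTION,
    MISSENSE,
    Proteoform,
    ReferenceMismatchError,
    START_LOST,
    STOP_GAINED,
    STOP_LOST,
    SYNONYMOUS,
    apply_variants,
    build_proteoform,
    classify_consequences,
    classify_variant,
    protein_change_label,
    qc_filter,
    rescue_start,
    translate_cds,
    translate_frameshift,
)

from conftest import apply_descending, make_tv, random_dna, random_edit_set


class TestApplyVariants:
    def test_single_substitution(self):
        assert apply_variants("ATGAAACCC", [make_tv(4, "A", "G")]) == "ATGGAACCC"

    def test_insertion_shifts_later_snp(self):
        # oracle: descending-coordinate application without shift tracking
        tvs = [make_tv(4, "A", "AG"), make_tv(7, "C", "T")]
        edited = apply_variants("ATGAAACCC", tvs)
        assert edited == "ATGAGAATCC"
        assert edited == apply_descending("ATGAAACCC", tvs)

    def test_empty_edit_set_is_identity(self):
        assert apply_variants("ATGAAACCC", []) == "ATGAAACCC"

    def test_ref_mismatch_at_shifted_position(self):
        with pytest.raises(ReferenceMismatchError):
            apply_variants("ATGAAACCC", [make_tv(4, "C", "G")])

    def test_overlapping_edits_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            apply_variants(
                "ATGAAACCC", [make_tv(4, "AA", "A"), make_tv(5, "A", "G")]
            )

    def test_random_fixtures_match_descending_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(200):
            cds = random_dna(rng, int(rng.integers(30, 120)))
            tvs = random_edit_set(rng, cds)
            assert apply_variants(cds, tvs) == apply_descending(cds, tvs)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_length_accounting_property(self, seed):
        rng = np.random.default_rng(seed)
        cds = random_dna(rng, int(rng.integers(30, 90)))
        tvs = random_edit_set(rng, cds)
        edited = apply_variants(cds, tvs)
        assert len(edited) - len(cds) == sum(tv.shift for tv in tvs)


class TestTranslateCds:
    def test_standard_code_terminal_stop_dropped(self):
        assert translate_cds("ATGAAATAA") == ("MK", frozenset())

    def test_premature_stop_truncates(self):
        protein, flags = translate_cds("ATGTAAAAACCC")
        assert protein == "M"
        assert flags == {"truncated_premature_stop"}

    def test_no_stop_trailing_bases_ignored(self):
        # oracle: codon-by-codon table lookup of ATG AAA, CC dropped
        assert translate_cds("ATGAAACC") == ("MK", frozenset({"no_stop_reached"}))

    def test_stop_codon_straddles_downstream_boundary(self):
        protein, flags = translate_cds("ATGAAAT", downstream="AG")
        assert protein == "MK"
        assert flags == {"extended_readthrough"}


class TestRescueStart:
    def test_next_in_frame_atg(self):
        dna = "TTGAAAATGGCCTAA"
        assert rescue_start(dna) == 6
        assert translate_cds(dna[6:]) == ("MA", frozenset())

    def test_out_of_frame_atg_ignored(self):
        # ATG at offset 4 is out of frame; first in-frame ATG is at 9
        assert rescue_start("TTGAATGCCATGTAA") == 9

    def test_absent(self):
        assert rescue_start("TTGAAAA") is None


class TestFrameshiftReadthrough:
    def test_no_downstream_stops_at_sequence_end(self):
        tv = make_tv(4, "AA", "A")  # 1-bp deletion
        edited = apply_variants("ATGAAACCCTAA", [tv])
        assert edited == "ATGAACCCTAA"
        protein, flags = translate_frameshift(edited)
        assert protein == "MNP"
        assert flags == {FRAMESHIFT, "no_stop_reached"}

    def test_downstream_extension_until_stop(self):
        # same edit; walk continues ATG AAC CCT AAT AGC then TAA stops it
        edited = "ATGAACCCTAA"
        protein, flags = translate_frameshift(edited, downstream="TAGCTAACCC")
        assert protein == "MNPNS"
        assert flags == {FRAMESHIFT, "extended_readthrough"}

    def test_inframe_deletion_has_no_frameshift_flag(self):
        tv = make_tv(4, "AAAC", "A")  # net -3
        edited = apply_variants("ATGAAACCCTAA", [tv])
        p = build_proteoform("ATGAAACCCTAA", [tv], "T1", "h")
        assert FRAMESHIFT not in p.flags
        assert p.dna == edited


class TestBuildProteoform:
    CDS = "ATGAAACCCGGGTAA"  # MKPG

    def test_wildtype_identity_empty_flags(self):
        p = build_proteoform(self.CDS, [], "T1")
        assert p.protein == "MKPG"
        assert p.flags == frozenset()
        assert p.qc_pass

    def test_start_loss_rescued_at_next_in_frame_atg(self):
        cds = "ATGAAAATGGGGTAA"
        p = build_proteoform(cds, [make_tv(1, "A", "T")], "T1", "h")
        assert "start_rescued" in p.flags
        assert p.protein == "MG"

    def test_start_loss_without_rescue_fails_qc(self):
        p = build_proteoform(
            "ATGAAACCCGGGTAA"[:15], [make_tv(2, "T", "C")], "T1", "h"
        )
        assert p.qc == "fail:no_start"
        assert p.flags == {"no_start"}


class TestClassifyConsequences:
    CDS = "ATGAAACCCGGGTAA"

    @pytest.mark.parametrize(
        "tv,expected",
        [
            (make_tv(6, "A", "G"), SYNONYMOUS),  # AAA->AAG both K
            (make_tv(4, "A", "G"), MISSENSE),  # AAA->GAA K->E
            (make_tv(4, "A", "T"), STOP_GAINED),  # AAA->TAA
            (make_tv(1, "A", "T"), START_LOST),
            (make_tv(13, "T", "C"), STOP_LOST),  # TAA->CAA
            (make_tv(6, "A", "AGCT"), INFRAME_INSERTION),
            (make_tv(6, "ACCC", "A"), INFRAME_DELETION),
            (make_tv(6, "AC", "A"), FRAMESHIFT),
        ],
    )
    def test_single_variant_labels(self, tv, expected):
        assert classify_variant(self.CDS, tv) == expected

    def test_haplotype_labels_positionally_aligned(self):
        tvs = [make_tv(4, "A", "G"), make_tv(6, "A", "G")]
        # applied alone: missense at 4, synonymous at 6 — but 6:A>G after a
        # variant at 4 is still evaluated alone by contract
        assert classify_consequences(self.CDS, sorted(tvs, key=lambda t: t.tpos)) == (
            MISSENSE,
            SYNONYMOUS,
        )

    def test_brute_force_positional_diff_agrees(self):
        # single-substitution classification vs an alignment-free diff oracle
        rng = np.random.default_rng(5)
        sense = [
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
            if a + b + c not in {"TAA", "TAG", "TGA"}
        ]
        cds = (
            "ATG"
            + "".join(sense[i] for i in rng.integers(0, len(sense), size=20))
            + "TAA"
        )
        wt_protein, _ = translate_cds(cds)
        for _ in range(50):
            tpos = int(rng.integers(4, len(cds) - 3))
            ref = cds[tpos - 1]
            alt = "ACGT"[(("ACGT".index(ref)) + 1 + int(rng.integers(0, 3))) % 4]
            tv = make_tv(tpos, ref, alt)
            label = classify_variant(cds, tv)
            mt_protein, mt_flags = translate_cds(apply_variants(cds, [tv]))
            if mt_protein == wt_protein:
                expected = SYNONYMOUS
            elif "truncated_premature_stop" in mt_flags:
                expected = STOP_GAINED
            elif len(mt_protein) == len(wt_protein):
                expected = MISSENSE
            else:
                expected = label  # stop-lost handled in dedicated case above
            assert label == expected

    def test_protein_change_label(self):
        assert protein_change_label(self.CDS, make_tv(4, "A", "G")) == "K2E"
        assert protein_change_label(self.CDS, make_tv(6, "A", "G")) is None


class TestQcFilter:
    def mk(self, n):
        return Proteoform("T1", "h", "ATG", "A" * n, frozenset(), ())

    @pytest.mark.parametrize(
        "length,verdict",
        [
            (9, "fail:protein_too_short"),
            (10, "pass"),
            (553, "pass"),
            (4000, "pass"),
            (4001, "fail:protein_too_long"),
        ],
    )
    def test_length_boundaries(self, length, verdict):
        assert qc_filter(self.mk(length)).qc == verdict

    def test_existing_failure_preserved(self):
        p = Proteoform("T1", "h", "TTG", "", frozenset({"no_start"}), (), qc="fail:no_start")
        assert qc_filter(p).qc == "fail:no_start"
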