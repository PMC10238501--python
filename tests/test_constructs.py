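"""Construction arithmetic: translation, fusion building, frame calls, site naming."""

import numpy as np
import pytest

from dipscreen.constructs import (
    FrameVariant,
    InsertDesign,
    InsertionEvent,
    TargetConstruct,
    assign_aa_site,
    build_insertion_cds,
    classify_frame,
    construct_report,
    enumerate_in_frame_positions,
    normalize_position,
    reverse_complement,
    translate_cds,
)


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGAAA", "MK"), ("TAA", "*"), ("ATGAAAT", "MK"), ("atgaaa", "MK")],
    )
    def test_examples(self, seq, expected):
        assert translate_cds(seq) == expected

    def test_rejects_non_acgt(self):
        with pytest.raises(ValueError):
            translate_cds("ATGNAA")

    def test_rejects_too_short(self):
        with pytest.raises(ValueError):
            translate_cds("AT")

    def test_gal4_ser22_lys23(self, gal4_target):
        """The packaged Gal4 CDS translates with Ser at 22 and Lys at 23."""
        protein = gal4_target.protein
        assert protein[21] == "S" and protein[22] == "K"
        assert protein[28] == "A"  # third hit site of the screen cluster


class TestTargetConstruct:
    def test_length_must_be_codon_multiple(self):
        with pytest.raises(ValueError):
            TargetConstruct("bad", "ATGA")

    def test_protein_strips_terminal_stop(self):
        t = TargetConstruct("t", "ATGAAATAA")
        assert t.protein == "MK"


class TestBuildInsertion:
    def test_prepend_no_duplication(self):
        target = TargetConstruct("t", "ATGGGG")
        design = InsertDesign(
            domain_seq="AAATTT", tsd_len=0, variants=(FrameVariant("V", "", ""),)
        )
        ev = InsertionEvent(p=0, variant="V")
        assert build_insertion_cds(target, ev, design) == "AAATTTATGGGG"

    def test_length_formula(self, small_design):
        cds = "ATG" + "GCA" * 145 + "TGA"  # 441 nt
        target = TargetConstruct("t441", cds)
        ev = InsertionEvent(p=3, variant="LOV02")
        fusion = build_insertion_cds(target, ev, small_design)
        assert len(fusion) == 441 + 5 + 2 + 60 + 2

    def test_full_length_formula_on_real_design(self, gal4_target, lov_design):
        ev = InsertionEvent(p=3, variant="LOV02")
        fusion = build_insertion_cds(gal4_target, ev, lov_design)
        assert len(fusion) == 600 + 5 + 2 + 408 + 2

    def test_target_site_duplication_appears_twice(self, gal4_target, lov_design):
        """The 5-mer downstream of p occurs on both sides of the insert."""
        p = 65
        ev = InsertionEvent(p=p, variant="LOV02")
        fusion = build_insertion_cds(gal4_target, ev, lov_design)
        dup = gal4_target.cds[p : p + 5]
        insert = lov_design.insert_seq("LOV02")
        left = fusion[: p + 5]
        right = fusion[p + 5 + len(insert) :]
        assert left.endswith(dup)
        assert right.startswith(dup)

    def test_reverse_orientation_inserts_revcomp(self, toy_target, small_design):
        fwd = build_insertion_cds(
            toy_target, InsertionEvent(p=30, orientation="forward", variant="LOV01"),
            small_design,
        )
        rev = build_insertion_cds(
            toy_target, InsertionEvent(p=30, orientation="reverse", variant="LOV01"),
            small_design,
        )
        ins = small_design.insert_seq("LOV01")
        assert reverse_complement(ins) in rev
        assert len(fwd) == len(rev)

    def test_out_of_range_positions_raise(self, toy_target, small_design):
        with pytest.raises(ValueError):
            build_insertion_cds(
                toy_target, InsertionEvent(p=600, variant="LOV01"), small_design
            )  # p + d > L
        with pytest.raises(ValueError):
            build_insertion_cds(
                toy_target, InsertionEvent(p=999, variant="LOV01"), small_design
            )


class TestClassifyFrame:
    @pytest.mark.parametrize("p,in_frame", [(65, True), (66, False), (62, True)])
    def test_lov02_modular_arithmetic(self, gal4_target, lov_design, p, in_frame):
        ev = InsertionEvent(p=p, variant="LOV02")
        call = classify_frame(ev, lov_design, gal4_target)
        assert call.domain_in_frame is ((p + 5 + 2) % 3 == 0)
        assert call.domain_in_frame is in_frame

    def test_reverse_orientation_never_functional(self, toy_target, small_design):
        for p in (0, 1, 2, 33):
            ev = InsertionEvent(p=p, orientation="reverse", variant="LOV02")
            call = classify_frame(ev, small_design, toy_target)
            assert not call.domain_in_frame and not call.functional

    def test_frame_call_agrees_with_direct_translation(self, toy_target, small_design):
        """domain_in_frame iff the domain's own translation appears in the fusion's."""
        rng = np.random.default_rng(0)
        domain_aa = translate_cds(small_design.domain_seq)
        for _ in range(300):
            p = int(rng.integers(0, toy_target.length - 5 + 1))
            v = small_design.variants[int(rng.integers(0, 3))]
            ev = InsertionEvent(p=p, variant=v.name)
            call = classify_frame(ev, small_design, toy_target)
            fusion = build_insertion_cds(toy_target, ev, small_design)
            aa = translate_cds(fusion)
            start = p + 5 + len(v.s5)
            if call.domain_in_frame:
                assert aa[start // 3 : start // 3 + len(domain_aa)] == domain_aa
            else:
                assert start % 3 != 0

    def test_stop_in_linker_detected(self):
        """A scar engineered to create an in-frame stop codon is flagged."""
        target = TargetConstruct("t", "ATGGCAGCAGCAGCAGCA")
        # p=0 with tsd 0 and 3-nt stop scar: insert starts TAA in frame
        design = InsertDesign(
            domain_seq="GCAGCA", tsd_len=0, variants=(FrameVariant("V", "TAA", ""),)
        )
        call = classify_frame(InsertionEvent(p=0, variant="V"), design, target)
        assert call.stop_in_linker and not call.functional


class TestFramePartition:
    def test_defaults_partition_all_positions(self, toy_target, small_design):
        """Exactly one default variant is fully in frame at every position."""
        mapping = enumerate_in_frame_positions(toy_target, small_design)
        assert set(mapping) == set(range(0, 600 - 5 + 1))
        assert all(v is not None for v in mapping.values())
        by_class = {r: {mapping[p] for p in mapping if p % 3 == r} for r in range(3)}
        assert by_class == {0: {"LOV01"}, 1: {"LOV03"}, 2: {"LOV02"}}

    def test_bad_design_rejected(self):
        with pytest.raises(ValueError):
            InsertDesign(
                domain_seq="GCAGCA", tsd_len=5, variants=(FrameVariant("V", "", ""),)
            )  # 5 + 6 not a multiple of 3


class TestAssignSite:
    def test_identity_gives_full_length(self, gal4_target):
        assert assign_aa_site(gal4_target.cds, gal4_target.protein) == len(
            gal4_target.protein
        )

    def test_sk22_ke23_ak29_trio(self, gal4_target, lov_design):
        """The three in-frame LOV02 insertions of the screen's hit cluster."""
        expected = {62: 22, 65: 23, 83: 29}
        for p, site in expected.items():
            ev = InsertionEvent(p=p, variant="LOV02")
            assert classify_frame(ev, lov_design, gal4_target).functional
            fusion = build_insertion_cds(gal4_target, ev, lov_design)
            assert assign_aa_site(fusion, gal4_target.protein) == site

    def test_site_bounds_for_functional_constructs(self, toy_target, small_design):
        """site >= floor(p/3) always; it exceeds floor((p+d)/3)+1 only when a
        scar/insert codon coincidentally translates to the same residue as the
        target (wobble), which is rare and short-lived."""
        mapping = enumerate_in_frame_positions(toy_target, small_design)
        overshoots = []
        n_checked = 0
        for p in range(0, 596, 7):
            v = mapping[p]
            ev = InsertionEvent(p=p, variant=v)
            call = classify_frame(ev, small_design, toy_target)
            if not call.functional:
                continue
            n_checked += 1
            fusion = build_insertion_cds(toy_target, ev, small_design)
            site = assign_aa_site(fusion, toy_target.protein)
            assert site >= p // 3
            excess = site - ((p + 5) // 3 + 1)
            if excess > 0:
                overshoots.append(excess)
        assert n_checked > 50
        assert len(overshoots) <= 0.10 * n_checked
        assert all(e <= 3 for e in overshoots)


class TestNormalizePosition:
    def test_homopolymer_run_normalises_left(self):
        cds = "ATG" + "AAAAAA" + "GGGTAA"
        for p in (4, 5, 6):
            # within the A-run, shifting left keeps the fusion identical
            assert normalize_position(cds, p, 2) <= p
        assert normalize_position(cds, 5, 2) == normalize_position(cds, 4, 2)

    def test_unique_context_is_fixed_point(self, toy_target):
        assert normalize_position(toy_target.cds, 62, 5) in range(0, 63)


def test_construct_report_columns(toy_target, small_design):
    events = [
        InsertionEvent(p=10, variant="LOV01"),
        InsertionEvent(p=11, orientation="reverse", variant="LOV02"),
    ]
    df = construct_report(toy_target, small_design, events)
    assert list(df.columns) == [
        "p", "variant", "orientation", "domain_in_frame",
        "downstream_in_frame", "stop_in_linker", "functional", "aa_site",
    ]
    assert len(df) == 2
    assert df.loc[1, "functional"] == False  # noqa: E712
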