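"""Insertion mapper: k-mer index, junction detection, position calling, profiles."""

import numpy as np
import pytest

from dipscreen.constructs import (
    InsertionEvent,
    TargetConstruct,
    normalize_position,
    reverse_complement,
)
from dipscreen.mapping import (
    InsertionProfile,
    MapParams,
    TargetIndex,
    build_profile,
    call_insertion,
    find_junctions,
    index_target,
)
from dipscreen.simulate_reads import (
    LibrarySpec,
    ReadSimSpec,
    pool_from_events,
    sample_library,
    shear_and_read,
    write_fastq,
)
from tests.conftest import random_cds


class TestTargetIndex:
    def test_unique_sequence_unique_offsets(self, toy_target):
        idx = index_target(toy_target.cds, k=20)
        for i in range(0, 581, 13):
            hits = idx.lookup(toy_target.cds[i : i + 20])
            assert [(o, s) for o, s, *_ in [(h[0], h[1]) for h in hits] if s == "+"] == [
                (i, "+")
            ]

    def test_internal_repeat_preserves_ambiguity(self):
        repeat = random_cds(27, seed=3)[:25]
        cds = random_cds(120, seed=1) + repeat + random_cds(120, seed=2) + repeat + "AC"
        cds = cds[: len(cds) // 3 * 3]
        idx = TargetIndex(cds, k=20)
        hits = [h for h in idx.lookup(repeat[:20]) if h[1] == "+"]
        assert len(hits) == 2

    def test_k_larger_than_target_raises(self):
        with pytest.raises(ValueError):
            TargetIndex("ACGTAC", k=10)

    def test_approx_lookup_tolerates_one_mismatch(self, toy_target):
        idx = index_target(toy_target.cds, k=20)
        kmer = toy_target.cds[100:120]
        mutated = ("A" if kmer[7] != "A" else "C") + kmer[1:]
        mutated = kmer[:7] + ("A" if kmer[7] != "A" else "C") + kmer[8:]
        hits = idx.lookup_approx(mutated, max_mm=1)
        assert (100, "+", 1) in hits


class TestFindJunctions:
    def test_read_inside_domain_has_no_flanked_junction(self, toy_target, small_design):
        idx = index_target(toy_target.cds, 20)
        read = small_design.domain_seq  # wholly inside the cassette
        call, category = call_insertion(read, idx, small_design, "LOV02")
        assert call is None and category == "non-junction"

    def test_left_junction_found_in_synthetic_read(self, toy_target, small_design):
        ins = small_design.insert_seq("LOV02")
        read = toy_target.cds[30:70] + ins[:40]  # left junction at offset 40
        hits = find_junctions(read, small_design, "LOV02")
        assert ("left", 40, "forward") in hits

    def test_revcomp_domain_start_implies_reverse_orientation(
        self, toy_target, small_design
    ):
        ins = small_design.insert_seq("LOV02")
        read = toy_target.cds[30:70] + reverse_complement(ins)[:40]
        hits = find_junctions(read, small_design, "LOV02")
        assert any(side == "left" and orient == "reverse" for side, _, orient in hits)


@pytest.fixture(scope="module")
def idx(toy_target):
    return index_target(toy_target.cds, 20)


class TestCallInsertion:
    def _left_junction_read(self, target, design, p, flank=60, ins_part=60):
        from dipscreen.constructs import build_insertion_cds

        fusion = build_insertion_cds(target, InsertionEvent(p=p, variant="LOV02"), design)
        cut = p + design.tsd_len  # insert starts here in the fusion
        return fusion[cut - flank : cut + ins_part]

    def test_error_free_left_junction_call(self, toy_target, small_design, idx):
        read = self._left_junction_read(toy_target, small_design, 65)
        call, cat = call_insertion(read, idx, small_design, "LOV02")
        assert cat == "mapped"
        assert call.p == normalize_position(toy_target.cds, 65, 5)
        assert call.orientation == "forward" and call.side == "left"

    def test_one_substitution_in_flank_tolerated(self, toy_target, small_design, idx):
        read = self._left_junction_read(toy_target, small_design, 65)
        mutated = read[:30] + ("A" if read[30] != "A" else "C") + read[31:]
        call, cat = call_insertion(mutated, idx, small_design, "LOV02")
        assert cat == "mapped" and call.p == normalize_position(toy_target.cds, 65, 5)

    def test_short_flank_filtered(self, toy_target, small_design, idx):
        read = self._left_junction_read(toy_target, small_design, 65, flank=10)
        call, cat = call_insertion(read, idx, small_design, "LOV02")
        assert call is None and cat == "non-junction"

    def test_both_junctions_agree(self, toy_target, small_design, idx):
        """Left and right junctions of one insert give the same normalised p."""
        from dipscreen.constructs import build_insertion_cds

        p = 65
        fusion = build_insertion_cds(toy_target, InsertionEvent(p=p, variant="LOV02"), small_design)
        ins_len = len(small_design.insert_seq("LOV02"))
        read = fusion[p + 5 - 40 : p + 5 + ins_len + 40]  # spans the whole cassette
        call, cat = call_insertion(read, idx, small_design, "LOV02")
        assert cat == "mapped" and call.side == "both"
        assert call.p == normalize_position(toy_target.cds, p, 5)

    def test_reverse_strand_read_maps_identically(self, toy_target, small_design, idx):
        read = self._left_junction_read(toy_target, small_design, 65)
        call_f, _ = call_insertion(read, idx, small_design, "LOV02")
        call_r, _ = call_insertion(
            reverse_complement(read), idx, small_design, "LOV02"
        )
        assert call_f == call_r


class TestBuildProfile:
    def test_empty_fastq_all_zero(self, toy_target, small_design, tmp_path):
        fq = tmp_path / "empty.fastq"
        fq.write_text("")
        prof = build_profile(fq, toy_target, small_design)
        assert prof.total == 0 and not prof.counts

    def test_malformed_fastq_reports_record(self, toy_target, small_design, tmp_path):
        fq = tmp_path / "bad.fastq"
        fq.write_text("@r1\nACGT\n+\nIII\n")  # qual/seq length mismatch
        with pytest.raises(ValueError, match="record #1"):
            build_profile(fq, toy_target, small_design)

    def test_category_conservation_and_roundtrip(self, toy_target, small_design, tmp_path):
        spec = LibrarySpec(
            toy_target, small_design, n_clones=300, reverse_fraction=0.3,
            variant="LOV02",
        )
        events = sample_library(spec, 8)
        pool = pool_from_events(events, toy_target, small_design)
        reads = shear_and_read(
            pool,
            ReadSimSpec(fragment_len_range=(150, 250), read_len=200,
                        per_base_error=0.0, n_reads=4000, seed=9),
        )
        fq = tmp_path / "sim.fastq"
        write_fastq(reads, fq)
        prof = build_profile(fq, toy_target, small_design, variant="LOV02")
        assert prof.total == len(reads)
        assert prof.total == prof.mapped + prof.unmapped + prof.ambiguous + prof.non_junction
        truth = {
            (normalize_position(toy_target.cds, e.p, 5), e.orientation) for e in events
        }
        assert set(prof.counts) <= truth  # no phantom positions at zero noise
        assert prof.mapped > 0

    def test_profile_tsv_roundtrip(self, tmp_path):
        prof = InsertionProfile(label="lib1", total=10, mapped=5, unmapped=2,
                                ambiguous=1, non_junction=2)
        prof.counts[(65, "forward")] = 4
        prof.counts[(12, "reverse")] = 1
        path = tmp_path / "prof.tsv"
        prof.to_tsv(path)
        back = InsertionProfile.from_tsv(path)
        assert back.counts == prof.counts
        assert back.label == "lib1" and back.total == 10 and back.mapped == 5
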