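"""Nested-insertion resolution, DR cross-matching, composite scanning and
genome context."""

import random

import pytest

from isannot.config import PipelineConfig
from isannot.genome_io import GenomeFeature, Replicon
from isannot.nucleotide_stage import ISCopy
from isannot.structure_context import (
    annotate_context,
    match_drs_across_copies,
    resolve_intercalated,
    scan_composite_candidates,
)
from isannot.synthetic_fixtures import (
    FixtureSpec,
    ImplantSpec,
    generate_reference_library,
    generate_test_genome,
)
from isannot.pipeline import analyze_replicon


def _copy(copy_id, start, end, ref="ISA", family="ISF1", strand="+",
          ref_span=(0, 0), left="", right="", replicon="r"):
    return ISCopy(
        copy_id=copy_id, replicon_id=replicon, start=start, end=end,
        strand=strand, reference_is=ref, family=family, identity_nt=100.0,
        completeness="partial", orf_status="intact", ref_span=ref_span,
        ref_covered=ref_span[1] - ref_span[0],
        left_flank_49=left, right_flank_49=right,
    )


def _nested_fixture(seed, child_dr=None, levels=1):
    lib = generate_reference_library(3, 3, seed)
    names = sorted(lib.references)
    implants = [ImplantSpec(ref=names[0], pos=10_000)]
    for level in range(levels):
        implants.append(
            ImplantSpec(ref=names[(level + 1) % 3], pos=0, nest_in=level,
                        dr_len=child_dr if child_dr is not None
                        else min(lib[names[(level + 1) % 3]].dr_length or 4, 8))
        )
    spec = FixtureSpec(replicon_id="nst", background_length=30_000,
                       library=lib, implants=implants)
    rep, truths = generate_test_genome(spec, seed)
    return lib, rep, truths


class TestIntercalated:
    def test_parent_split_by_child_is_reconstructed(self, cfg):
        lib, rep, truths = _nested_fixture(seed=5)
        result = analyze_replicon(rep, lib, cfg, "annotate")
        assert len(result.structures) == 1
        s = result.structures[0]
        parent_truth, child_truth = truths
        parent = next(c for c in result.copies if c.copy_id == s.parent_copy)
        assert parent.interrupted
        assert parent.reference_is == parent_truth.reference_is
        assert (parent.start, parent.end) == (parent_truth.start, parent_truth.end)
        child = next(c for c in result.copies if c.copy_id in s.inserted)
        assert child.nested_in == parent.copy_id
        assert s.junction_gap == len(child_truth.dr_seq)

    def test_child_without_duplication_resolves_with_zero_gap(self, cfg):
        lib, rep, truths = _nested_fixture(seed=6, child_dr=0)
        result = analyze_replicon(rep, lib, cfg, "annotate")
        assert len(result.structures) == 1
        assert result.structures[0].junction_gap == 0

    def test_distant_fragments_without_intervening_copy_not_joined(self, cfg):
        f1 = _copy("a", 1000, 2000, ref_span=(0, 1000))
        f2 = _copy("b", 52000, 53000, ref_span=(1000, 2000))
        rep = Replicon(id="r", sequence="A" * 60000)
        lib = generate_reference_library(1, 1, 0)
        structures, copies = resolve_intercalated([f1, f2], lib, rep,
                                                  PipelineConfig())
        assert structures == [] and len(copies) == 2

    def test_three_level_nesting_recovers_the_full_tree(self, cfg):
        lib, rep, truths = _nested_fixture(seed=8, levels=2)
        result = analyze_replicon(rep, lib, cfg, "annotate")
        assert len(result.structures) == 2
        by_ref = {c.reference_is: c for c in result.copies}
        outer, middle, inner = truths
        assert by_ref[outer.reference_is].interrupted
        assert by_ref[middle.reference_is].interrupted
        assert by_ref[middle.reference_is].nested_in == \
            by_ref[outer.reference_is].copy_id
        assert by_ref[inner.reference_is].nested_in == \
            by_ref[middle.reference_is].copy_id
        # fragments never overlap on the reference; children lie inside parents
        for c in result.copies:
            if c.nested_in:
                parent = next(p for p in result.copies
                              if p.copy_id == c.nested_in)
                assert parent.start < c.start and c.end < parent.end


class TestDrMatches:
    def test_swapped_duplications_between_two_copies_found(self):
        # copy2's left DR reappears as copy3's right DR and vice versa
        c2 = _copy("c2", 1000, 2000, left="G" * 41 + "ACGTACGT",
                   right="TTTTGGGG" + "C" * 41)
        c3 = _copy("c3", 30000, 31000, left="A" * 41 + "TTTTGGGG",
                   right="ACGTACGT" + "T" * 41)
        matches = match_drs_across_copies([c2, c3], min_len=4)
        pairs = {(m.copy_a, m.side_a, m.copy_b, m.side_b, m.seq)
                 for m in matches}
        assert ("c2", "left", "c3", "right", "ACGTACGT") in pairs
        assert ("c2", "right", "c3", "left", "TTTTGGGG") in pairs
        assert len(matches) == 2

    def test_distinct_flanks_yield_no_matches(self):
        a = _copy("a", 0, 10, left="A" * 49, right="C" * 49)
        b = _copy("b", 100, 110, left="G" * 49, right="T" * 49)
        assert match_drs_across_copies([a, b], min_len=4) == []

    def test_matches_below_minimum_length_excluded(self):
        a = _copy("a", 0, 10, left="C" * 46 + "ACG", right="T" * 49)
        b = _copy("b", 100, 110, left="G" * 49, right="ACG" + "A" * 46)
        assert match_drs_across_copies([a, b], min_len=4) == []
        assert match_drs_across_copies([a, b], min_len=3) != []


class TestComposite:
    def test_nearby_same_is_pair_with_bracketing_dr(self, cfg):
        a = _copy("a", 1000, 2000, left="C" * 41 + "ACGTACGT")
        b = _copy("b", 6000, 7000, right="ACGTACGT" + "G" * 41)
        candidates, notes = scan_composite_candidates([a, b], cfg)
        assert len(candidates) == 1
        cand = candidates[0]
        assert cand.orientation == "direct"
        assert cand.span == (1000, 7000)
        assert cand.flanking_dr == "ACGTACGT"
        assert notes == []

    def test_distant_pair_with_shared_dr_becomes_rearrangement_note(self, cfg):
        a = _copy("a", 1000, 2000, left="C" * 41 + "ACGTACGT")
        b = _copy("b", 60000, 61000, right="ACGTACGT" + "G" * 41)
        candidates, notes = scan_composite_candidates([a, b], cfg)
        assert candidates == []
        assert len(notes) == 1 and "rearrangement" in notes[0]

    def test_different_families_never_pair(self, cfg):
        a = _copy("a", 1000, 2000, ref="ISA", family="ISF1")
        b = _copy("b", 3000, 4000, ref="ISB", family="ISF2")
        candidates, notes = scan_composite_candidates([a, b], cfg)
        assert candidates == [] and notes == []

    def test_inverted_orientation_recorded(self, cfg):
        a = _copy("a", 1000, 2000, strand="+")
        b = _copy("b", 4000, 5000, strand="-")
        candidates, _ = scan_composite_candidates([a, b], cfg)
        assert candidates[0].orientation == "inverted"


class TestContext:
    def test_insertion_inside_gene_reports_it_disrupted(self):
        rep = Replicon(
            id="r", sequence="A" * 10000,
            features=[GenomeFeature("CDS", 3000, 5000, "+",
                                    {"locus_tag": "geneX"})],
        )
        copy = _copy("c", 3500, 4500)
        report = annotate_context(copy, rep)
        assert report.disrupted_gene and "geneX" in report.disrupted_gene

    def test_flanking_genes_located_within_window(self):
        rep = Replicon(
            id="r", sequence="A" * 20000,
            features=[
                GenomeFeature("CDS", 1000, 2000, "+", {"locus_tag": "left1"}),
                GenomeFeature("CDS", 9000, 9900, "+", {"locus_tag": "right1"}),
            ],
        )
        report = annotate_context(_copy("c", 4000, 6000), rep, window=5000)
        assert "left1" in report.left_gene
        assert "right1" in report.right_gene
        assert report.disrupted_gene is None

    def test_copy_at_replicon_start_has_no_left_gene(self):
        rep = Replicon(
            id="r", sequence="A" * 10000,
            features=[GenomeFeature("CDS", 5000, 6000, "+", {})],
        )
        report = annotate_context(_copy("c", 0, 1000), rep)
        assert report.left_gene is None and report.right_gene is not None

    def test_featureless_replicon_gives_empty_report(self):
        rep = Replicon(id="r", sequence="A" * 5000)
        report = annotate_context(_copy("c", 1000, 2000), rep)
        assert (report.left_gene, report.right_gene,
                report.disrupted_gene) == (None, None, None)


def test_dr_matches_are_reverifiable_from_the_sequence(small_fixture, cfg):
    """Every reported cross-copy DR match is an exact string fact about the
    replicon, checkable without the detector."""
    rep = small_fixture["rep"]
    lib = small_fixture["lib"]
    result = analyze_replicon(rep, lib, cfg, "annotate")
    for m in result.dr_matches:
        by_id = {c.copy_id: c for c in result.copies}
        a, b = by_id[m.copy_a], by_id[m.copy_b]
        k = len(m.seq)
        word_a = (rep.sequence[a.start - k : a.start] if m.side_a == "left"
                  else rep.sequence[a.end : a.end + k])
        word_b = (rep.sequence[b.start - k : b.start] if m.side_b == "left"
                  else rep.sequence[b.end : b.end + k])
        assert word_a == word_b == m.seq
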