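"""Candidate regions, nucleotide search, clustering, IR/DR detection and
copy assembly."""

import dataclasses
import itertools
import random

import pytest

from isannot.config import PipelineConfig
from isannot.genome_io import Replicon
from isannot.nucleotide_stage import (
    CandidateRegion,
    assemble_is_copy,
    cluster_candidate_regions,
    detect_direct_repeat,
    detect_inverted_repeats,
    extract_candidate_region,
    find_orfless_partials,
    pairwise_region_identity,
    search_nucleotide_library,
)
from isannot.protein_stage import CandidateOrf
from isannot.util import revcomp


def _orf(start, end, replicon="r", strand="+"):
    return CandidateOrf(
        replicon_id=replicon, start=start, end=end, strand=strand,
        protein="M" * max(30, (end - start) // 3 - 1), source="called",
        classification="complete", nearest_is="ISToy1",
    )


def _rep(seq, rid="r"):
    return Replicon(id=rid, sequence=seq)


def _region(seq, rid="r"):
    return CandidateRegion(
        replicon_id=rid, start=0, end=len(seq), ext_start=0, ext_end=len(seq),
        sequence=seq, extended_sequence=seq,
    )


def _mutate(seq, frac, seed):
    rng = random.Random(seed)
    chars = list(seq)
    for i in rng.sample(range(len(chars)), int(frac * len(chars))):
        choices = [b for b in "ACGT" if b != chars[i]]
        chars[i] = rng.choice(choices)
    return "".join(chars)


class TestCandidateRegion:
    def test_core_span_is_first_orf_start_to_last_orf_end(self):
        rep = _rep("A" * 5000)
        region = extract_candidate_region(
            [_orf(1000, 2000), _orf(2100, 3000)], 500, rep
        )
        assert (region.start, region.end) == (1000, 3000)
        assert (region.ext_start, region.ext_end) == (500, 3500)

    def test_single_orf_core_equals_orf_span(self):
        region = extract_candidate_region([_orf(700, 1600)], 500, _rep("G" * 3000))
        assert (region.start, region.end) == (700, 1600)

    def test_extended_span_clipped_at_replicon_edge(self):
        region = extract_candidate_region([_orf(200, 900)], 500, _rep("C" * 1100))
        assert region.ext_start == 0 and region.ext_end == 1100

    def test_orfs_from_different_replicons_rejected(self):
        with pytest.raises(ValueError):
            extract_candidate_region(
                [_orf(0, 300, "a"), _orf(400, 700, "b")], 500, _rep("A" * 1000)
            )


class TestNucleotideSearch:
    def test_exact_copy_hits_full_subject_at_full_identity(self, lib, cfg):
        name, seq = lib.nucleotide_entries()[0]
        region = _region("GATC" * 100 + seq + "TTGA" * 100)
        hits = search_nucleotide_library(region, lib, cfg)
        top = hits[0]
        assert top.subject_is == name and top.identity == 100.0
        assert top.subject_span == (0, len(seq))
        assert top.query_span == (400, 400 + len(seq))

    def test_ninety_percent_copy_not_retained_at_default_threshold(self, lib, cfg):
        name, seq = lib.nucleotide_entries()[0]
        region = _region(_mutate(seq, 0.10, 1))
        hits = [h for h in search_nucleotide_library(region, lib, cfg)
                if h.subject_is == name]
        assert hits == []

    def test_internal_fragment_retained_with_partial_subject_span(self, lib, cfg):
        name, seq = lib.nucleotide_entries()[0]
        frag = seq[500:800]
        rng = random.Random(41)
        flank = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        region = _region(flank(200) + frag + flank(200))
        hits = [h for h in search_nucleotide_library(region, lib, cfg)
                if h.subject_is == name]
        assert hits
        s0, s1 = hits[0].subject_span
        assert abs(s0 - 500) <= 5 and abs(s1 - 800) <= 5

    def test_lowering_identity_threshold_never_loses_hits(self, lib, cfg):
        name, seq = lib.nucleotide_entries()[0]
        region = _region(
            "GATC" * 50 + _mutate(seq, 0.03, 2) + "AATC" * 50 + seq[200:600]
        )
        counts = []
        for threshold in (99.0, 97.0, 95.0, 90.0, 80.0):
            c = dataclasses.replace(cfg, nt_identity=threshold)
            counts.append(len(search_nucleotide_library(region, lib, c)))
        assert counts == sorted(counts)


class TestClustering:
    def test_three_identical_regions_form_one_group(self):
        seq = _mutate("ACGT" * 150, 0.0, 0)
        groups = cluster_candidate_regions([_region(seq)] * 3, 90.0)
        assert len(groups) == 1

    def test_eighty_percent_identity_splits_at_ninety_threshold(self):
        rng = random.Random(4)
        base = "".join(rng.choice("ACGT") for _ in range(600))
        a, b = _region(base), _region(_mutate(base, 0.20, 5))
        assert pairwise_region_identity(a.sequence, b.sequence) < 90
        assert len(cluster_candidate_regions([a, b], 90.0)) == 2

    def test_single_linkage_chains_transitive_groups(self):
        rng = random.Random(6)
        base = "".join(rng.choice("ACGT") for _ in range(600))
        a = _region(base)
        b = _region(_mutate(base, 0.07, 7))  # ~93% to a
        c = _region(_mutate(b.sequence, 0.07, 8))  # ~93% to b, ~86% to a
        assert pairwise_region_identity(a.sequence, c.sequence) < 90
        assert len(cluster_candidate_regions([a, b, c], 90.0)) == 1

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_candidate_regions([], 90.0)

    def test_matches_brute_force_connected_components(self):
        """Union-find clustering equals an independent BFS over the identity
        graph on randomized region sets."""
        rng = random.Random(13)
        for trial in range(10):
            bases = ["".join(rng.choice("ACGT") for _ in range(400))
                     for _ in range(3)]
            regions = [
                _region(_mutate(bases[rng.randrange(3)],
                                rng.choice([0.0, 0.04, 0.2]), trial * 31 + i))
                for i in range(6)
            ]
            got = cluster_candidate_regions(regions, 90.0)
            # oracle: adjacency + BFS, written independently of the union-find
            n = len(regions)
            adj = {i: set() for i in range(n)}
            for i, j in itertools.combinations(range(n), 2):
                if pairwise_region_identity(regions[i].sequence,
                                            regions[j].sequence) >= 90.0:
                    adj[i].add(j)
                    adj[j].add(i)
            seen, comps = set(), []
            for i in range(n):
                if i in seen:
                    continue
                queue, comp = [i], set()
                while queue:
                    k = queue.pop()
                    if k in comp:
                        continue
                    comp.add(k)
                    queue.extend(adj[k] - comp)
                seen |= comp
                comps.append(comp)
            ids = {id(r): i for i, r in enumerate(regions)}
            got_sets = [{ids[id(r)] for r in g} for g in got]
            assert sorted(map(sorted, got_sets)) == sorted(map(sorted, comps))


class TestDirectRepeat:
    def test_flanking_word_recovered(self):
        seq = "GGGGG" + "ACGTT" + "T" * 50 + "ACGTT" + "GGGGG"
        dr = detect_direct_repeat(_rep(seq), 10, 60)
        assert dr is not None and dr.seq == "ACGTT" and dr.length == 5

    def test_no_shared_terminal_word_returns_none(self):
        seq = "AAAAACC" + "T" * 40 + "GGAAAAA"
        assert detect_direct_repeat(_rep(seq), 7, 47) is None

    def test_search_truncates_at_replicon_edges(self):
        seq = "A" * 30
        assert detect_direct_repeat(_rep(seq), 0, 30) is None  # no flanks at all

    def test_fixture_duplications_recovered_exactly(self, small_fixture):
        rep = small_fixture["rep"]
        for truth in small_fixture["truths"]:
            if not truth.dr_seq:
                continue
            dr = detect_direct_repeat(rep, truth.start, truth.end)
            assert dr is not None and dr.seq == truth.dr_seq


class TestInvertedRepeats:
    def test_exact_reverse_complement_termini_found_de_novo(self):
        core = "GGTTCTG" + "A" * 200 + revcomp("GGTTCTG")
        seq = "C" * 50 + core + "C" * 50
        ir = detect_inverted_repeats(_rep(seq), 50, 50 + len(core), min_ir=7)
        assert ir is not None and ir.mode == "de_novo"
        assert ir.left_seq == "GGTTCTG" and ir.right_seq == "CAGAACC"
        assert ir.mismatches == 0

    def test_random_termini_yield_none(self):
        rng = random.Random(21)
        for trial in range(5):
            seq = "".join(rng.choice("ACGT") for _ in range(400))
            ir = detect_inverted_repeats(_rep(seq), 50, 350)
            if ir is None:
                continue
            # brute-force check: any reported pair must genuinely satisfy the
            # reverse-complement invariant within the mismatch budget
            assert ir.right_seq == _rep(seq).subseq(ir.right_start, ir.right_end)
            n_mm = sum(
                1 for x, y in zip(ir.left_seq, revcomp(ir.right_seq)) if x != y
            )
            assert n_mm == ir.mismatches
            assert n_mm <= 0.3 * len(ir.left_seq)
            assert len(ir.left_seq) >= 10

    def test_reference_guided_counts_terminal_substitution(self, lib):
        ref = lib[sorted(lib.references)[0]]
        elem = list(ref.sequence)
        elem[-1] = "A" if elem[-1] != "A" else "C"  # 1 substitution at terminus
        seq = "T" * 60 + "".join(elem) + "T" * 60
        ir = detect_inverted_repeats(_rep(seq), 60, 60 + len(elem), ref=ref)
        assert ir is not None and ir.mode == "reference_guided"
        assert ir.mismatches == 1


class TestAssembly:
    def test_exact_implant_becomes_complete_copy_with_dr(self, small_fixture, cfg):
        rep = small_fixture["rep"]
        lib = small_fixture["lib"]
        truth = small_fixture["truths"][0]
        region = CandidateRegion(
            replicon_id=rep.id, start=truth.start, end=truth.end,
            ext_start=max(0, truth.start - 500), ext_end=truth.end + 500,
            sequence=rep.subseq(truth.start, truth.end),
            extended_sequence=rep.subseq(truth.start - 500, truth.end + 500),
        )
        hits = search_nucleotide_library(region, lib, cfg)
        copies = assemble_is_copy(region, hits, rep, lib, cfg)
        match = [c for c in copies if c.reference_is == truth.reference_is]
        assert match
        copy = match[0]
        assert (copy.start, copy.end) == (truth.start, truth.end)
        assert copy.completeness == "complete"
        assert copy.dr is not None and copy.dr.seq == truth.dr_seq
        assert len(copy.left_flank_49) == 49 and len(copy.right_flank_49) == 49

    def test_partial_hit_spans_only_the_aligned_segment(self, lib, cfg):
        name, seq = lib.nucleotide_entries()[0]
        frag = seq[200:1200]
        rng = random.Random(43)
        flank = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
        genome = flank(800) + frag + flank(800)
        rep = _rep(genome)
        region = CandidateRegion(
            replicon_id="r", start=800, end=800 + len(frag), ext_start=300,
            ext_end=1300 + len(frag),
            sequence=frag, extended_sequence=rep.subseq(300, 1300 + len(frag)),
        )
        hits = [h for h in search_nucleotide_library(region, lib, cfg)
                if h.subject_is == name]
        copies = assemble_is_copy(region, hits, rep, lib, cfg)
        copy = copies[0]
        assert copy.completeness == "partial"
        assert abs(copy.start - 800) <= 5
        assert abs(copy.end - (800 + len(frag))) <= 5

    def test_copy_near_replicon_start_gets_truncated_flank(self, lib, cfg):
        name, seq = lib.nucleotide_entries()[0]
        genome = seq[300:700] + "GATC" * 300
        rep = _rep(genome)
        copies = find_orfless_partials(rep, lib, [], cfg)
        assert copies and copies[0].subject_coverage < 1
        assert copies[0].start <= 2
        assert len(copies[0].left_flank_49) < 49


class TestOrflessPartials:
    def test_internal_fragment_without_orf_detected(self, lib, cfg):
        name, seq = lib.nucleotide_entries()[1]
        frag = seq[600:850]
        rng = random.Random(31)
        bg = "".join(rng.choice("ACGT") for _ in range(4000))
        rep = _rep(bg[:2000] + frag + bg[2000:])
        copies = find_orfless_partials(rep, lib, [], cfg)
        ours = [c for c in copies if c.reference_is == name]
        assert ours and ours[0].orf_status == "absent"
        assert ours[0].completeness == "partial"
        assert ours[0].family == lib[name].family

    def test_mite_like_derivative_detected_as_single_orfless_copy(self, lib, cfg):
        name, seq = lib.nucleotide_entries()[0]
        mite = seq[:100] + seq[-100:]
        rng = random.Random(33)
        bg = "".join(rng.choice("ACGT") for _ in range(4000))
        rep = _rep(bg[:2000] + mite + bg[2000:])
        ours = [c for c in find_orfless_partials(rep, lib, [], cfg)
                if c.reference_is == name]
        assert len(ours) == 1
        copy = ours[0]
        assert copy.orf_status == "absent"
        assert abs(copy.start - 2000) <= 3
        assert abs(copy.end - (2000 + len(mite))) <= 3

    def test_is_free_genome_yields_no_copies(self, lib, cfg):
        rng = random.Random(35)
        rep = _rep("".join(rng.choice("ACGT") for _ in range(10000)))
        assert find_orfless_partials(rep, lib, [], cfg) == []
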