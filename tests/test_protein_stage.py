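"""ORF calling, protein library search, translated search and classification."""

import random

import pytest

from isannot.config import PipelineConfig
from isannot.genome_io import Replicon, extract_annotated_orfs
from isannot.protein_stage import (
    CandidateOrf,
    call_orfs,
    classify_orf,
    group_candidate_orfs,
    search_protein_library,
    translated_genome_search,
)
from isannot.util import revcomp


def _orf(protein, replicon="r", start=0, end=None, strand="+",
         source="called", pseudo=False):
    return CandidateOrf(
        replicon_id=replicon, start=start,
        end=end if end is not None else start + 3 * len(protein) + 3,
        strand=strand, protein=protein, source=source, pseudo_flag=pseudo,
    )


class TestCallOrfs:
    def test_single_orf_span_includes_stop_protein_does_not(self):
        orf_nt = "ATG" + "GCT" * 98 + "TAA"  # 300 nt
        rep = Replicon(id="r", sequence="C" * 100 + orf_nt + "C" * 100)
        found = [o for o in call_orfs(rep, 150) if o.strand == "+"]
        assert any(
            o.start == 100 and o.end == 400 and len(o.protein) == 99
            for o in found
        )

    def test_orf_below_min_length_excluded(self):
        orf_nt = "ATG" + "GCT" * 38 + "TAA"  # 120 nt
        rep = Replicon(id="r", sequence="CCC" + orf_nt + "CCC")
        assert not any(o.start == 3 for o in call_orfs(rep, 150))
        assert any(o.start == 3 for o in call_orfs(rep, 120))

    def test_reverse_strand_orf_reported_in_forward_projection(self):
        orf_nt = "ATG" + "TGG" * 60 + "TAA"
        rep = Replicon(id="r", sequence="G" * 70 + revcomp(orf_nt) + "G" * 70)
        hits = [o for o in call_orfs(rep, 150) if o.strand == "-"]
        assert any(
            o.start == 70 and o.end == 70 + len(orf_nt)
            and o.protein == "M" + "W" * 60
            for o in hits
        )


class TestLibrarySearch:
    def test_exact_transposase_is_top_hit_at_full_identity(self, lib, cfg,
                                                           transposase):
        ref, orf, protein = transposase
        hits = search_protein_library(_orf(protein), lib, cfg)
        assert hits and hits[0].subject_is == ref.name
        assert hits[0].identity == 100.0
        assert hits[0].evalue <= cfg.protein_evalue

    def test_shuffled_proteins_never_pass_the_cutoff(self, lib, cfg,
                                                     transposase):
        _, _, protein = transposase
        rng = random.Random(42)
        for _ in range(10):
            shuffled = list(protein)
            rng.shuffle(shuffled)
            assert search_protein_library(_orf("".join(shuffled)), lib, cfg) == []

    def test_half_protein_reports_half_subject_coverage(self, lib, cfg,
                                                        transposase):
        ref, _, protein = transposase
        half = protein[: len(protein) // 2]
        hits = search_protein_library(_orf(half), lib, cfg)
        assert hits[0].subject_is == ref.name
        assert hits[0].subject_coverage == pytest.approx(0.5, abs=0.05)

    def test_empty_library_is_an_error(self, cfg):
        from isannot.reference_library import ReferenceLibrary

        with pytest.raises(ValueError):
            search_protein_library(_orf("MKRW" * 20), ReferenceLibrary(), cfg)

    def test_hit_order_is_deterministic(self, lib, cfg, transposase):
        _, _, protein = transposase
        a = search_protein_library(_orf(protein), lib, cfg)
        b = search_protein_library(_orf(protein), lib, cfg)
        assert [(h.subject_is, h.subject_orf, h.evalue) for h in a] == [
            (h.subject_is, h.subject_orf, h.evalue) for h in b
        ]


class TestClassify:
    def _classified(self, protein, lib, cfg, pseudo=False):
        orf = _orf(protein, pseudo=pseudo)
        orf.hits = search_protein_library(orf, lib, cfg)
        return classify_orf(orf, lib, cfg)

    def test_exact_copy_is_complete_and_same_is(self, lib, cfg, transposase):
        ref, _, protein = transposase
        orf = self._classified(protein, lib, cfg)
        assert orf.classification == "complete"
        assert orf.same_is and orf.nearest_is == ref.name
        assert orf.family == ref.family

    def test_forty_percent_fragment_is_partial(self, lib, cfg, transposase):
        _, _, protein = transposase
        orf = self._classified(protein[: int(0.4 * len(protein))], lib, cfg)
        assert orf.classification == "partial"

    def test_intact_length_with_internal_stop_is_pseudogene(self, lib, cfg,
                                                            transposase):
        _, _, protein = transposase
        mid = len(protein) // 2
        orf = self._classified(protein[:mid] + "*" + protein[mid + 1 :], lib, cfg)
        assert orf.classification == "pseudogene"

    def test_accessory_domain_only_hit_is_unknown(self, lib, cfg):
        accessory = next(
            o.protein
            for ref in lib.references.values()
            for o in ref.orfs
            if o.role == "accessory"
        )
        orf = self._classified(accessory[: int(0.6 * len(accessory))], lib, cfg)
        assert orf.classification == "unknown"

    def test_no_hit_stays_none(self, lib, cfg):
        rng = random.Random(3)
        junk = "".join(rng.choice("ACDEFGHIKLMNPQRSTVWY") for _ in range(300))
        orf = self._classified(junk, lib, cfg)
        assert orf.classification == "none"

    def test_every_hit_bearing_orf_gets_exactly_one_category(self, lib, cfg,
                                                             transposase):
        _, _, protein = transposase
        queries = [
            protein, protein[:150], protein[: len(protein) // 2],
            protein[:100] + "*" + protein[101:],
        ]
        for q in queries:
            orf = self._classified(q, lib, cfg)
            if orf.hits:
                assert orf.classification in (
                    "complete", "partial", "pseudogene", "unknown"
                )

    def test_below_similarity_cutoff_flags_putative_new_is(self, lib, cfg,
                                                           transposase):
        ref, _, protein = transposase
        rng = random.Random(5)
        mutated = list(protein)
        for i in rng.sample(range(1, len(mutated)), int(0.15 * len(mutated))):
            mutated[i] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
        orf = self._classified("".join(mutated), lib, cfg)
        assert orf.hits and not orf.same_is
        assert orf.new_is_flag == "putative new IS"
        assert orf.family == ref.family


class TestTranslatedSearch:
    def test_unannotated_exact_gene_copy_found_at_its_coordinates(
        self, lib, cfg, transposase
    ):
        ref, orf, _ = transposase
        gene = ref.sequence[orf.start : orf.end]
        rep = Replicon(id="r", sequence="GATC" * 500 + gene + "CTGA" * 500)
        found = translated_genome_search(rep, lib, [], cfg)
        assert len(found) == 1
        cand = found[0]
        assert cand.strand == "+"
        assert abs(cand.start - 2000) <= 3
        assert abs(cand.end - (2000 + len(gene))) <= 3
        assert cand.hits[0].subject_is == ref.name

    def test_is_free_genome_yields_nothing(self, lib, cfg):
        rng = random.Random(9)
        rep = Replicon(
            id="r",
            sequence="".join(rng.choice("ACGT") for _ in range(20000)),
        )
        assert translated_genome_search(rep, lib, [], cfg) == []

    def test_single_base_deletion_merges_frames_as_pseudogene(
        self, lib, cfg, transposase
    ):
        ref, orf, _ = transposase
        gene = ref.sequence[orf.start : orf.end]
        mid = len(gene) // 2
        shifted = gene[:mid] + gene[mid + 1 :]  # 1-bp deletion: frameshift
        rep = Replicon(id="r", sequence="GATC" * 400 + shifted + "CTGA" * 400)
        found = translated_genome_search(rep, lib, [], cfg)
        assert len(found) == 1
        assert found[0].pseudo_flag
        assert found[0].hits[0].subject_is == ref.name

    def test_excluded_intervals_are_not_searched(self, lib, cfg, transposase):
        ref, orf, _ = transposase
        gene = ref.sequence[orf.start : orf.end]
        rep = Replicon(id="r", sequence="GATC" * 300 + gene + "CTGA" * 300)
        covered = [(1200, 1200 + len(gene))]
        assert translated_genome_search(rep, lib, covered, cfg) == []


def test_recall_of_implanted_transposases_is_complete(small_fixture, cfg):
    """Annotation extraction plus translated search recovers every implanted
    transposase at 100% identity."""
    rep = small_fixture["rep"]
    lib = small_fixture["lib"]
    orfs = extract_annotated_orfs(rep)
    for orf in orfs:
        orf.hits = search_protein_library(orf, lib, cfg)
        classify_orf(orf, lib, cfg)
    covered = [o.span for o in orfs]
    t_orfs = translated_genome_search(rep, lib, covered, cfg)
    for orf in t_orfs:
        classify_orf(orf, lib, cfg)
    every = orfs + t_orfs
    for truth in small_fixture["truths"]:
        ref = lib[truth.reference_is]
        tnp = ref.transposase_orfs()[0]
        if truth.strand == "+":
            span = (truth.start + tnp.start, truth.start + tnp.end)
        else:
            span = (truth.start + len(ref) - tnp.end,
                    truth.start + len(ref) - tnp.start)
        recovering = [
            o for o in every
            if o.nearest_is == truth.reference_is
            and min(o.end, span[1]) - max(o.start, span[0])
            >= 0.8 * (span[1] - span[0])
        ]
        assert recovering, f"{truth.implant_id} transposase not recovered"


def test_grouping_joins_same_reference_orfs_within_gap(cfg):
    a = _orf("M" * 40, start=1000)
    b = _orf("M" * 40, start=2500)
    c = _orf("M" * 40, start=9000)
    for o, cls in ((a, "complete"), (b, "partial"), (c, "complete")):
        o.classification = cls
        o.nearest_is = "ISToy1"
    groups = group_candidate_orfs([a, b, c], cfg)
    assert [len(g) for g in groups] == [2, 1]


def test_backend_agreement_on_high_identity_queries(lib, cfg, transposase):
    """The builtin scorer and blastp agree on the top subject for >= 95% of
    near-identical queries."""
    import dataclasses
    import shutil

    if shutil.which("blastp") is None:
        pytest.skip("BLAST+ not on PATH")
    rng = random.Random(17)
    queries = []
    for _, _, _, _, protein in lib.proteins():
        queries.append(protein)
        mutated = list(protein)
        for i in rng.sample(range(1, len(mutated)), int(0.08 * len(mutated))):
            mutated[i] = rng.choice("ACDEFGHIKLMNPQRSTVWY")
        queries.append("".join(mutated))
    ext_cfg = dataclasses.replace(cfg, backend="external")
    agree = total = 0
    for q in queries:
        builtin = search_protein_library(_orf(q), lib, cfg)
        external = search_protein_library(_orf(q), lib, ext_cfg)
        if builtin and external:
            total += 1
            agree += builtin[0].subject_is == external[0].subject_is
    assert total >= len(queries) * 0.9
    assert agree / total >= 0.95
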