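"""End-to-end orchestration of the annotation stages.

``predict`` mode stops after protein-stage classification and region
clustering and emits only the headline counts (a rapid estimate of IS
content); ``annotate`` runs the nucleotide, structure and export stages and
writes the full output bundle.  Every automatic call is logged with the rule
that produced it, and all copies start with ``validation_status=pending`` —
automatic results are a proposal for curation, not a final annotation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from isannot.config import PipelineConfig
from isannot.genome_io import (
    Replicon,
    extract_annotated_orfs,
    read_replicons,
    write_annotated_genbank,
)
from isannot.nucleotide_stage import (
    CandidateRegion,
    ISCopy,
    assemble_is_copy,
    cluster_candidate_regions,
    dedupe_copies,
    extract_candidate_region,
    find_orfless_partials,
    merge_adjacent_copies,
    search_nucleotide_library,
)
from isannot.protein_stage import (
    CandidateOrf,
    call_orfs,
    classify_orf,
    group_candidate_orfs,
    search_protein_library,
    translated_genome_search,
)
from isannot.reference_library import ReferenceLibrary, load_reference_library
from isannot.reporting_export import (
    PredictionSummary,
    build_annotation_table,
    export_gff,
    render_is_report,
    render_is_report_text,
    summarize_prediction,
    write_summary_json,
)
from isannot.structure_context import (
    ContextReport,
    annotate_context,
    match_drs_across_copies,
    resolve_intercalated,
    scan_composite_candidates,
)
from isannot.util import merge_intervals

logger = logging.getLogger("isannot")


@dataclass
class PipelineResult:
    mode: str
    replicons: list[Replicon]
    orfs: list[CandidateOrf] = field(default_factory=list)
    regions: list[CandidateRegion] = field(default_factory=list)
    region_clusters: list[list[CandidateRegion]] = field(default_factory=list)
    copies: list[ISCopy] = field(default_factory=list)
    structures: list = field(default_factory=list)
    dr_matches: list = field(default_factory=list)
    composites: list = field(default_factory=list)
    rearrangement_notes: list[str] = field(default_factory=list)
    contexts: list[ContextReport] = field(default_factory=list)
    summary: PredictionSummary | None = None


def analyze_replicon(
    rep: Replicon, lib: ReferenceLibrary, cfg: PipelineConfig, mode: str
) -> PipelineResult:
    """Run the stages on a single replicon (already in memory)."""
    result = PipelineResult(mode=mode, replicons=[rep])

    # -- protein stage: candidates from annotation or de novo calling
    if any(f.kind in ("CDS", "pseudogene") for f in rep.features):
        orfs = extract_annotated_orfs(rep)
        logger.info("%s: %d annotated coding features", rep.id, len(orfs))
    else:
        orfs = call_orfs(rep, cfg.orf_min_len)
        logger.info("%s: %d ORFs called de novo", rep.id, len(orfs))
    for orf in orfs:
        orf.hits = search_protein_library(orf, lib, cfg)
        classify_orf(orf, lib, cfg)

    # -- translated search over everything not already examined
    covered = merge_intervals([o.span for o in orfs])
    t_orfs = translated_genome_search(rep, lib, covered, cfg)
    for orf in t_orfs:
        orf.hits = search_protein_library(orf, lib, cfg) or orf.hits
        classify_orf(orf, lib, cfg)
    all_orfs = orfs + t_orfs
    result.orfs = all_orfs

    # -- candidate regions and clustering
    groups = group_candidate_orfs(all_orfs, cfg)
    regions = [extract_candidate_region(g, cfg.region_margin, rep) for g in groups]
    result.regions = regions
    if regions:
        result.region_clusters = cluster_candidate_regions(
            regions, cfg.cluster_identity
        )
    if mode == "predict":
        is_orfs = [o for o in all_orfs if o.classification != "none"]
        result.summary = PredictionSummary(
            total_is_orf=len(is_orfs),
            complete_orf=sum(o.classification == "complete" for o in is_orfs),
            partial_orf=sum(o.classification == "partial" for o in is_orfs),
            pseudogene=sum(o.classification == "pseudogene" for o in is_orfs),
            unknown_orf=sum(o.classification == "unknown" for o in is_orfs),
            total_is=len(regions),
            different_is=len({g[0].nearest_is for g in groups if g[0].nearest_is}),
        )
        return result

    # -- nucleotide stage
    copies: list[ISCopy] = []
    for region in regions:
        hits = search_nucleotide_library(region, lib, cfg)
        copies.extend(assemble_is_copy(region, hits, rep, lib, cfg))
    covered_copies = merge_intervals([c.span for c in copies])
    copies.extend(find_orfless_partials(rep, lib, covered_copies, cfg))
    copies = merge_adjacent_copies(copies, rep, lib, cfg)
    copies = dedupe_copies(copies, cfg)
    # provisional ids; fragments joined during intercalation resolution keep
    # these in the structure record, final copies are renumbered ISCnnnn
    for i, copy in enumerate(copies, 1):
        copy.copy_id = f"pre{i:04d}"

    # -- structure: intercalated clusters, DR matches, composites, context
    structures, copies = resolve_intercalated(copies, lib, rep, cfg)
    mapping = {
        c.copy_id: f"ISC{i:04d}"
        for i, c in enumerate(
            sorted(copies, key=lambda c: (c.replicon_id, c.start)), 1
        )
    }
    for copy in copies:
        if copy.nested_in:
            copy.nested_in = mapping.get(copy.nested_in, copy.nested_in)
        copy.nested_children = [mapping.get(x, x) for x in copy.nested_children]
    for s in structures:
        s.parent_copy = mapping.get(s.parent_copy, s.parent_copy)
        s.inserted = [mapping.get(x, x) for x in s.inserted]
        s.fragments = [mapping.get(x, x) for x in s.fragments]
    for copy in copies:
        copy.copy_id = mapping[copy.copy_id]
    copies.sort(key=lambda c: (c.replicon_id, c.start))
    result.copies = copies
    result.structures = structures
    result.dr_matches = match_drs_across_copies(copies, cfg.dr_match_min,
                                                cfg.dr_max)
    result.composites, result.rearrangement_notes = scan_composite_candidates(
        copies, cfg
    )
    result.contexts = [annotate_context(c, rep, cfg.context_window)
                       for c in copies]
    result.summary = summarize_prediction(all_orfs, copies)
    return result


def _merge_results(results: list[PipelineResult], mode: str) -> PipelineResult:
    merged = PipelineResult(mode=mode, replicons=[])
    for r in results:
        merged.replicons += r.replicons
        merged.orfs += r.orfs
        merged.regions += r.regions
        merged.region_clusters += r.region_clusters
        merged.copies += r.copies
        merged.structures += r.structures
        merged.dr_matches += r.dr_matches
        merged.composites += r.composites
        merged.rearrangement_notes += r.rearrangement_notes
        merged.contexts += r.contexts
    summaries = [r.summary for r in results if r.summary is not None]
    if summaries:
        merged.summary = PredictionSummary(
            total_is_orf=sum(s.total_is_orf for s in summaries),
            complete_orf=sum(s.complete_orf for s in summaries),
            partial_orf=sum(s.partial_orf for s in summaries),
            pseudogene=sum(s.pseudogene for s in summaries),
            unknown_orf=sum(s.unknown_orf for s in summaries),
            total_is=sum(s.total_is for s in summaries),
            different_is=len({c.reference_is for r in results for c in r.copies})
            if mode == "annotate"
            else sum(s.different_is for s in summaries),
        )
    # copy ids must be unique across replicons
    if len(merged.replicons) > 1 and merged.copies:
        remap = {}
        for i, copy in enumerate(
            sorted(merged.copies, key=lambda c: (c.replicon_id, c.start)), 1
        ):
            remap[(copy.replicon_id, copy.copy_id)] = f"ISC{i:04d}"
        for copy in merged.copies:
            key = (copy.replicon_id, copy.copy_id)
            if copy.nested_in:
                copy.nested_in = remap.get((copy.replicon_id, copy.nested_in),
                                           copy.nested_in)
            copy.copy_id = remap[key]
    return merged


def run_pipeline(
    genome_path: str | Path,
    library_path: str | Path,
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    mode: str = "annotate",
) -> PipelineResult:
    """Load inputs, run every stage, and (optionally) write the output bundle:
    summary.json, annotation_table.tsv, copies.gff3, re-annotated GenBank and
    per-IS reports."""
    if mode not in ("predict", "annotate"):
        raise ValueError(f"unknown mode {mode!r}")
    cfg = cfg or PipelineConfig()
    lib = load_reference_library(library_path)
    if not lib.references:
        raise ValueError("reference library is empty")
    replicons = read_replicons(genome_path, "auto")
    results = [analyze_replicon(rep, lib, cfg, mode) for rep in replicons]
    merged = _merge_results(results, mode)
    if out_dir is not None:
        write_output_bundle(merged, Path(out_dir))
    return merged


def write_output_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    if result.summary is not None:
        write_summary_json(result.summary, result.copies, out_dir / "summary.json")
    if result.mode == "predict":
        return
    build_annotation_table(result.copies, out_dir / "annotation_table.tsv")
    export_gff(result.copies, out_dir / "copies.gff3")
    for rep in result.replicons:
        rep_copies = [c for c in result.copies if c.replicon_id == rep.id]
        write_annotated_genbank(rep, rep_copies, out_dir / f"{rep.id}.annotated.gbk")
    reports_dir = out_dir / "reports"
    reports_dir.mkdir(exist_ok=True)
    for name in sorted({c.reference_is for c in result.copies}):
        report = render_is_report(name, result.copies, result.dr_matches)
        (reports_dir / f"{name}.json").write_text(
            json.dumps(report, indent=2) + "\n"
        )
        (reports_dir / f"{name}.txt").write_text(render_is_report_text(report))
    extras = {
        "nested_structures": [
            {
                "parent_copy": s.parent_copy,
                "fragments": s.fragments,
                "inserted": s.inserted,
                "junction_gap": s.junction_gap,
            }
            for s in result.structures
        ],
        "composite_candidates": [
            {
                "copy_a": c.copy_a, "copy_b": c.copy_b,
                "orientation": c.orientation, "span": list(c.span),
                "flanking_dr": c.flanking_dr,
            }
            for c in result.composites
        ],
        "rearrangement_notes": result.rearrangement_notes,
        "contexts": [
            {
                "copy_id": c.copy_id, "left_gene": c.left_gene,
                "right_gene": c.right_gene, "disrupted_gene": c.disrupted_gene,
            }
            for c in result.contexts
        ],
    }
    (out_dir / "structure.json").write_text(json.dumps(extras, indent=2) + "\n")


def apply_validation(
    result: PipelineResult, edited_table: str | Path, out_dir: str | Path
) -> PipelineResult:
    """Re-export after curation: rows marked ``rejected`` in the edited
    annotation table are dropped; other status/comment edits are carried over."""
    from isannot.reporting_export import read_annotation_table

    df = read_annotation_table(edited_table)
    status = {row["copy_id"]: (row["validation_status"], row["comment"])
              for _, row in df.iterrows()}
    kept = []
    for copy in result.copies:
        st, comment = status.get(copy.copy_id, ("pending", copy.comment))
        if st == "rejected":
            logger.info("validation: %s rejected by curator", copy.copy_id)
            continue
        copy.validation_status = st
        copy.comment = comment
        kept.append(copy)
    filtered = PipelineResult(
        mode=result.mode, replicons=result.replicons, orfs=result.orfs,
        regions=result.regions, copies=kept, structures=result.structures,
        dr_matches=match_drs_across_copies(kept),
        summary=summarize_prediction(result.orfs, kept),
    )
    write_output_bundle(filtered, Path(out_dir))
    return filtered
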