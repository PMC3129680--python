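"""Prediction summary, annotation table, per-IS reports and GFF3 export.

The annotation table is the editable deliverable of a run: one row per IS
copy with 1-based inclusive coordinates, a ``validation_status`` column
(``pending`` until a curator accepts or rejects the call) and a free-text
comment field.  Empty optional fields are written as empty strings.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from isannot.nucleotide_stage import ISCopy
from isannot.protein_stage import CandidateOrf
from isannot.structure_context import DrMatch

TABLE_COLUMNS = [
    "is_name", "family", "group", "copy_id", "replicon_id", "start", "end",
    "strand", "identity_nt", "completeness", "orf_status", "irl_seq",
    "irr_seq", "dr_seq", "left_flank_49", "right_flank_49", "interrupted",
    "nested_in", "validation_status", "comment",
]


@dataclass(frozen=True)
class PredictionSummary:
    total_is_orf: int
    complete_orf: int
    partial_orf: int
    pseudogene: int
    unknown_orf: int
    total_is: int
    different_is: int

    def __post_init__(self) -> None:
        parts = (self.complete_orf + self.partial_orf + self.pseudogene
                 + self.unknown_orf)
        if parts != self.total_is_orf:
            raise ValueError(
                f"ORF category counts ({parts}) do not sum to total_is_orf "
                f"({self.total_is_orf})"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "total_is_orf": self.total_is_orf,
            "complete_orf": self.complete_orf,
            "partial_orf": self.partial_orf,
            "pseudogene": self.pseudogene,
            "unknown_orf": self.unknown_orf,
            "total_is": self.total_is,
            "different_is": self.different_is,
        }


def summarize_prediction(
    orfs: list[CandidateOrf], copies: list[ISCopy]
) -> PredictionSummary:
    """Headline counts of a run.

    ``total_is`` counts genomic copies after intercalation resolution, so an
    interrupted element counts once, not per fragment; ``different_is``
    counts distinct reference IS names among the copies.
    """
    counted = [o for o in orfs if o.classification != "none"]
    by = {c: sum(1 for o in counted if o.classification == c)
          for c in ("complete", "partial", "pseudogene", "unknown")}
    return PredictionSummary(
        total_is_orf=len(counted),
        complete_orf=by["complete"],
        partial_orf=by["partial"],
        pseudogene=by["pseudogene"],
        unknown_orf=by["unknown"],
        total_is=len(copies),
        different_is=len({c.reference_is for c in copies}),
    )


def copy_to_row(copy: ISCopy, group: str = "") -> dict:
    return {
        "is_name": copy.reference_is,
        "family": copy.family,
        "group": group,
        "copy_id": copy.copy_id,
        "replicon_id": copy.replicon_id,
        "start": copy.start + 1,  # 1-based inclusive in the emitted file
        "end": copy.end,
        "strand": copy.strand,
        "identity_nt": round(copy.identity_nt, 2),
        "completeness": copy.completeness,
        "orf_status": copy.orf_status,
        "irl_seq": copy.ir.left_seq if copy.ir else "",
        "irr_seq": copy.ir.right_seq if copy.ir else "",
        "dr_seq": copy.dr.seq if copy.dr else "",
        "left_flank_49": copy.left_flank_49,
        "right_flank_49": copy.right_flank_49,
        "interrupted": str(copy.interrupted).lower(),
        "nested_in": copy.nested_in or "",
        "validation_status": copy.validation_status,
        "comment": copy.comment,
    }


def build_annotation_table(copies: list[ISCopy], out: str | Path) -> Path:
    """Write the per-copy annotation table (TSV, losslessly re-readable)."""
    ids = [c.copy_id for c in copies]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate copy_id in annotation table")
    rows = [copy_to_row(c) for c in
            sorted(copies, key=lambda c: (c.replicon_id, c.start, c.end))]
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(out, sep="\t", index=False)
    return out


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _gff_escape(value: str) -> str:
    for char, esc in (("%", "%25"), (";", "%3B"), ("=", "%3D"),
                      ("&", "%26"), (",", "%2C")):
        value = value.replace(char, esc)
    return value


def export_gff(copies: list[ISCopy], out: str | Path) -> Path:
    """GFF3 track: one mobile_genetic_element per copy with inverted_repeat
    children for detected IRs."""
    lines = ["##gff-version 3"]
    for copy in sorted(copies, key=lambda c: (c.replicon_id, c.start, c.end)):
        attrs = {
            "ID": copy.copy_id,
            "Name": copy.reference_is,
            "family": copy.family,
            "completeness": copy.completeness,
            "orf_status": copy.orf_status,
            "identity": f"{copy.identity_nt:.2f}",
        }
        if copy.dr:
            attrs["dr_seq"] = copy.dr.seq
        if copy.interrupted:
            attrs["interrupted"] = "true"
        if copy.nested_in:
            attrs["Parent_element"] = copy.nested_in
        attr_str = ";".join(f"{k}={_gff_escape(v)}" for k, v in attrs.items())
        lines.append(
            "\t".join(
                [copy.replicon_id, "isannot", "mobile_genetic_element",
                 str(copy.start + 1), str(copy.end), ".", copy.strand, ".",
                 attr_str]
            )
        )
        if copy.ir:
            for tag, s, e in (("irl", copy.ir.left_start, copy.ir.left_end),
                              ("irr", copy.ir.right_start, copy.ir.right_end)):
                lines.append(
                    "\t".join(
                        [copy.replicon_id, "isannot", "inverted_repeat",
                         str(s + 1), str(e), ".", copy.strand, ".",
                         f"ID={copy.copy_id}_{tag};Parent={copy.copy_id}"]
                    )
                )
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text("\n".join(lines) + "\n")
    return out


def render_is_report(
    reference_is: str, copies: list[ISCopy], matches: list[DrMatch]
) -> dict:
    """Per-reference report: every genomic copy with its coordinates, 49-bp
    flanks and DR, plus cross-copy DR matches involving those copies."""
    own = [c for c in copies if c.reference_is == reference_is]
    if not own:
        raise ValueError(f"no copies of {reference_is!r}")
    own.sort(key=lambda c: (c.replicon_id, c.start))
    ids = {c.copy_id for c in own}
    own_matches = [m for m in matches if m.copy_a in ids or m.copy_b in ids]
    report = {
        "reference_is": reference_is,
        "family": own[0].family,
        "n_copies": len(own),
        "copies": [
            {
                "copy_id": c.copy_id,
                "replicon_id": c.replicon_id,
                "start": c.start + 1,
                "end": c.end,
                "strand": c.strand,
                "completeness": c.completeness,
                "identity_nt": round(c.identity_nt, 2),
                "left_flank_49": c.left_flank_49,
                "right_flank_49": c.right_flank_49,
                "dr_seq": c.dr.seq if c.dr else "",
            }
            for c in own
        ],
        "dr_matches": [
            {
                "copy_a": m.copy_a, "side_a": m.side_a,
                "copy_b": m.copy_b, "side_b": m.side_b,
                "seq": m.seq, "distance_bp": m.distance_bp,
            }
            for m in own_matches
        ],
    }
    return report


def render_is_report_text(report: dict) -> str:
    lines = [
        f"IS report: {report['reference_is']} (family {report['family']}), "
        f"{report['n_copies']} copies",
        "",
        "copy_id\treplicon\tcoords\tstrand\tcompleteness\tDR",
    ]
    for c in report["copies"]:
        lines.append(
            f"{c['copy_id']}\t{c['replicon_id']}\t{c['start']}..{c['end']}\t"
            f"{c['strand']}\t{c['completeness']}\t{c['dr_seq'] or '-'}"
        )
    lines.append("")
    for c in report["copies"]:
        lines.append(f"{c['copy_id']} left  flank: {c['left_flank_49']}")
        lines.append(f"{c['copy_id']} right flank: {c['right_flank_49']}")
    if report["dr_matches"]:
        lines.append("")
        lines.append("cross-copy DR matches:")
        for m in report["dr_matches"]:
            lines.append(
                f"  {m['copy_a']}.{m['side_a']} == {m['copy_b']}.{m['side_b']}"
                f" ({m['seq']}, {m['distance_bp']} bp apart)"
            )
    return "\n".join(lines) + "\n"


def write_summary_json(
    summary: PredictionSummary, copies: list[ISCopy], out: str | Path
) -> Path:
    data = summary.to_dict()
    data["families"] = sorted({c.family for c in copies})
    data["n_families"] = len(data["families"])
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(data, indent=2) + "\n")
    return out
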