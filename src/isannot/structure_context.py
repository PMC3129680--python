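"""Higher-order IS structure: nested insertions, DR cross-matches, composite
transposon candidates, and genome context of each copy.

Prokaryotic replicons often carry intercalated IS clusters in which one
element is interrupted by the insertion of one or more others.  The naive
copy list then shows the interrupted parent as two (or more) fragments; the
resolver joins fragments of the same reference element when an intact copy
(or chain of copies) tiles the genomic gap between them and their reference
intervals are contiguous up to a small tolerance — the tolerance absorbs the
target site duplication the inner element created inside the parent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from isannot.config import PipelineConfig
from isannot.genome_io import GenomeFeature, Replicon
from isannot.nucleotide_stage import ISCopy, finalize_copy
from isannot.reference_library import ReferenceLibrary
from isannot.util import overlap_len

logger = logging.getLogger("isannot")


@dataclass
class NestedStructure:
    parent_copy: str  # id of the reconstructed (interrupted) element
    fragments: list[str]  # ids of the joined fragments, genome order
    inserted: list[str]  # ids of the copies sitting between the fragments
    junction_gap: int  # bp discrepancy at the reconstructed reference junction


@dataclass(frozen=True)
class DrMatch:
    copy_a: str
    copy_b: str
    side_a: str  # left | right
    side_b: str
    seq: str
    distance_bp: int


@dataclass
class CompositeCandidate:
    copy_a: str
    copy_b: str
    orientation: str  # direct | inverted
    span: tuple[int, int]
    flanking_dr: str | None = None


@dataclass
class ContextReport:
    copy_id: str
    left_gene: str | None
    right_gene: str | None
    disrupted_gene: str | None
    notes: list[str] = field(default_factory=list)


# --- intercalated clusters --------------------------------------------------


def _junction_gap(f1: ISCopy, f2: ISCopy, inner: list[ISCopy]) -> int:
    """Reference-coordinate discrepancy between two genome-ordered fragments.

    Alignment of a fragment can run a few bases into the inserted element
    (e.g. across the duplicated target site); those genome-overlap bases are
    trimmed from the reference intervals before measuring the junction, so
    the reported gap is the insertion's target duplication length, not the
    duplication plus alignment jitter.
    """
    trim1 = trim2 = 0
    if inner:
        trim1 = max(0, f1.end - min(c.start for c in inner))
        trim2 = max(0, max(c.end for c in inner) - f2.start)
    if f1.strand == "+":
        return abs((f2.ref_span[0] + trim2) - (f1.ref_span[1] - trim1))
    return abs((f1.ref_span[0] + trim1) - (f2.ref_span[1] - trim2))


def _tiles_gap(
    inner: list[ISCopy], left_end: int, right_start: int, tol: int
) -> bool:
    if not inner:
        return False
    inner = sorted(inner, key=lambda c: c.start)
    cursor = left_end
    for c in inner:
        if abs(c.start - cursor) > tol:
            return False
        cursor = c.end
    return abs(right_start - cursor) <= tol


def resolve_intercalated(
    copies: list[ISCopy],
    lib: ReferenceLibrary,
    rep: Replicon,
    cfg: PipelineConfig,
) -> tuple[list[NestedStructure], list[ISCopy]]:
    """Resolve intercalated clusters, innermost first.

    Returns the nested structures found and the updated copy list in which
    each resolved parent appears once (spanning all of its fragments and
    children, marked ``interrupted``) and inner copies carry ``nested_in``.
    Chains of inserted elements and nesting up to arbitrary depth are handled
    by iterating until no further join applies.
    """
    copies = [c for c in copies]
    structures: list[NestedStructure] = []
    counter = 0
    while True:
        join = _find_innermost_join(copies, cfg)
        if join is None:
            break
        f1, f2, inner = join
        counter += 1
        parent_id = f"{f1.copy_id}" if f1.interrupted else f"{f1.copy_id}+join{counter}"
        gap = _junction_gap(f1, f2, inner)
        parent = ISCopy(
            copy_id=parent_id,
            replicon_id=f1.replicon_id,
            start=f1.start, end=f2.end, strand=f1.strand,
            reference_is=f1.reference_is, family=f1.family,
            identity_nt=(f1.identity_nt * len(f1) + f2.identity_nt * len(f2))
            / (len(f1) + len(f2)),
            completeness="partial",
            orf_status=("pseudogene" if "pseudogene" in (f1.orf_status, f2.orf_status)
                        else "intact" if "intact" in (f1.orf_status, f2.orf_status)
                        else "absent"),
            ref_span=(min(f1.ref_span[0], f2.ref_span[0]),
                      max(f1.ref_span[1], f2.ref_span[1])),
            ref_covered=min(
                f1.ref_covered + f2.ref_covered,
                max(f1.ref_span[1], f2.ref_span[1])
                - min(f1.ref_span[0], f2.ref_span[0]),
            ),
            orf_spans=sorted(set(f1.orf_spans) | set(f2.orf_spans)),
            interrupted=True,
        )
        finalize_copy(parent, rep, lib, cfg)
        for c in inner:
            c.nested_in = parent.copy_id
        parent.nested_children = [c.copy_id for c in inner]
        structures.append(
            NestedStructure(
                parent_copy=parent.copy_id,
                fragments=[f1.copy_id, f2.copy_id],
                inserted=[c.copy_id for c in inner],
                junction_gap=gap,
            )
        )
        logger.info(
            "intercalated: %s fragments [%d,%d)+[%d,%d) joined over %s "
            "(junction gap %d bp)",
            parent.reference_is, f1.start, f1.end, f2.start, f2.end,
            ",".join(c.copy_id for c in inner), gap,
        )
        copies = [c for c in copies if c.copy_id not in (f1.copy_id, f2.copy_id)]
        copies.append(parent)
        copies.sort(key=lambda c: (c.replicon_id, c.start))
    return structures, copies


def _find_innermost_join(
    copies: list[ISCopy], cfg: PipelineConfig
) -> tuple[ISCopy, ISCopy, list[ISCopy]] | None:
    tol = cfg.nest_tolerance
    candidates = []
    by_key: dict[tuple[str, str, str], list[ISCopy]] = {}
    for c in copies:
        by_key.setdefault((c.replicon_id, c.reference_is, c.strand), []).append(c)
    for key, group in sorted(by_key.items()):
        group = sorted(group, key=lambda c: c.start)
        for i in range(len(group) - 1):
            f1, f2 = group[i], group[i + 1]
            if f1.end >= f2.start:
                continue
            # successive, essentially non-overlapping pieces of the reference
            if f1.strand == "+":
                if f2.ref_span[1] <= f1.ref_span[1]:
                    continue
            elif f1.ref_span[1] <= f2.ref_span[1]:
                continue
            inner = [
                c for c in copies
                if c.replicon_id == f1.replicon_id
                and c.copy_id not in (f1.copy_id, f2.copy_id)
                and c.start >= f1.end - tol and c.end <= f2.start + tol
            ]
            # only top-level fillers tile the gap: a copy nested inside
            # another filler is already accounted for by its host
            inner = [
                c for c in inner
                if not any(
                    o is not c and o.start <= c.start and c.end <= o.end
                    for o in inner
                )
            ]
            if _junction_gap(f1, f2, inner) > tol:
                continue
            if _tiles_gap(inner, f1.end, f2.start, tol):
                candidates.append((f2.end - f1.start, f1, f2, inner))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])  # innermost (smallest outer span) first
    _, f1, f2, inner = candidates[0]
    return f1, f2, inner


# --- DR cross-matching (rearrangement evidence) -----------------------------


def _flank_word(copy: ISCopy, side: str, k: int) -> str:
    if side == "left":
        return copy.left_flank_49[-k:] if len(copy.left_flank_49) >= k else ""
    return copy.right_flank_49[:k] if len(copy.right_flank_49) >= k else ""


def _longest_cross_match(copy_a: ISCopy, copy_b: ISCopy, side_a: str,
                         side_b: str, min_len: int, max_len: int) -> str:
    for k in range(max_len, min_len - 1, -1):
        wa = _flank_word(copy_a, side_a, k)
        wb = _flank_word(copy_b, side_b, k)
        if wa and wa == wb:
            return wa
    return ""


def match_drs_across_copies(
    copies: list[ISCopy], min_len: int = 4, max_len: int = 20
) -> list[DrMatch]:
    """Cross-copy exact matches between one copy's left-flank DR word and
    another copy's right-flank DR word (either pairing) — the signature of an
    IS-mediated rearrangement or of a composite transposon insertion point."""
    matches = []
    for i, a in enumerate(copies):
        for b in copies[i + 1 :]:
            if a.copy_id == b.copy_id:
                continue
            for side_a, side_b in (("left", "right"), ("right", "left")):
                seq = _longest_cross_match(a, b, side_a, side_b, min_len, max_len)
                if seq:
                    matches.append(
                        DrMatch(
                            copy_a=a.copy_id, copy_b=b.copy_id,
                            side_a=side_a, side_b=side_b, seq=seq,
                            distance_bp=max(b.start - a.end, a.start - b.end, 0),
                        )
                    )
    matches.sort(key=lambda m: (m.copy_a, m.copy_b, m.side_a))
    return matches


# --- composite transposon scan ----------------------------------------------


def scan_composite_candidates(
    copies: list[ISCopy], cfg: PipelineConfig
) -> tuple[list[CompositeCandidate], list[str]]:
    """Pairs of same-IS (optionally same-family) copies close enough to act
    as the arms of a composite transposon; pairs beyond the distance cutoff
    are surfaced as rearrangement notes instead."""
    ordered = sorted(copies, key=lambda c: (c.replicon_id, c.start))
    candidates: list[CompositeCandidate] = []
    notes: list[str] = []
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            if a.replicon_id != b.replicon_id:
                break
            same = (a.reference_is == b.reference_is
                    or (cfg.composite_same_family and a.family == b.family))
            if not same:
                continue
            distance = b.start - a.end
            if distance <= cfg.composite_max_distance:
                flanking = _longest_cross_match(a, b, "left", "right",
                                                cfg.dr_match_min, cfg.dr_max)
                candidates.append(
                    CompositeCandidate(
                        copy_a=a.copy_id, copy_b=b.copy_id,
                        orientation="direct" if a.strand == b.strand else "inverted",
                        span=(a.start, b.end),
                        flanking_dr=flanking or None,
                    )
                )
            else:
                shared = _longest_cross_match(a, b, "left", "right",
                                              cfg.dr_match_min, cfg.dr_max)
                shared = shared or _longest_cross_match(
                    b, a, "left", "right", cfg.dr_match_min, cfg.dr_max)
                if shared:
                    notes.append(
                        f"{a.copy_id} and {b.copy_id} share DR evidence "
                        f"({shared}) but lie {distance} bp apart — too far for "
                        "a composite transposon; IS-mediated rearrangement likely"
                    )
    return candidates, notes


# --- genome context ---------------------------------------------------------


def _feature_summary(feat: GenomeFeature) -> str:
    label = feat.qualifiers.get("locus_tag") or feat.qualifiers.get("gene") or ""
    product = feat.qualifiers.get("product", "")
    desc = "; ".join(x for x in (label, product) if x)
    return f"{feat.kind} [{feat.start + 1}..{feat.end}] ({desc})" if desc else (
        f"{feat.kind} [{feat.start + 1}..{feat.end}]"
    )


def annotate_context(
    copy: ISCopy, rep: Replicon, window: int = 5000
) -> ContextReport:
    """Nearest non-IS gene on each side of a copy (within ``window`` bp) and
    any gene the insertion disrupted.  Feature-less replicons give an empty
    report."""
    genes = [f for f in rep.features if f.kind in ("CDS", "gene", "pseudogene")]
    left = right = disrupted = None
    for f in genes:
        if overlap_len((f.start, f.end), copy.span) > 0:
            # a gene the element landed in (ignore the element's own ORFs)
            if not any(overlap_len((f.start, f.end), s) >= 0.8 * (f.end - f.start)
                       for s in copy.orf_spans):
                disrupted = f
            continue
        if f.end <= copy.start and copy.start - f.end <= window:
            if left is None or f.end > left.end:
                left = f
        elif f.start >= copy.end and f.start - copy.end <= window:
            if right is None or f.start < right.start:
                right = f
    return ContextReport(
        copy_id=copy.copy_id,
        left_gene=_feature_summary(left) if left else None,
        right_gene=_feature_summary(right) if right else None,
        disrupted_gene=_feature_summary(disrupted) if disrupted else None,
    )
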