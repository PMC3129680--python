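"""Nucleotide-level definition of genomic IS copies.

Classified ORF groups become candidate regions (ORF span plus a margin so
element ends fall inside the searched window); regions are compared against
the reference nucleotide set, clustered by single-linkage identity, and the
retained hits are projected into genomic element boundaries.  Terminal
inverted repeats (IRs) and target site duplications (DRs) are then located at
the final bounds, and genome regions without any IS-associated ORF are
re-scanned for ORF-less partial copies and MITE-like derivatives.

The builtin nucleotide search is seed-and-extend: exact k-mer seeds chained
on diagonals, verified by local alignment.  At region scale this is
exhaustive in effect; the external backend delegates to blastn with the
configured word size.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import edlib

from isannot.alignment import align_pair
from isannot.config import PipelineConfig
from isannot.genome_io import Replicon
from isannot.protein_stage import CandidateOrf
from isannot.reference_library import ISReference, ReferenceLibrary
from isannot.util import complement_intervals, overlap_len, revcomp

logger = logging.getLogger("isannot")


@dataclass
class CandidateRegion:
    replicon_id: str
    start: int  # core span: min ORF start
    end: int  # core span: max ORF end
    ext_start: int  # extended span (core +/- margin, clipped)
    ext_end: int
    member_orfs: list[CandidateOrf] = field(default_factory=list)
    family: str | None = None
    sequence: str = ""  # core-span nucleotides (used for clustering)
    extended_sequence: str = ""  # extended-span nucleotides (used for search)


@dataclass(frozen=True)
class NucleotideHit:
    subject_is: str
    identity: float  # %
    strand: str
    query_span: tuple[int, int]  # genome coords, half-open
    subject_span: tuple[int, int]  # reference coords, half-open, forward strand
    score: float
    aligned_columns: int


@dataclass
class InvertedRepeatPair:
    left_start: int
    left_end: int
    right_start: int
    right_end: int
    left_seq: str
    right_seq: str
    mismatches: int
    mode: str  # reference_guided | de_novo


@dataclass
class DirectRepeat:
    seq: str
    length: int
    left_span: tuple[int, int]
    right_span: tuple[int, int]


@dataclass
class ISCopy:
    copy_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    reference_is: str
    family: str
    identity_nt: float
    completeness: str  # complete | partial
    orf_status: str  # intact | pseudogene | absent
    ref_span: tuple[int, int] = (0, 0)  # covered reference interval (bounds)
    ref_covered: int = 0  # aligned reference bp (sum over hit segments)
    subject_coverage: float = 0.0
    ir: InvertedRepeatPair | None = None
    dr: DirectRepeat | None = None
    left_flank_49: str = ""
    right_flank_49: str = ""
    orf_spans: list[tuple[int, int]] = field(default_factory=list)
    nested_children: list[str] = field(default_factory=list)
    nested_in: str | None = None
    interrupted: bool = False
    flagged: bool = False  # conflicting family assignment, for manual review
    validation_status: str = "pending"
    comment: str = ""

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def __len__(self) -> int:
        return self.end - self.start


# --- candidate regions ------------------------------------------------------


def extract_candidate_region(
    group: list[CandidateOrf], margin: int, rep: Replicon
) -> CandidateRegion:
    """Region from an ORF group: core span is first-ORF start to last-ORF end;
    the extended span adds ``margin`` bp each side, clipped to the replicon."""
    if not group:
        raise ValueError("empty ORF group")
    if len({o.replicon_id for o in group}) != 1:
        raise ValueError("ORF group spans multiple replicons")
    start = min(o.start for o in group)
    end = max(o.end for o in group)
    ext_start, ext_end = max(0, start - margin), min(len(rep), end + margin)
    fams = [o.family for o in group if o.family]
    return CandidateRegion(
        replicon_id=group[0].replicon_id,
        start=start, end=end, ext_start=ext_start, ext_end=ext_end,
        member_orfs=list(group), family=fams[0] if fams else None,
        sequence=rep.subseq(start, end),
        extended_sequence=rep.subseq(ext_start, ext_end),
    )


# --- builtin seeded nucleotide search --------------------------------------

_NT_K = 11
_NT_BAND = 20
_NT_SEED_GAP = 150


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" not in word:
            index.setdefault(word, []).append(i)
    return index


def nucleotide_local_hits(
    query: str,
    subjects: list[tuple[str, str]],
    min_identity: float,
    min_len: int = 40,
) -> list[NucleotideHit]:
    """Seeded local search of ``query`` against each subject, both strands.

    Returns hits with identity strictly above ``min_identity`` (percent) and
    aligned span >= ``min_len``.  Query spans are in query coordinates; subject
    spans are always on the subject's forward strand.
    """
    hits: list[NucleotideHit] = []
    for name, subject in subjects:
        for strand in "+-":
            sseq = subject if strand == "+" else revcomp(subject)
            index = _kmer_positions(sseq, _NT_K)
            seeds = []
            for i in range(len(query) - _NT_K + 1):
                for j in index.get(query[i : i + _NT_K], ()):
                    seeds.append((i, j))
            if not seeds:
                continue
            for chain in _chain_nt_seeds(seeds):
                hit = _verify_nt_chain(query, sseq, chain, name, strand,
                                       len(subject), min_identity, min_len)
                if hit is not None:
                    hits.append(hit)
    hits = _dedupe_hits(hits)
    hits.sort(key=lambda h: (-h.score, h.subject_is, h.query_span))
    return hits


def _chain_nt_seeds(seeds: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    chains: list[list[tuple[int, int]]] = []
    for q, s in sorted(seeds):
        placed = False
        for chain in chains:
            lq, ls = chain[-1]
            if 0 <= q - lq <= _NT_SEED_GAP and abs((q - s) - (lq - ls)) <= _NT_BAND:
                chain.append((q, s))
                placed = True
                break
        if not placed:
            chains.append([(q, s)])
    return [c for c in chains if (c[-1][0] + _NT_K - c[0][0]) >= 2 * _NT_K]


_ANCHOR = 8  # hit ends are trimmed to runs of this many exact matches


def _trim_to_anchors(
    qseq: str, sseq: str, blocks: tuple, anchor: int = _ANCHOR
) -> tuple[tuple[int, int], tuple[int, int], int, int] | None:
    """Trim alignment ends to the outermost ``anchor``-length exact-match
    runs, so a hit never ends on chance matches straggling past a boundary.
    Returns (query span, subject span, matches, columns) or None."""
    cols: list[tuple[int, int, bool]] = []
    prev = None
    for (qs, qe), (ss, se) in blocks:
        if prev is not None:
            gap_cols = (qs - prev[0]) + (ss - prev[1])
            cols.extend([(-1, -1, False)] * gap_cols)
        for i in range(qe - qs):
            cols.append((qs + i, ss + i, qseq[qs + i] == sseq[ss + i]))
        prev = (qe, se)
    run = 0
    first = last = None
    for i, (_, _, m) in enumerate(cols):
        run = run + 1 if m else 0
        if run >= anchor:
            if first is None:
                first = i - run + 1
            last = i
    if first is None:
        return None
    trimmed = cols[first : last + 1]
    matches = sum(1 for _, _, m in trimmed if m)
    qspan = (trimmed[0][0], trimmed[-1][0] + 1)
    sspan = (trimmed[0][1], trimmed[-1][1] + 1)
    return qspan, sspan, matches, len(trimmed)


def _verify_nt_chain(
    query: str, sseq: str, chain: list[tuple[int, int]], name: str,
    strand: str, subject_len: int, min_identity: float, min_len: int,
) -> NucleotideHit | None:
    pad = 40
    q0 = max(0, chain[0][0] - pad)
    q1 = min(len(query), chain[-1][0] + _NT_K + pad)
    s0 = max(0, min(s for _, s in chain) - pad)
    s1 = min(len(sseq), max(s for _, s in chain) + _NT_K + pad)
    qseq = query[q0:q1]
    sub = sseq[s0:s1]
    res = align_pair(qseq, sub, mode="local", alphabet="nucleotide")
    if res.aligned_columns < min_len:
        return None
    trimmed = _trim_to_anchors(qseq, sub, res.blocks)
    if trimmed is None:
        return None
    (tq, ts, matches, columns) = trimmed
    identity = 100.0 * matches / columns if columns else 0.0
    if columns < min_len or identity <= min_identity:
        return None
    qspan = (q0 + tq[0], q0 + tq[1])
    ss, se = s0 + ts[0], s0 + ts[1]
    if strand == "+":
        sspan = (ss, se)
    else:
        sspan = (subject_len - se, subject_len - ss)
    return NucleotideHit(
        subject_is=name, identity=identity, strand=strand,
        query_span=qspan, subject_span=sspan, score=float(res.score),
        aligned_columns=columns,
    )


def _dedupe_hits(hits: list[NucleotideHit]) -> list[NucleotideHit]:
    """Drop hits whose query span is (near-)contained in a higher-scoring hit
    to the same subject/strand (over-merged seed chains produce duplicates)."""
    kept: list[NucleotideHit] = []
    for h in sorted(hits, key=lambda h: -h.score):
        redundant = False
        for k in kept:
            if (k.subject_is == h.subject_is and k.strand == h.strand
                    and overlap_len(k.query_span, h.query_span)
                    >= 0.8 * (h.query_span[1] - h.query_span[0])):
                redundant = True
                break
        if not redundant:
            kept.append(h)
    return kept


def search_nucleotide_library(
    region: CandidateRegion, lib: ReferenceLibrary, cfg: PipelineConfig
) -> list[NucleotideHit]:
    """Search a candidate region's extended span against the reference
    nucleotide set; hits above the identity cutoff (default >95%) are returned
    in genome coordinates, best-first."""
    if cfg.backend == "external":
        from isannot.blast_backend import blastn_search

        raw = blastn_search(region.extended_sequence, lib, cfg)
    else:
        raw = nucleotide_local_hits(
            region.extended_sequence, lib.nucleotide_entries(),
            cfg.nt_identity, cfg.nt_min_hit_len,
        )
    out = [
        NucleotideHit(
            subject_is=h.subject_is, identity=h.identity, strand=h.strand,
            query_span=(region.ext_start + h.query_span[0],
                        region.ext_start + h.query_span[1]),
            subject_span=h.subject_span, score=h.score,
            aligned_columns=h.aligned_columns,
        )
        for h in raw
        if h.identity > cfg.nt_identity
    ]
    return out


# --- region clustering ------------------------------------------------------


def pairwise_region_identity(a: str, b: str) -> float:
    """Global percent identity between two region sequences (best strand),
    from the edit distance over the longer length."""
    if not a or not b:
        return 0.0
    best = 0.0
    for bb in (b, revcomp(b)):
        dist = edlib.align(a, bb, task="distance", mode="NW")["editDistance"]
        best = max(best, 100.0 * (1.0 - dist / max(len(a), len(bb))))
    return best


def cluster_candidate_regions(
    regions: list[CandidateRegion], threshold: float = 90.0
) -> list[list[CandidateRegion]]:
    """Single-linkage clustering: connected components of the graph with an
    edge wherever pairwise identity >= threshold.  No length-coverage
    requirement is applied."""
    if not regions:
        raise ValueError("no regions to cluster")
    parent = list(range(len(regions)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(len(regions)), 2):
        if pairwise_region_identity(regions[i].sequence, regions[j].sequence) >= threshold:
            parent[find(i)] = find(j)

    groups: dict[int, list[CandidateRegion]] = {}
    for i, region in enumerate(regions):
        groups.setdefault(find(i), []).append(region)
    return [groups[k] for k in sorted(groups, key=lambda k: min(
        regions.index(r) for r in groups[k]))]


# --- IR / DR detection ------------------------------------------------------


def detect_direct_repeat(
    rep: Replicon, start: int, end: int, max_dr: int = 20, min_dr: int = 2
) -> DirectRepeat | None:
    """Longest exact word (min_dr..max_dr bp) duplicated immediately 5' of
    ``start`` and immediately 3' of ``end``.  Searches shrink at replicon
    edges instead of failing."""
    seq = rep.sequence
    limit = min(max_dr, start, len(seq) - end)
    for k in range(limit, min_dr - 1, -1):
        if seq[start - k : start] == seq[end : end + k]:
            return DirectRepeat(
                seq=seq[start - k : start], length=k,
                left_span=(start - k, start), right_span=(end, end + k),
            )
    return None


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def _best_ungapped_placement(pattern: str, window: str) -> tuple[int, int]:
    """(offset, mismatches) of the best ungapped placement of pattern in
    window; leftmost wins ties."""
    best = (0, len(pattern) + 1)
    for off in range(0, len(window) - len(pattern) + 1):
        mm = _hamming(pattern, window[off : off + len(pattern)])
        if mm < best[1]:
            best = (off, mm)
    return best


def detect_inverted_repeats(
    rep: Replicon,
    start: int,
    end: int,
    ref: ISReference | None = None,
    window: int = 50,
    min_ir: int = 10,
    max_mismatch_frac: float = 0.3,
) -> InvertedRepeatPair | None:
    """Locate terminal IRs of an element at [start, end).

    Reference-guided mode places the reference element's IRs in the terminal
    windows (ungapped, best placement); de novo mode scans the left window
    against the reverse complement of the right window for the best ungapped
    complementary segment.  Either way the reported pair satisfies
    "right equals reverse complement of left up to `mismatches` mismatches".
    """
    w = min(window, max(1, (end - start) // 2))
    left = rep.subseq(start, start + w)
    right = rep.subseq(end - w, end)
    if ref is not None and ref.ir_left and ref.ir_right:
        pair = _reference_guided_ir(left, right, start, end, w, ref,
                                    max_mismatch_frac)
        if pair is not None:
            return pair
    return _de_novo_ir(left, right, start, end, w, min_ir, max_mismatch_frac)


def _reference_guided_ir(
    left: str, right: str, start: int, end: int, w: int,
    ref: ISReference, max_mismatch_frac: float,
) -> InvertedRepeatPair | None:
    irl, irr = ref.ir_left.upper(), ref.ir_right.upper()
    if len(irl) > len(left) or len(irr) > len(right):
        return None
    off_l, mm_l = _best_ungapped_placement(irl, left)
    # best placement of ir_right, rightmost wins ties
    best = (0, len(irr) + 1)
    for off in range(len(right) - len(irr), -1, -1):
        mm = _hamming(irr, right[off : off + len(irr)])
        if mm < best[1]:
            best = (off, mm)
    off_r, mm_r = best
    if (mm_l > max_mismatch_frac * len(irl)) or (mm_r > max_mismatch_frac * len(irr)):
        return None
    left_seq = left[off_l : off_l + len(irl)]
    right_seq = right[off_r : off_r + len(irr)]
    n = min(len(left_seq), len(right_seq))
    mismatches = _hamming(left_seq[:n], revcomp(right_seq)[:n]) + abs(
        len(left_seq) - len(right_seq)
    )
    return InvertedRepeatPair(
        left_start=start + off_l, left_end=start + off_l + len(irl),
        right_start=end - w + off_r, right_end=end - w + off_r + len(irr),
        left_seq=left_seq, right_seq=right_seq,
        mismatches=mismatches, mode="reference_guided",
    )


def _de_novo_ir(
    left: str, right: str, start: int, end: int, w: int,
    min_ir: int, max_mismatch_frac: float,
) -> InvertedRepeatPair | None:
    target = revcomp(right)  # position j here = genome position end-1-j
    best = None  # (score, length, left_off, target_off)
    for diag in range(-(len(target) - min_ir), len(left) - min_ir + 1):
        i0 = max(0, diag)
        j0 = i0 - diag
        span = min(len(left) - i0, len(target) - j0)
        if span < min_ir:
            continue
        # best window on this diagonal: evaluate all [a, b) windows >= min_ir
        mask = [left[i0 + t] == target[j0 + t] for t in range(span)]
        prefix = [0]
        for m in mask:
            prefix.append(prefix[-1] + (1 if m else 0))
        for a in range(0, span - min_ir + 1):
            for b in range(a + min_ir, span + 1):
                length = b - a
                matches = prefix[b] - prefix[a]
                mm = length - matches
                if mm > max_mismatch_frac * length:
                    continue
                score = matches - 2 * mm
                key = (score, length, -(i0 + a))
                if best is None or key > best[0]:
                    best = (key, (i0 + a, i0 + b, j0 + a, j0 + b, mm))
    if best is None:
        return None
    la, lb, ta, tb, mm = best[1]
    left_seq = left[la:lb]
    # target positions map back to the right window reversed
    right_genome_start = end - tb
    right_genome_end = end - ta
    right_seq = right[right_genome_start - (end - w) : right_genome_end - (end - w)]
    return InvertedRepeatPair(
        left_start=start + la, left_end=start + lb,
        right_start=right_genome_start, right_end=right_genome_end,
        left_seq=left_seq, right_seq=right_seq,
        mismatches=mm, mode="de_novo",
    )


# --- copy assembly ----------------------------------------------------------


def _merge_colinear_hits(
    hits: list[NucleotideHit], merge_gap: int
) -> list[list[NucleotideHit]]:
    """Group same-subject/strand hits that are adjacent on the genome and
    colinear on the reference (an internal deletion, e.g. a MITE, appears as
    two such hits)."""
    groups: list[list[NucleotideHit]] = []
    for h in sorted(hits, key=lambda h: h.query_span):
        placed = False
        for g in groups:
            last = g[-1]
            gap = h.query_span[0] - last.query_span[1]
            if gap > merge_gap or gap < -merge_gap:
                continue
            if h.strand == "+":
                colinear = h.subject_span[0] >= last.subject_span[1] - merge_gap
            else:
                colinear = h.subject_span[1] <= last.subject_span[0] + merge_gap
            if colinear:
                g.append(h)
                placed = True
                break
        if not placed:
            groups.append([h])
    return groups


def _orf_status(member_orfs: list[CandidateOrf]) -> str:
    if not member_orfs:
        return "absent"
    if any(o.classification == "pseudogene" for o in member_orfs):
        return "pseudogene"
    return "intact"


def finalize_copy(
    copy: ISCopy, rep: Replicon, lib: ReferenceLibrary, cfg: PipelineConfig
) -> ISCopy:
    """(Re)compute IRs, the DR and the 49-bp flanks at the copy's final bounds."""
    ref = lib[copy.reference_is] if copy.reference_is in lib else None
    copy.ir = detect_inverted_repeats(
        rep, copy.start, copy.end, ref=ref, window=cfg.ir_window,
        min_ir=cfg.ir_min, max_mismatch_frac=cfg.ir_max_mismatch_frac,
    )
    copy.dr = detect_direct_repeat(rep, copy.start, copy.end,
                                   max_dr=cfg.dr_max, min_dr=cfg.dr_min)
    copy.left_flank_49 = rep.subseq(copy.start - cfg.flank_len, copy.start)
    copy.right_flank_49 = rep.subseq(copy.end, copy.end + cfg.flank_len)
    if ref is not None:
        covered = copy.ref_covered or (copy.ref_span[1] - copy.ref_span[0])
        copy.subject_coverage = min(1.0, covered / len(ref))
        copy.completeness = (
            "complete"
            if copy.subject_coverage >= cfg.copy_complete_cov
            and copy.identity_nt > cfg.nt_identity
            else "partial"
        )
    return copy


def assemble_is_copy(
    region: CandidateRegion,
    hits: list[NucleotideHit],
    rep: Replicon,
    lib: ReferenceLibrary,
    cfg: PipelineConfig,
) -> list[ISCopy]:
    """Turn a region's nucleotide hits into IS copies.

    The best subject wins; a contradictory overlapping assignment to a
    different family within 10% of the best score is also reported, flagged
    for manual validation.  Boundaries are the genome projection of the
    aligned subject ends; completeness requires subject coverage >=
    ``copy_complete_cov`` at identity above the nucleotide cutoff.
    """
    if not hits:
        return []
    candidates = []
    by_subject: dict[tuple[str, str], list[NucleotideHit]] = {}
    for h in hits:
        by_subject.setdefault((h.subject_is, h.strand), []).append(h)
    for (subject, strand), shits in sorted(by_subject.items()):
        for group in _merge_colinear_hits(shits, cfg.copy_merge_gap):
            start = min(h.query_span[0] for h in group)
            end = max(h.query_span[1] for h in group)
            ref_lo = min(h.subject_span[0] for h in group)
            ref_hi = max(h.subject_span[1] for h in group)
            ref_covered = sum(h.subject_span[1] - h.subject_span[0]
                              for h in group)
            total = sum(h.aligned_columns for h in group)
            identity = sum(h.identity * h.aligned_columns for h in group) / total
            score = sum(h.score for h in group)
            candidates.append(
                (score, subject, strand, start, end, (ref_lo, ref_hi),
                 identity, ref_covered)
            )
    candidates.sort(key=lambda c: (-c[0], c[1]))
    # accept every candidate whose genome span is essentially free of an
    # already-accepted, better one; near-tie overlaps from a different family
    # are contradictory assignments, reported but flagged for validation
    chosen: list[tuple[tuple, bool]] = []
    for cand in candidates:
        span = (cand[3], cand[4])
        conflict = None
        for acc, _ in chosen:
            if overlap_len(span, (acc[3], acc[4])) >= 0.5 * (span[1] - span[0]):
                conflict = acc
                break
        if conflict is None:
            chosen.append((cand, False))
        elif (lib[cand[1]].family != lib[conflict[1]].family
              and cand[0] >= 0.9 * conflict[0]):
            chosen.append((cand, True))

    copies = []
    for (score, subject, strand, start, end, ref_span, identity,
         ref_covered), flagged in chosen:
        members = [
            o for o in region.member_orfs if overlap_len(o.span, (start, end)) > 0
        ]
        copy = ISCopy(
            copy_id=f"tmp:{region.replicon_id}:{start}-{end}:{subject}",
            replicon_id=region.replicon_id, start=start, end=end, strand=strand,
            reference_is=subject, family=lib[subject].family,
            identity_nt=identity, completeness="partial",
            orf_status=_orf_status(members), ref_span=ref_span,
            ref_covered=ref_covered,
            orf_spans=[o.span for o in members], flagged=flagged,
            comment="conflicting family assignment" if flagged else "",
        )
        copies.append(finalize_copy(copy, rep, lib, cfg))
        logger.info(
            "assemble: %s [%d,%d) %s -> %s (%s, id %.1f%%)%s",
            region.replicon_id, start, end, strand, subject,
            copy.completeness, identity, " FLAGGED" if flagged else "",
        )
    return copies


def find_orfless_partials(
    rep: Replicon,
    lib: ReferenceLibrary,
    covered: list[tuple[int, int]],
    cfg: PipelineConfig,
) -> list[ISCopy]:
    """Nucleotide scan of genome regions without IS-associated ORFs.

    Matches become ORF-less copies: partial fragments and MITE-like
    derivatives (complete when a short reference is matched end to end).
    """
    copies: list[ISCopy] = []
    subjects = lib.nucleotide_entries()
    for iv_start, iv_end in complement_intervals(
        covered, len(rep), pad=20, min_len=max(30, cfg.nt_min_hit_len)
    ):
        segment = rep.subseq(iv_start, iv_end)
        raw = nucleotide_local_hits(segment, subjects, cfg.nt_identity,
                                    cfg.nt_min_hit_len)
        by_subject: dict[tuple[str, str], list[NucleotideHit]] = {}
        for h in raw:
            if h.identity <= cfg.nt_identity:
                continue
            shifted = NucleotideHit(
                subject_is=h.subject_is, identity=h.identity, strand=h.strand,
                query_span=(iv_start + h.query_span[0], iv_start + h.query_span[1]),
                subject_span=h.subject_span, score=h.score,
                aligned_columns=h.aligned_columns,
            )
            by_subject.setdefault((h.subject_is, h.strand), []).append(shifted)
        for (subject, strand), shits in sorted(by_subject.items()):
            for group in _merge_colinear_hits(shits, cfg.copy_merge_gap):
                start = min(h.query_span[0] for h in group)
                end = max(h.query_span[1] for h in group)
                ref_lo = min(h.subject_span[0] for h in group)
                ref_hi = max(h.subject_span[1] for h in group)
                total = sum(h.aligned_columns for h in group)
                identity = sum(h.identity * h.aligned_columns for h in group) / total
                copy = ISCopy(
                    copy_id=f"tmp:{rep.id}:{start}-{end}:{subject}",
                    replicon_id=rep.id, start=start, end=end, strand=strand,
                    reference_is=subject, family=lib[subject].family,
                    identity_nt=identity, completeness="partial",
                    orf_status="absent", ref_span=(ref_lo, ref_hi),
                    ref_covered=sum(h.subject_span[1] - h.subject_span[0]
                                    for h in group),
                )
                copies.append(finalize_copy(copy, rep, lib, cfg))
                logger.info(
                    "orfless: %s [%d,%d) %s -> %s fragment (ref %d..%d)",
                    rep.id, start, end, strand, subject, ref_lo, ref_hi,
                )
    return copies


def merge_adjacent_copies(
    copies: list[ISCopy], rep: Replicon, lib: ReferenceLibrary, cfg: PipelineConfig
) -> list[ISCopy]:
    """Merge same-subject copies that abut or overlap on the genome with
    colinear reference intervals (fragments clipped at region margins join
    their ORF-less remainders here)."""
    merged: list[ISCopy] = []
    for copy in sorted(copies, key=lambda c: (c.replicon_id, c.reference_is,
                                              c.strand, c.start)):
        target = None
        for m in merged:
            if (m.replicon_id, m.reference_is, m.strand) != (
                    copy.replicon_id, copy.reference_is, copy.strand):
                continue
            gap = copy.start - m.end
            if gap > cfg.copy_merge_gap:
                continue
            # distinct tandem copies cover the same reference interval twice;
            # genuine fragments of one copy cover near-disjoint intervals
            ref_ov = overlap_len(m.ref_span, copy.ref_span)
            if ref_ov > 3 * cfg.copy_merge_gap:
                continue
            if overlap_len(m.span, copy.span) > 0 or abs(gap) <= cfg.copy_merge_gap:
                target = m
                break
        if target is None:
            merged.append(copy)
        else:
            w1 = len(target)
            w2 = len(copy)
            target.identity_nt = (
                target.identity_nt * w1 + copy.identity_nt * w2
            ) / (w1 + w2)
            target.start = min(target.start, copy.start)
            target.end = max(target.end, copy.end)
            target.ref_span = (
                min(target.ref_span[0], copy.ref_span[0]),
                max(target.ref_span[1], copy.ref_span[1]),
            )
            target.ref_covered = min(
                target.ref_covered + copy.ref_covered,
                target.ref_span[1] - target.ref_span[0],
            )
            target.orf_spans = sorted(set(target.orf_spans) | set(copy.orf_spans))
            if copy.orf_status != "absent" and target.orf_status == "absent":
                target.orf_status = copy.orf_status
            elif copy.orf_status == "pseudogene":
                target.orf_status = "pseudogene"
    return [finalize_copy(c, rep, lib, cfg) for c in merged]


def dedupe_copies(copies: list[ISCopy], cfg: PipelineConfig) -> list[ISCopy]:
    """Remove copies overlapping an accepted copy by >= 50%, keeping the
    higher-identity (then longer) assignment; contradictory families stay,
    flagged for validation."""
    kept: list[ISCopy] = []
    for copy in sorted(copies, key=lambda c: (-c.identity_nt * len(c), c.start)):
        drop = False
        for k in kept:
            if k.replicon_id != copy.replicon_id:
                continue
            ov = overlap_len(k.span, copy.span)
            if ov >= 0.5 * min(len(k), len(copy)):
                if k.family == copy.family:
                    drop = True
                else:
                    copy.flagged = True
                    copy.comment = copy.comment or "conflicting family assignment"
                break
        if not drop:
            kept.append(copy)
    kept.sort(key=lambda c: (c.replicon_id, c.start, c.end))
    return kept
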