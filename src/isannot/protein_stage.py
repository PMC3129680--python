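"""Protein-level discovery and classification of IS-associated ORFs.

Candidate coding regions come from three sources: the input annotation, a de
novo ORF enumerator (genetic code 11, starts ATG/GTG/TTG), and a six-frame
translated search of genome regions not already covered by candidates.  Each
candidate is searched against the reference protein set and routed through a
decision tree combining local and global alignment:

* no significant hit                          -> none (not IS-associated)
* internal stop / frameshift signature        -> pseudogene
* global subject coverage >= complete_cov and
  query length within len_tol of the subject  -> complete
* only accessory-domain-level evidence        -> unknown (kept for review)
* otherwise                                   -> partial

An ORF is attributed to its best subject's family; it is flagged as the same
IS only above the similarity cutoff (default 97% aa similarity), otherwise it
is a putative new IS of that family (or a putative new family when no hit
reaches family level at all).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from isannot.alignment import align_pair  # noqa: F401  (stage-level surface)
from isannot.config import PipelineConfig
from isannot.genome_io import Replicon, conceptual_translation
from isannot.reference_library import ReferenceLibrary
from isannot.util import revcomp

logger = logging.getLogger("isannot")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

CLASSIFICATIONS = ("complete", "partial", "pseudogene", "unknown", "none")


@dataclass(frozen=True)
class ProteinHit:
    subject_is: str
    subject_orf: str
    family: str
    role: str
    identity: float  # % aa identity
    similarity: float  # % positive-scoring aligned positions
    subject_coverage: float
    query_coverage: float
    evalue: float
    score: float
    aln_query_span: tuple[int, int]
    aln_subject_span: tuple[int, int]


@dataclass
class CandidateOrf:
    replicon_id: str
    start: int
    end: int
    strand: str
    protein: str
    source: str  # annotation | called | translated_search
    pseudo_flag: bool = False
    hits: list[ProteinHit] = field(default_factory=list)
    classification: str = "none"
    family: str | None = None
    nearest_is: str | None = None
    same_is: bool = False
    new_is_flag: str | None = None  # "putative new IS" / "putative new family"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def has_internal_stop(self) -> bool:
        return "*" in self.protein.rstrip("*")


def call_orfs(rep: Replicon, min_len_nt: int = 150) -> list[CandidateOrf]:
    """Enumerate ORFs on both strands (stop-to-stop, first ATG/GTG/TTG start).

    The ORF span includes the stop codon; the protein does not.  Coordinates
    are the forward-strand projection.  This plain enumerator plus the
    homology filter downstream stands in for a trained gene caller.
    """
    n = len(rep)
    out = []
    for strand in "+-":
        seq = rep.sequence if strand == "+" else revcomp(rep.sequence)
        for frame in range(3):
            start_codon: int | None = None
            for pos in range(frame, n - 2, 3):
                codon = seq[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start_codon is not None and pos + 3 - start_codon >= min_len_nt:
                        out.append(
                            _orf_from_strand_coords(
                                rep, strand, start_codon, pos + 3, seq
                            )
                        )
                    start_codon = None
                elif start_codon is None and codon in START_CODONS:
                    start_codon = pos
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def _orf_from_strand_coords(
    rep: Replicon, strand: str, s: int, e: int, strand_seq: str
) -> CandidateOrf:
    n = len(rep)
    if strand == "+":
        start, end = s, e
    else:
        start, end = n - e, n - s
    protein = str(
        conceptual_translation(rep, start, end, strand)
    )
    if protein:
        protein = "M" + protein[1:]  # initiator residue
    return CandidateOrf(
        replicon_id=rep.id, start=start, end=end, strand=strand,
        protein=protein, source="called",
    )


def _builtin_protein_hits(
    protein: str, lib: ReferenceLibrary, cfg: PipelineConfig
) -> list[ProteinHit]:
    hits = []
    query = protein.rstrip("*")
    for is_name, orf_id, role, family, subject in lib.proteins():
        res = align_pair(query, subject, mode="local", alphabet="protein")
        if res.evalue <= cfg.protein_evalue:
            hits.append(
                ProteinHit(
                    subject_is=is_name, subject_orf=orf_id, family=family,
                    role=role, identity=res.identity, similarity=res.similarity,
                    subject_coverage=res.subject_coverage,
                    query_coverage=res.query_coverage,
                    evalue=res.evalue, score=res.score,
                    aln_query_span=res.query_span,
                    aln_subject_span=res.subject_span,
                )
            )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_is, h.subject_orf))
    return hits


def search_protein_library(
    orf: CandidateOrf, lib: ReferenceLibrary, cfg: PipelineConfig
) -> list[ProteinHit]:
    """Local search of one candidate protein against the library protein set.

    Hits passing the significance cutoff are returned best-first (ties broken
    by subject name, so results are deterministic).  Low-complexity masking is
    never applied.  With the external backend this shells out to blastp with
    the configured word size and e-value.
    """
    if not lib.references:
        raise ValueError("empty reference library")
    if not orf.protein.rstrip("*"):
        return []
    if cfg.backend == "external":
        from isannot.blast_backend import blastp_search

        return blastp_search(orf.protein, lib, cfg)
    return _builtin_protein_hits(orf.protein, lib, cfg)


# --- six-frame translated search -------------------------------------------

_SEED_K = 4  # aa seed word length
_SEED_BAND = 8  # max diagonal drift within a chain (aa)
_SEED_GAP = 60  # max along-query gap between chained seeds (aa)


def _protein_seed_index(lib: ReferenceLibrary) -> dict[str, list[tuple[int, int]]]:
    index: dict[str, list[tuple[int, int]]] = {}
    for subj_idx, (_, _, _, _, protein) in enumerate(lib.proteins()):
        for i in range(len(protein) - _SEED_K + 1):
            index.setdefault(protein[i : i + _SEED_K], []).append((subj_idx, i))
    return index


def _chain_seeds(
    seeds: list[tuple[int, int]], band: int, max_gap: int
) -> list[list[tuple[int, int]]]:
    """Greedy single-pass chaining of (qpos, spos) seeds by diagonal."""
    chains: list[list[tuple[int, int]]] = []
    for q, s in sorted(seeds):
        placed = False
        for chain in chains:
            lq, ls = chain[-1]
            if 0 <= q - lq <= max_gap and abs((q - s) - (lq - ls)) <= band:
                chain.append((q, s))
                placed = True
                break
        if not placed:
            chains.append([(q, s)])
    return chains


def translated_genome_search(
    rep: Replicon,
    lib: ReferenceLibrary,
    exclude: list[tuple[int, int]],
    cfg: PipelineConfig,
) -> list[CandidateOrf]:
    """Six-frame translated comparison of uncovered genome regions.

    Seeded (exact 4-mer words, chained on diagonals) and verified by local
    protein alignment, so only regions with genuine similarity are aligned.
    Hits to the same subject that overlap in genome space across frames are
    merged into one candidate with the frameshift/pseudogene flag set.
    """
    n = len(rep)
    proteins = lib.proteins()
    index = _protein_seed_index(lib)
    covered = [False] * n
    for s, e in exclude:
        for i in range(max(0, s), min(n, e)):
            covered[i] = True

    raw_hits: list[dict] = []
    for strand in "+-":
        seq = rep.sequence if strand == "+" else revcomp(rep.sequence)
        for frame in range(3):
            usable = (n - frame) // 3 * 3
            if usable < _SEED_K * 3:
                continue
            from Bio.Seq import Seq

            trans = str(Seq(seq[frame : frame + usable]).translate(table=11))
            per_subject: dict[int, list[tuple[int, int]]] = {}
            for i in range(len(trans) - _SEED_K + 1):
                gpos = _frame_to_genome(strand, frame, i, n)[0]
                if covered[min(max(gpos, 0), n - 1)]:
                    continue
                for subj_idx, spos in index.get(trans[i : i + _SEED_K], ()):
                    per_subject.setdefault(subj_idx, []).append((i, spos))
            for subj_idx, seeds in per_subject.items():
                subject = proteins[subj_idx][4]
                for chain in _chain_seeds(seeds, _SEED_BAND, _SEED_GAP):
                    if len(chain) < 2:
                        continue
                    q0 = max(0, chain[0][0] - 15)
                    q1 = min(len(trans), chain[-1][0] + _SEED_K + 15)
                    window = trans[q0:q1]
                    if "*" in window:
                        # restrict to the stop-free stretch holding the chain
                        continue_flag = False
                        parts = _split_on_stops(window, q0)
                        for ps, pe in parts:
                            sub = [c for c in chain if ps <= c[0] < pe]
                            if len(sub) >= 2:
                                raw_hits.extend(
                                    _verify_chain(
                                        trans, ps, pe, subject, subj_idx,
                                        proteins, strand, frame, n, cfg,
                                    )
                                )
                                continue_flag = True
                        if continue_flag:
                            continue
                    raw_hits.extend(
                        _verify_chain(
                            trans, q0, q1, subject, subj_idx, proteins,
                            strand, frame, n, cfg,
                        )
                    )
    return _merge_translated_hits(rep, raw_hits, cfg)


def _split_on_stops(window: str, offset: int) -> list[tuple[int, int]]:
    parts = []
    start = 0
    for i, c in enumerate(window + "*"):
        if c == "*":
            if i - start >= _SEED_K:
                parts.append((offset + start, offset + i))
            start = i + 1
    return parts


def _frame_to_genome(strand: str, frame: int, aa_pos: int, n: int) -> tuple[int, int]:
    """Genome span (half-open) of one translated residue."""
    s = frame + 3 * aa_pos
    if strand == "+":
        return (s, s + 3)
    return (n - s - 3, n - s)


def _verify_chain(
    trans: str, q0: int, q1: int, subject: str, subj_idx: int,
    proteins, strand: str, frame: int, n: int, cfg: PipelineConfig,
) -> list[dict]:
    window = trans[q0:q1]
    if len(window) < _SEED_K:
        return []
    res = align_pair(window, subject, mode="local", alphabet="protein")
    if res.evalue > cfg.protein_evalue or res.aligned_columns < 15:
        return []
    qa0, qa1 = q0 + res.query_span[0], q0 + res.query_span[1]
    g0 = _frame_to_genome(strand, frame, qa0, n)
    g1 = _frame_to_genome(strand, frame, qa1 - 1, n)
    gstart, gend = min(g0[0], g1[0]), max(g0[1], g1[1])
    is_name, orf_id, role, family, _ = proteins[subj_idx]
    hit = ProteinHit(
        subject_is=is_name, subject_orf=orf_id, family=family, role=role,
        identity=res.identity, similarity=res.similarity,
        subject_coverage=res.subject_coverage,
        query_coverage=res.query_coverage, evalue=res.evalue, score=res.score,
        aln_query_span=(qa0, qa1), aln_subject_span=res.subject_span,
    )
    return [
        {
            "start": gstart, "end": gend, "strand": strand, "frame": frame,
            "protein": trans[qa0:qa1], "hit": hit,
            # merge per subject ORF: two genes of one element are separate
            # candidates, while split pieces of one gene are one pseudogene
            "subject": (is_name, orf_id),
        }
    ]


def _merge_translated_hits(
    rep: Replicon, raw_hits: list[dict], cfg: PipelineConfig
) -> list[CandidateOrf]:
    """Merge co-located same-subject hits into candidates.

    Overlapping or near-adjacent hits to one subject on one strand become one
    candidate; a frame change (frameshift) or a stop-split same-frame pair
    marks it as a pseudogene candidate.
    """
    out: list[CandidateOrf] = []
    bystrand: dict[tuple[str, str], list[dict]] = {}
    for h in raw_hits:
        bystrand.setdefault((h["subject"], h["strand"]), []).append(h)
    for (_, strand), hits in sorted(bystrand.items()):
        # drop hits (near-)contained in a better hit to the same subject
        hits.sort(key=lambda h: -h["hit"].score)
        kept: list[dict] = []
        for h in hits:
            span, n = (h["start"], h["end"]), h["end"] - h["start"]
            if not any(
                min(span[1], k["end"]) - max(span[0], k["start"]) >= 0.8 * n
                for k in kept
            ):
                kept.append(h)
        kept.sort(key=lambda h: (h["start"], h["end"]))
        group = [kept[0]]
        for h in kept[1:]:
            if h["start"] - max(g["end"] for g in group) <= 45:
                group.append(h)
            else:
                out.append(_group_to_candidate(rep, group, strand))
                group = [h]
        out.append(_group_to_candidate(rep, group, strand))
    # one candidate per locus: a weaker same-locus match to a related subject
    # is a shadow of the best one, not an independent ORF
    out.sort(key=lambda o: (-o.hits[0].score, o.start))
    accepted: list[CandidateOrf] = []
    for cand in out:
        n = cand.end - cand.start
        if not any(
            min(cand.end, a.end) - max(cand.start, a.start) >= 0.8 * min(n, a.end - a.start)
            for a in accepted
            if a.strand == cand.strand
        ):
            accepted.append(cand)
    accepted.sort(key=lambda o: (o.start, o.end))
    return accepted


def _group_to_candidate(rep: Replicon, group: list[dict], strand: str) -> CandidateOrf:
    start = min(h["start"] for h in group)
    end = max(h["end"] for h in group)
    frames = {h["frame"] for h in group}
    pseudo = len(group) > 1  # frameshift or internal-stop split
    ordered = sorted(group, key=lambda h: h["start"], reverse=(strand == "-"))
    protein = "".join(h["protein"] for h in ordered)
    hits = sorted(
        (h["hit"] for h in group),
        key=lambda h: (h.evalue, -h.score, h.subject_is, h.subject_orf),
    )
    logger.info(
        "translated_search: %s [%d,%d) %s -> %s%s", rep.id, start, end, strand,
        hits[0].subject_is, " (frameshift/stop merge)" if pseudo else "",
    )
    return CandidateOrf(
        replicon_id=rep.id, start=start, end=end, strand=strand,
        protein=protein, source="translated_search", pseudo_flag=pseudo,
        hits=hits,
    )


# --- classification ---------------------------------------------------------


def classify_orf(
    orf: CandidateOrf, lib: ReferenceLibrary, cfg: PipelineConfig
) -> CandidateOrf:
    """Apply the complete/partial/pseudogene/unknown decision tree (see module
    docstring).  Requires hits from search_protein_library on ``orf.hits``."""
    if not orf.hits:
        orf.classification = "none"
        logger.info("classify: %s [%d,%d) no passing hit -> none",
                    orf.replicon_id, orf.start, orf.end)
        return orf
    best = orf.hits[0]
    orf.family = best.family
    orf.nearest_is = best.subject_is
    orf.same_is = best.similarity > cfg.same_is_similarity
    if not orf.same_is:
        family_level = any(h.family == best.family for h in orf.hits)
        orf.new_is_flag = "putative new IS" if family_level else "putative new family"

    subject = _subject_protein(lib, best)
    rule = ""
    if orf.pseudo_flag or orf.has_internal_stop:
        orf.classification = "pseudogene"
        rule = "internal stop or frameshift"
    else:
        res = align_pair(orf.protein.rstrip("*"), subject, mode="global",
                         alphabet="protein")
        qlen, slen = len(orf.protein.rstrip("*")), len(subject)
        if (res.subject_coverage >= cfg.complete_cov
                and abs(qlen - slen) <= cfg.len_tol * slen):
            orf.classification = "complete"
            rule = f"global subject coverage {res.subject_coverage:.2f}"
        elif _accessory_only(orf, cfg):
            orf.classification = "unknown"
            rule = "accessory-domain evidence only"
        else:
            orf.classification = "partial"
            rule = f"global subject coverage {res.subject_coverage:.2f} < {cfg.complete_cov}"
    logger.info(
        "classify: %s [%d,%d) best=%s/%s sim=%.1f -> %s (%s)",
        orf.replicon_id, orf.start, orf.end, best.subject_is, best.subject_orf,
        best.similarity, orf.classification, rule,
    )
    return orf


def _subject_protein(lib: ReferenceLibrary, hit: ProteinHit) -> str:
    ref = lib[hit.subject_is]
    for o in ref.orfs:
        if o.orf_id == hit.subject_orf:
            return o.protein
    raise KeyError(f"{hit.subject_is}/{hit.subject_orf} not in library")


def _accessory_only(orf: CandidateOrf, cfg: PipelineConfig) -> bool:
    """True when every significant hit is to an accessory/passenger subject
    (or a configured accessory confounder such as an IstB-like ATPase)."""
    for h in orf.hits:
        tag = f"{h.subject_is}_{h.subject_orf}"
        if h.role == "transposase" and tag not in cfg.accessory_subjects:
            return False
    return True


def group_candidate_orfs(
    orfs: list[CandidateOrf], cfg: PipelineConfig
) -> list[list[CandidateOrf]]:
    """Group classified IS-associated ORFs into element candidates.

    Same-strand ORFs attributed to the same reference IS within
    ``group_max_gap`` bp form one group (multi-ORF elements, programmed
    frameshifts); overlapping different-frame ORFs hitting the same subject
    fall into the same group by the distance rule.
    """
    keep = [o for o in orfs if o.classification != "none"]
    keep.sort(key=lambda o: (o.replicon_id, o.start, o.end))
    groups: list[list[CandidateOrf]] = []
    for orf in keep:
        target = None
        for group in groups:
            last = group[-1]
            if (last.replicon_id == orf.replicon_id
                    and last.strand == orf.strand
                    and last.nearest_is == orf.nearest_is
                    and orf.start - max(m.end for m in group) <= cfg.group_max_gap):
                target = group
                break
        if target is None:
            groups.append([orf])
        else:
            target.append(orf)
    return groups
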