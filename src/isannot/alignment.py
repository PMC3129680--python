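"""Pairwise alignment primitives shared by the protein and nucleotide stages.

Local alignments are Smith-Waterman with affine gaps (BLOSUM62 for proteins,
match/mismatch scoring for nucleotides); global alignments are end-to-end
Needleman-Wunsch over the full sequences.  Significance of local protein hits
is expressed as a Karlin-Altschul expectation value computed from the raw
score with gapped BLOSUM62 parameters, so the builtin search backend reports
numbers on the same scale as BLAST without shelling out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

# Gapped Karlin-Altschul parameters: BLOSUM62 with gap open 11 / extend 1,
# and a blastn-like nucleotide scheme.  Used only to place raw local scores
# on an expectation-value scale.
_KA_PROTEIN = (0.267, 0.041)  # (lambda, K)
_KA_NUCLEOTIDE = (0.625, 0.41)


def _nt_matrix() -> substitution_matrices.Array:
    arr = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            # N never matches anything, including itself
            arr[x, y] = 2.0 if (x == y and x != "N") else -3.0
    return arr


@lru_cache(maxsize=None)
def _aligner(mode: str, alphabet: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    if alphabet == "protein":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    elif alphabet == "nucleotide":
        aligner.substitution_matrix = _nt_matrix()
        aligner.open_gap_score = -5.0
        aligner.extend_gap_score = -2.0
    else:
        raise ValueError(f"unknown alphabet {alphabet!r}")
    if mode not in ("local", "global"):
        raise ValueError(f"unknown mode {mode!r}")
    aligner.mode = mode
    return aligner


@dataclass(frozen=True)
class PairwiseResult:
    """Summary of one pairwise alignment (percentages on a 0-100 scale)."""

    score: float
    identity: float  # % identical columns over aligned columns (gaps counted)
    similarity: float  # % positive-scoring residue pairs over aligned columns
    query_coverage: float  # fraction of query residues aligned to residues
    subject_coverage: float
    query_span: tuple[int, int]  # 0-based half-open, on the query
    subject_span: tuple[int, int]
    matches: int
    mismatches: int
    gaps: int
    aligned_columns: int
    evalue: float
    blocks: tuple = ()  # paired ((qs, qe), (ss, se)) gap-free block spans


def _sanitize(seq: str, alphabet: str) -> str:
    seq = seq.upper()
    if alphabet == "nucleotide":
        return "".join(c if c in "ACGTN" else "N" for c in seq)
    # BLOSUM62 alphabet: map unknowns (including selenocysteine etc.) to X
    known = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in known else "X" for c in seq)


def align_pair(
    a: str, b: str, mode: str = "local", alphabet: str = "protein"
) -> PairwiseResult:
    """Align query ``a`` against subject ``b`` and summarize the result.

    Local mode returns the maximal-scoring local alignment; global mode an
    end-to-end alignment of the full sequences.  Identity is computed as
    matches over aligned columns (gap columns included, as in BLAST reports).
    """
    if not a or not b:
        raise ValueError("align_pair requires nonempty sequences")
    qa, qb = _sanitize(a, alphabet), _sanitize(b, alphabet)
    aligner = _aligner(mode, alphabet)
    try:
        aln = aligner.align(qa, qb)[0]
    except IndexError:  # no positive-scoring local alignment exists
        return PairwiseResult(
            score=0.0, identity=0.0, similarity=0.0, query_coverage=0.0,
            subject_coverage=0.0, query_span=(0, 0), subject_span=(0, 0),
            matches=0, mismatches=0, gaps=0, aligned_columns=0,
            evalue=math.inf,
        )
    counts = aln.counts()
    matches = counts.identities
    mismatches = counts.mismatches
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:  # empty local alignment (all-negative scores)
        return PairwiseResult(
            score=0.0, identity=0.0, similarity=0.0, query_coverage=0.0,
            subject_coverage=0.0, query_span=(0, 0), subject_span=(0, 0),
            matches=0, mismatches=0, gaps=0, aligned_columns=0,
            evalue=math.inf,
        )
    qspan = (int(qblocks[0][0]), int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]), int(sblocks[-1][1]))
    aligned_res = sum(int(e - s) for s, e in qblocks)
    if mode == "global":
        columns = aln.length
        gaps = columns - aligned_res
    else:
        # local: columns of the aligned region only
        columns = (qspan[1] - qspan[0]) + (sspan[1] - sspan[0]) - aligned_res
        gaps = columns - aligned_res
    matrix = aligner.substitution_matrix
    positives = 0
    for (qs, qe), (ss, se) in zip(qblocks, sblocks):
        for i in range(qe - qs):
            if matrix[qa[qs + i], qb[ss + i]] > 0:
                positives += 1
    lam, k = _KA_PROTEIN if alphabet == "protein" else _KA_NUCLEOTIDE
    evalue = k * len(qa) * len(qb) * math.exp(-lam * float(aln.score))
    return PairwiseResult(
        score=float(aln.score),
        identity=100.0 * matches / columns if columns else 0.0,
        similarity=100.0 * positives / columns if columns else 0.0,
        query_coverage=aligned_res / len(qa),
        subject_coverage=aligned_res / len(qb),
        query_span=qspan,
        subject_span=sspan,
        matches=int(matches),
        mismatches=int(mismatches),
        gaps=int(gaps),
        aligned_columns=int(columns),
        evalue=evalue,
        blocks=tuple(
            ((int(qs), int(qe)), (int(ss), int(se)))
            for (qs, qe), (ss, se) in zip(qblocks, sblocks)
        ),
    )
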