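"""Optional external search backend using NCBI BLAST+ (blastp / blastn).

The builtin aligner is the default and the two backends share one contract:
same hit records, same thresholds.  The external backend honors the word-size
parameters (3 for proteins, 7 for nucleotides) and disables low-complexity
filtering, matching the published search settings.  Requires ``makeblastdb``,
``blastp`` and ``blastn`` on PATH.
"""

from __future__ import annotations

import subprocess
import tempfile
from pathlib import Path

from isannot.config import PipelineConfig
from isannot.nucleotide_stage import NucleotideHit
from isannot.protein_stage import ProteinHit
from isannot.reference_library import ReferenceLibrary

_OUTFMT = ("6 sseqid pident ppos length qstart qend sstart send evalue "
           "bitscore qlen slen sstrand")


def _run(cmd: list[str]) -> str:
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"{cmd[0]} failed: {proc.stderr.strip()}")
    return proc.stdout


def blastp_search(
    protein: str, lib: ReferenceLibrary, cfg: PipelineConfig
) -> list[ProteinHit]:
    meta = {
        f"{name}_{orf_id}": (name, orf_id, role, family, subject)
        for name, orf_id, role, family, subject in lib.proteins()
    }
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db = tmp / "lib.faa"
        db.write_text(
            "".join(f">{tag}\n{seq}\n" for tag, (_, _, _, _, seq) in meta.items())
        )
        (tmp / "query.faa").write_text(f">q\n{protein.rstrip('*')}\n")
        _run(["makeblastdb", "-in", str(db), "-dbtype", "prot"])
        out = _run(
            ["blastp", "-query", str(tmp / "query.faa"), "-db", str(db),
             "-evalue", str(cfg.protein_evalue),
             "-word_size", str(cfg.protein_word_size),
             "-seg", "no", "-outfmt", _OUTFMT]
        )
    hits = []
    for line in out.splitlines():
        f = line.split("\t")
        name, orf_id, role, family, subject = meta[f[0]]
        length = int(f[3])
        hits.append(
            ProteinHit(
                subject_is=name, subject_orf=orf_id, family=family, role=role,
                identity=float(f[1]), similarity=float(f[2]),
                subject_coverage=min(1.0, length / int(f[11])),
                query_coverage=min(1.0, length / int(f[10])),
                evalue=float(f[8]), score=float(f[9]),
                aln_query_span=(int(f[4]) - 1, int(f[5])),
                aln_subject_span=(int(f[6]) - 1, int(f[7])),
            )
        )
    hits.sort(key=lambda h: (h.evalue, -h.score, h.subject_is, h.subject_orf))
    return hits


def blastn_search(
    query: str, lib: ReferenceLibrary, cfg: PipelineConfig
) -> list[NucleotideHit]:
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        db = tmp / "lib.fna"
        db.write_text(
            "".join(f">{name}\n{seq}\n" for name, seq in lib.nucleotide_entries())
        )
        (tmp / "query.fna").write_text(f">q\n{query}\n")
        _run(["makeblastdb", "-in", str(db), "-dbtype", "nucl"])
        out = _run(
            ["blastn", "-query", str(tmp / "query.fna"), "-db", str(db),
             "-evalue", "1e-5", "-word_size", str(cfg.nt_word_size),
             "-dust", "no", "-outfmt", _OUTFMT]
        )
    hits = []
    for line in out.splitlines():
        f = line.split("\t")
        sstart, send = int(f[6]), int(f[7])
        strand = "+" if f[12] == "plus" else "-"
        sspan = (sstart - 1, send) if strand == "+" else (send - 1, sstart)
        hits.append(
            NucleotideHit(
                subject_is=f[0], identity=float(f[1]), strand=strand,
                query_span=(int(f[4]) - 1, int(f[5])), subject_span=sspan,
                score=float(f[9]), aligned_columns=int(f[3]),
            )
        )
    hits.sort(key=lambda h: (-h.score, h.subject_is, h.query_span))
    return hits
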