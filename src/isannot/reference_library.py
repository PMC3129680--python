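"""The IS reference library: curated elements that drive every search.

A library is a directory of three plain-text files:

* ``is_seq.fna``   — element nucleotide FASTA, header ``>{name}|{family}|{group}``
* ``is_aa.faa``    — ORF protein FASTA, header ``>{name}_{orf_id}|{family}|{role}``
* ``metadata.tsv`` — one row per ORF with element-level columns repeated

Coordinates are 1-based inclusive in the files (GenBank convention) and
0-based half-open in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from isannot.util import revcomp

ORF_ROLES = ("transposase", "accessory", "passenger")

METADATA_COLUMNS = [
    "name", "family", "group", "length", "ir_left", "ir_right", "dr_length",
    "orf_id", "orf_start", "orf_end", "orf_strand", "orf_role",
]


class LibraryError(ValueError):
    """Raised when a reference library is structurally invalid."""


@dataclass
class ISOrfRef:
    """One ORF of a reference element (coords 0-based half-open, on the element)."""

    orf_id: str
    role: str
    start: int
    end: int
    strand: str
    protein: str

    def __post_init__(self) -> None:
        if self.role not in ORF_ROLES:
            raise LibraryError(f"ORF {self.orf_id}: unknown role {self.role!r}")
        if self.strand not in "+-":
            raise LibraryError(f"ORF {self.orf_id}: bad strand {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise LibraryError(f"ORF {self.orf_id}: bad coordinates")
        if len(self.protein) < 30:
            raise LibraryError(f"ORF {self.orf_id}: protein shorter than 30 aa")
        if "*" in self.protein:
            raise LibraryError(f"ORF {self.orf_id}: internal stop in protein")


@dataclass
class ISReference:
    """One curated IS element."""

    name: str
    family: str
    sequence: str
    group: str = ""
    orfs: list[ISOrfRef] = field(default_factory=list)
    ir_left: str | None = None
    ir_right: str | None = None
    dr_length: int | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for orf in self.orfs:
            if orf.end > len(self.sequence):
                raise LibraryError(
                    f"{self.name}/{orf.orf_id}: ORF exceeds element length"
                )
        if self.ir_left and not self.sequence.startswith(self.ir_left.upper()):
            raise LibraryError(f"{self.name}: ir_left is not a sequence prefix")
        if self.ir_right and not self.sequence.endswith(self.ir_right.upper()):
            raise LibraryError(f"{self.name}: ir_right is not a sequence suffix")
        if self.dr_length is not None and self.dr_length < 0:
            raise LibraryError(f"{self.name}: negative dr_length")

    def __len__(self) -> int:
        return len(self.sequence)

    def orf_nucleotides(self, orf: ISOrfRef) -> str:
        seg = self.sequence[orf.start : orf.end]
        return seg if orf.strand == "+" else revcomp(seg)

    def transposase_orfs(self) -> list[ISOrfRef]:
        return [o for o in self.orfs if o.role == "transposase"]


@dataclass
class ReferenceLibrary:
    """A set of reference elements keyed by name."""

    references: dict[str, ISReference] = field(default_factory=dict)

    @property
    def families(self) -> set[str]:
        return {r.family for r in self.references.values()}

    def __len__(self) -> int:
        return len(self.references)

    def __getitem__(self, name: str) -> ISReference:
        return self.references[name]

    def __contains__(self, name: str) -> bool:
        return name in self.references

    def add(self, ref: ISReference) -> None:
        if ref.name in self.references:
            raise LibraryError(f"duplicate IS name {ref.name!r}")
        self.references[ref.name] = ref

    def proteins(self) -> list[tuple[str, str, str, str, str]]:
        """Aggregate protein set as (is_name, orf_id, role, family, protein)."""
        out = []
        for ref in self.references.values():
            for orf in ref.orfs:
                out.append((ref.name, orf.orf_id, orf.role, ref.family, orf.protein))
        return out

    def nucleotide_entries(self) -> list[tuple[str, str]]:
        return [(r.name, r.sequence) for r in self.references.values()]


def validate_reference(ref: ISReference) -> list[str]:
    """Non-fatal consistency warnings for one reference element.

    Checks the canonical 0.7-3.5 kb IS length range (MITE references may be
    shorter, hence a warning rather than a rejection), approximate reverse
    complementarity of the terminal IRs, and agreement of each stored ORF
    protein with the conceptual translation of its coordinates.
    """
    warnings = []
    if not 700 <= len(ref) <= 3500:
        warnings.append(
            f"{ref.name}: length {len(ref)} bp outside the canonical "
            "0.7-3.5 kb IS range"
        )
    if ref.ir_left and ref.ir_right:
        left = ref.ir_left.upper()
        right_rc = revcomp(ref.ir_right.upper())
        n = min(len(left), len(right_rc))
        mismatches = sum(1 for i in range(n) if left[i] != right_rc[i])
        mismatches += abs(len(left) - len(right_rc))
        if mismatches > 0.5 * max(len(left), len(right_rc)):
            warnings.append(
                f"{ref.name}: ir_right is not approximately the reverse "
                f"complement of ir_left ({mismatches} mismatches)"
            )
    for orf in ref.orfs:
        nt = ref.orf_nucleotides(orf)
        conceptual = str(Seq(nt[: len(nt) - len(nt) % 3]).translate(table=11))
        conceptual = conceptual[:-1] if conceptual.endswith("*") else conceptual
        if conceptual != orf.protein:
            warnings.append(
                f"{ref.name}/{orf.orf_id}: stored protein disagrees with the "
                "conceptual translation of its coordinates"
            )
    return warnings


def load_reference_library(path: str | Path) -> ReferenceLibrary:
    """Load and cross-validate a three-file library directory."""
    path = Path(path)
    fna, faa, meta_path = path / "is_seq.fna", path / "is_aa.faa", path / "metadata.tsv"
    for p in (fna, faa, meta_path):
        if not p.exists():
            raise LibraryError(f"missing library file: {p}")

    meta = pd.read_csv(meta_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise LibraryError(f"metadata.tsv lacks columns: {sorted(missing_cols)}")

    nt_records: dict[str, tuple[str, str, str]] = {}
    for rec in SeqIO.parse(str(fna), "fasta"):
        name, family, group = (rec.description.split("|") + ["", ""])[:3]
        name = name.split()[0]
        if name in nt_records:
            raise LibraryError(f"duplicate IS name {name!r} in is_seq.fna")
        nt_records[name] = (family, group, str(rec.seq).upper())

    aa_records: dict[tuple[str, str], str] = {}
    for rec in SeqIO.parse(str(faa), "fasta"):
        tag = rec.description.split("|")[0].split()[0]
        name, _, orf_id = tag.rpartition("_")
        if (name, orf_id) in aa_records:
            raise LibraryError(f"duplicate protein record {tag!r} in is_aa.faa")
        aa_records[(name, orf_id)] = str(rec.seq).upper()

    lib = ReferenceLibrary()
    for name, rows in meta.groupby("name", sort=False):
        if name not in nt_records:
            raise LibraryError(f"metadata names {name!r} absent from is_seq.fna")
        family, group, sequence = nt_records[name]
        first = rows.iloc[0]
        orfs = []
        for _, row in rows.iterrows():
            key = (name, row["orf_id"])
            if key not in aa_records:
                raise LibraryError(
                    f"metadata ORF {name}_{row['orf_id']} absent from is_aa.faa"
                )
            orfs.append(
                ISOrfRef(
                    orf_id=row["orf_id"],
                    role=row["orf_role"],
                    start=int(row["orf_start"]) - 1,  # file 1-based inclusive
                    end=int(row["orf_end"]),
                    strand=row["orf_strand"],
                    protein=aa_records[key],
                )
            )
        lib.add(
            ISReference(
                name=name,
                family=first["family"] or family,
                group=first["group"] or group,
                sequence=sequence,
                orfs=orfs,
                ir_left=first["ir_left"] or None,
                ir_right=first["ir_right"] or None,
                dr_length=int(first["dr_length"]) if first["dr_length"] else None,
            )
        )

    orphan_nt = set(nt_records) - set(lib.references)
    if orphan_nt:
        raise LibraryError(
            f"is_seq.fna records without metadata rows: {sorted(orphan_nt)}"
        )
    orphan_aa = {
        f"{n}_{o}" for (n, o) in aa_records
        if n not in lib.references
        or o not in {orf.orf_id for orf in lib.references[n].orfs}
    }
    if orphan_aa:
        raise LibraryError(
            f"is_aa.faa records without metadata rows: {sorted(orphan_aa)}"
        )
    return lib


def write_reference_library(lib: ReferenceLibrary, path: str | Path) -> None:
    """Write the three-file library layout (inverse of load_reference_library)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    nt_recs, aa_recs, rows = [], [], []
    for ref in lib.references.values():
        nt_recs.append(
            SeqRecord(Seq(ref.sequence), id=f"{ref.name}|{ref.family}|{ref.group}",
                      description="")
        )
        for orf in ref.orfs:
            aa_recs.append(
                SeqRecord(
                    Seq(orf.protein),
                    id=f"{ref.name}_{orf.orf_id}|{ref.family}|{orf.role}",
                    description="",
                )
            )
            rows.append(
                {
                    "name": ref.name,
                    "family": ref.family,
                    "group": ref.group,
                    "length": len(ref),
                    "ir_left": ref.ir_left or "",
                    "ir_right": ref.ir_right or "",
                    "dr_length": "" if ref.dr_length is None else ref.dr_length,
                    "orf_id": orf.orf_id,
                    "orf_start": orf.start + 1,
                    "orf_end": orf.end,
                    "orf_strand": orf.strand,
                    "orf_role": orf.role,
                }
            )
    SeqIO.write(nt_recs, str(path / "is_seq.fna"), "fasta")
    SeqIO.write(aa_recs, str(path / "is_aa.faa"), "fasta")
    pd.DataFrame(rows, columns=METADATA_COLUMNS).to_csv(
        path / "metadata.tsv", sep="\t", index=False
    )
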