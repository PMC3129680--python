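"""Replicon input/output: GenBank and FASTA reading, annotated GenBank export.

Internal coordinates are 0-based half-open throughout; the 1-based inclusive
GenBank convention applies only inside files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from isannot.util import overlap_len, revcomp

if TYPE_CHECKING:  # pragma: no cover
    from isannot.nucleotide_stage import ISCopy

FEATURE_KINDS = ("CDS", "gene", "pseudogene", "mobile_element", "repeat_region", "other")

GENERIC_PRODUCTS = (
    "hypothetical protein",
    "integrase",
    "recombinase",
    "protein of unknown function",
    "unknown",
    "transposase",
)


@dataclass
class GenomeFeature:
    kind: str
    start: int
    end: int
    strand: str
    qualifiers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            self.kind = "other"
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad feature coordinates [{self.start}, {self.end})")

    @property
    def is_pseudo(self) -> bool:
        return self.kind == "pseudogene" or "pseudo" in self.qualifiers


@dataclass
class Replicon:
    id: str
    sequence: str
    features: list[GenomeFeature] = field(default_factory=list)
    topology: str = "linear"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"replicon {self.id}: empty sequence")
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if f.end > len(self.sequence):
                raise ValueError(f"replicon {self.id}: feature beyond sequence end")

    def __len__(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        return self.sequence[max(0, start) : min(len(self.sequence), end)]


def _classify_feature(ftype: str, qualifiers: dict[str, str]) -> str:
    if ftype == "CDS":
        return "pseudogene" if "pseudo" in qualifiers else "CDS"
    if ftype in ("gene", "mobile_element", "repeat_region"):
        if ftype == "gene" and "pseudo" in qualifiers:
            return "pseudogene"
        return ftype
    if ftype == "mobile_element_type":
        return "mobile_element"
    return "other"


def read_replicons(path: str | Path, format: str = "auto") -> list[Replicon]:
    """Read one or more replicons from a GenBank or FASTA file.

    GenBank features are captured (including /pseudo flags); FASTA records
    yield feature-less replicons.  More than ten replicons only triggers a
    warning, mirroring the ten-replicon project convention.
    """
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in (".gb", ".gbk", ".gbff", ".genbank"):
            format = "genbank"
        elif suffix in (".fa", ".fasta", ".fna"):
            format = "fasta"
        else:
            with open(path) as fh:
                first = fh.read(1)
            format = "fasta" if first == ">" else "genbank"
    replicons = []
    for idx, rec in enumerate(SeqIO.parse(str(path), format)):
        try:
            replicons.append(_record_to_replicon(rec))
        except Exception as exc:  # re-raise with the record index
            raise ValueError(f"record {idx} ({rec.id}): {exc}") from exc
    if not replicons:
        raise ValueError(f"no {format} records parsed from {path}")
    if len(replicons) > 10:
        warnings.warn(
            f"{len(replicons)} replicons in one project (more than the "
            "recommended 10)", stacklevel=2,
        )
    return replicons


def _record_to_replicon(rec: SeqRecord) -> Replicon:
    features = []
    for f in rec.features:
        if f.type in ("source",):
            continue
        if f.location is None:
            continue
        quals = {k: "|".join(str(x) for x in v) if isinstance(v, list) else str(v)
                 for k, v in f.qualifiers.items()}
        kind = _classify_feature(f.type, quals)
        if kind == "other" and f.type not in ("gene",):
            quals.setdefault("original_type", f.type)
        strand = "-" if f.location.strand == -1 else "+"
        features.append(
            GenomeFeature(
                kind=kind,
                start=int(f.location.start),
                end=int(f.location.end),
                strand=strand,
                qualifiers=quals,
            )
        )
    topology = rec.annotations.get("topology", "linear")
    return Replicon(
        id=rec.id, sequence=str(rec.seq), features=features,
        topology=topology if topology in ("linear", "circular") else "linear",
    )


def conceptual_translation(rep: Replicon, start: int, end: int, strand: str) -> str:
    """Genetic-code-11 translation of a genome span (internal stops retained,
    one trailing stop stripped)."""
    nt = rep.subseq(start, end)
    if strand == "-":
        nt = revcomp(nt)
    usable = len(nt) - len(nt) % 3
    protein = str(Seq(nt[:usable]).translate(table=11))
    return protein[:-1] if protein.endswith("*") else protein


def extract_annotated_orfs(rep: Replicon):
    """One protein-stage candidate per annotated CDS/pseudogene feature.

    The stored /translation is used verbatim when present; otherwise the span
    is conceptually translated (internal stops retained so pseudogenes stay
    recognisable).  A span that is not a codon multiple and has no stored
    translation is truncated to the codon boundary with a warning.
    """
    from isannot.protein_stage import CandidateOrf

    orfs = []
    for feat in rep.features:
        if feat.kind not in ("CDS", "pseudogene"):
            continue
        translation = feat.qualifiers.get("translation", "")
        if translation:
            protein = translation.upper().rstrip("*")
        else:
            if (feat.end - feat.start) % 3 and not feat.is_pseudo:
                warnings.warn(
                    f"{rep.id}: CDS [{feat.start},{feat.end}) is not a codon "
                    "multiple; conceptual translation truncated", stacklevel=2,
                )
            protein = conceptual_translation(rep, feat.start, feat.end, feat.strand)
        if not protein:
            continue
        orfs.append(
            CandidateOrf(
                replicon_id=rep.id,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                protein=protein,
                source="annotation",
                pseudo_flag=feat.is_pseudo,
            )
        )
    return orfs


def _feature_to_seqfeature(feat: GenomeFeature) -> SeqFeature:
    ftype = {"pseudogene": "CDS", "other": feat.qualifiers.get("original_type", "misc_feature")}.get(
        feat.kind, feat.kind
    )
    quals = {k: [v] for k, v in feat.qualifiers.items() if k != "original_type"}
    if feat.kind == "pseudogene":
        quals.setdefault("pseudo", [""])
    return SeqFeature(
        FeatureLocation(feat.start, feat.end, strand=1 if feat.strand == "+" else -1),
        type=ftype,
        qualifiers=quals,
    )


def write_annotated_genbank(
    rep: Replicon, copies: list["ISCopy"], out: str | Path
) -> Path:
    """Export the replicon with IS annotation layered over the original features.

    Per IS copy this adds a ``mobile_element`` feature, ``repeat_region``
    features for detected IRs, and renames transposase CDS products that carry
    generic labels ("hypothetical protein", "integrase", ...).  All original
    non-IS features are preserved.
    """
    seen = set()
    for copy in copies:
        if copy.copy_id in seen:
            raise ValueError(f"duplicate IS feature for copy {copy.copy_id}")
        seen.add(copy.copy_id)
        if copy.end > len(rep):
            raise ValueError(f"copy {copy.copy_id} outside replicon bounds")

    record = SeqRecord(
        Seq(rep.sequence), id=rep.id, name=rep.id[:16], description="",
        annotations={"molecule_type": "DNA", "topology": rep.topology},
    )
    features = [_feature_to_seqfeature(f) for f in rep.features]

    for copy in copies:
        strand = 1 if copy.strand == "+" else -1
        note = (
            f"family {copy.family}; completeness {copy.completeness}; "
            f"identity {copy.identity_nt:.1f}%"
        )
        if copy.dr is not None:
            note += f"; DR {copy.dr.seq}"
        quals = {
            "mobile_element_type": [f"insertion sequence:{copy.reference_is}"],
            "note": [note],
            "label": [copy.copy_id],
        }
        features.append(
            SeqFeature(
                FeatureLocation(copy.start, copy.end, strand=strand),
                type="mobile_element", qualifiers=quals,
            )
        )
        if copy.ir is not None:
            for s, e in ((copy.ir.left_start, copy.ir.left_end),
                         (copy.ir.right_start, copy.ir.right_end)):
                features.append(
                    SeqFeature(
                        FeatureLocation(s, e, strand=strand),
                        type="repeat_region",
                        qualifiers={"rpt_type": ["inverted"],
                                    "note": [f"terminal IR of {copy.copy_id}"]},
                    )
                )
        # rename generically-labelled transposase CDS products
        product = f"{copy.reference_is} transposase, {copy.family} family"
        for sf in features:
            if sf.type != "CDS":
                continue
            span = (int(sf.location.start), int(sf.location.end))
            for orf_span in copy.orf_spans:
                ov = overlap_len(span, (orf_span[0], orf_span[1]))
                if ov >= 0.5 * (span[1] - span[0]):
                    current = sf.qualifiers.get("product", [""])[0].lower()
                    if not current or any(g in current for g in GENERIC_PRODUCTS):
                        sf.qualifiers["product"] = [product]
                    break

    features.sort(key=lambda f: (int(f.location.start), int(f.location.end)))
    record.features = features
    out = Path(out)
    out.parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write([record], str(out), "genbank")
    return out
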