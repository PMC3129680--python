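"""Deterministic synthetic reference libraries and test genomes.

The generator emulates the structure of a curated IS dataset and of replicons
carrying IS insertions: reference elements with terminal IRs, one or two ORFs
and a characteristic target-duplication length; genomes with implanted
complete copies, 5'/3'-truncated partials, pseudogenized copies, intercalated
(nested) insertions and ORF-less MITE-like derivatives.  Every implant is
recorded as machine-readable ground truth so recovery can be scored without
touching the detectors: the generator builds strings, the detectors re-derive
features from the emitted sequence.

Insertion mechanics mirror target site duplication: inserting element E at
position p with duplication length d yields ``g[:p] + E + g[p-d:p] + g[p:]``,
so the d bases immediately 5' of the element recur immediately 3' of it.
Flanking background bases are resampled when an insertion site would, by
chance, carry a longer exact terminal duplication than the one created, so
the recorded DR is exactly the detectable one.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Seq import Seq

from isannot.alignment import align_pair
from isannot.genome_io import GenomeFeature, Replicon, write_annotated_genbank
from isannot.reference_library import (
    ISOrfRef,
    ISReference,
    ReferenceLibrary,
    load_reference_library,
)
from isannot.util import revcomp

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_NON_STOP_CODONS = [
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in _STOPS
]


def _random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_orf_nt(rng: np.random.Generator, n_aa: int) -> str:
    body = "".join(rng.choice(_NON_STOP_CODONS, size=n_aa - 1))
    return "ATG" + body + "TAA"


def _mutate_codons(rng: np.random.Generator, orf_nt: str, rate: float) -> str:
    """Codon-wise substitution that never introduces stops or touches the
    start/stop codons, preserving the reading frame."""
    codons = [orf_nt[i : i + 3] for i in range(0, len(orf_nt), 3)]
    for i in range(1, len(codons) - 1):
        if rng.random() < rate:
            new = codons[i]
            while new == codons[i]:
                new = _NON_STOP_CODONS[rng.integers(len(_NON_STOP_CODONS))]
            codons[i] = new
    return "".join(codons)


def _translate(nt: str) -> str:
    protein = str(Seq(nt).translate(table=11))
    return protein[:-1] if protein.endswith("*") else protein


def generate_reference_library(
    n_families: int, n_is: int, seed: int
) -> ReferenceLibrary:
    """Deterministic library: ``n_is`` elements over ``n_families`` families.

    Elements are 0.7-3.5 kb with terminal IRs of 10-25 bp, one or two ORFs
    and a characteristic DR length of 2-12 bp.  Transposases within a family
    derive from a common founder (>= 50% aa identity); across families they
    are independent (< 30% aa identity, verified after generation).
    """
    if not 1 <= n_families <= n_is:
        raise ValueError("need n_is >= n_families >= 1")
    for attempt in range(5):
        rng = np.random.default_rng((seed, 7919, attempt))
        lib = _build_library(rng, n_families, n_is)
        if _library_identity_ok(lib):
            return lib
    raise RuntimeError("could not generate a library meeting identity bounds")


def _build_library(
    rng: np.random.Generator, n_families: int, n_is: int
) -> ReferenceLibrary:
    founders = [
        _random_orf_nt(rng, int(rng.integers(270, 430)))
        for _ in range(n_families)
    ]
    lib = ReferenceLibrary()
    for i in range(n_is):
        fam_idx = i % n_families
        name = f"ISSyn{i + 1}"
        family = f"ISF{fam_idx + 1}"
        tnp_nt = _mutate_codons(rng, founders[fam_idx],
                                float(rng.uniform(0.08, 0.18)))
        ir = _random_dna(rng, int(rng.integers(10, 26)))
        left_filler = _random_dna(rng, int(rng.integers(20, 150)))
        right_filler = _random_dna(rng, int(rng.integers(20, 300)))
        orfs_nt: list[tuple[str, str]] = []  # (role, nt)
        if rng.random() < 0.4:
            orfs_nt.append(
                ("accessory", _random_orf_nt(rng, int(rng.integers(90, 150))))
            )
        orfs_nt.append(("transposase", tnp_nt))
        pieces = [ir, left_filler]
        orfs: list[ISOrfRef] = []
        cursor = len(ir) + len(left_filler)
        for k, (role, nt) in enumerate(orfs_nt):
            orfs.append(
                ISOrfRef(
                    orf_id=f"orf{k + 1}", role=role, start=cursor,
                    end=cursor + len(nt), strand="+", protein=_translate(nt),
                )
            )
            pieces.append(nt)
            gap = _random_dna(rng, int(rng.integers(10, 40)))
            pieces.append(gap)
            cursor += len(nt) + len(gap)
        pieces[-1] = right_filler  # replace trailing gap
        cursor = cursor - len(gap) + len(right_filler)
        pieces.append(revcomp(ir))
        sequence = "".join(pieces)
        lib.add(
            ISReference(
                name=name, family=family, sequence=sequence, orfs=orfs,
                ir_left=ir, ir_right=revcomp(ir),
                dr_length=int(rng.integers(2, 13)),
            )
        )
    return lib


def _library_identity_ok(lib: ReferenceLibrary) -> bool:
    tnps = {
        name: next(o.protein for o in ref.orfs if o.role == "transposase")
        for name, ref in lib.references.items()
    }
    names = sorted(tnps)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ident = align_pair(tnps[a], tnps[b], mode="global",
                               alphabet="protein").identity
            same_family = lib[a].family == lib[b].family
            if same_family and ident < 50.0:
                return False
            if not same_family and ident >= 30.0:
                return False
    return True


# --- implants ---------------------------------------------------------------


@dataclass
class GroundTruth:
    implant_id: str
    reference_is: str
    family: str
    start: int  # genome coords, 0-based half-open, kept current as later
    end: int  # implants shift/extend the genome
    strand: str
    identity: float  # realized % identity to the reference over the implant
    dr_seq: str  # empty when inserted without duplication
    truncation: str  # none | 5p | 3p | internal
    nested_in: str | None = None
    pseudogenized: bool = False
    n_substitutions: int = 0
    annotate: str | None = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ImplantSpec:
    ref: str
    pos: int  # insertion point in background coordinates (top-level implants)
    dr_len: int | None = None  # default: the reference's characteristic length
    mutate_frac: float = 0.0
    truncate: tuple[str, float] | None = None  # ("5p"|"3p"|"internal", fraction)
    strand: str = "+"
    nest_in: int | None = None  # index of a prior implant to interrupt
    offset_frac: float = 0.5  # where inside the parent the insertion lands
    pseudogenize: bool = False
    annotate: str | None = None  # None | transposase | hypothetical | pseudo


@dataclass
class FixtureSpec:
    replicon_id: str
    background_length: int
    library: ReferenceLibrary
    implants: list[ImplantSpec] = field(default_factory=list)
    gc: float = 0.5
    n_decoys: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FixtureSpec":
        data = yaml.safe_load(Path(path).read_text())
        lib_spec = data["library"]
        if "path" in lib_spec:
            library = load_reference_library(lib_spec["path"])
        else:
            library = generate_reference_library(
                lib_spec["n_families"], lib_spec["n_is"], lib_spec.get("seed", 0)
            )
        implants = [ImplantSpec(**imp) for imp in data.get("implants", [])]
        for imp in implants:
            if imp.truncate is not None:
                imp.truncate = (imp.truncate[0], float(imp.truncate[1]))
        return cls(
            replicon_id=data.get("replicon_id", "synrep1"),
            background_length=int(data["background_length"]),
            library=library,
            implants=implants,
            gc=float(data.get("gc", 0.5)),
            n_decoys=int(data.get("n_decoys", 0)),
        )


def _prepare_element(
    ref: ISReference,
    mutate_frac: float,
    truncate: tuple[str, float] | None,
    strand: str,
    pseudogenize: bool,
    rng: np.random.Generator,
) -> tuple[str, str, int]:
    """Element sequence to insert, truncation label, substitution count."""
    element = ref.sequence
    n_sub = 0
    if pseudogenize:
        tnp = ref.transposase_orfs()[0]
        n_codons = (tnp.end - tnp.start) // 3
        codon_idx = int(rng.integers(int(n_codons * 0.4), int(n_codons * 0.6)))
        at = tnp.start + 3 * codon_idx
        if element[at : at + 3] not in _STOPS:
            element = element[:at] + "TAA" + element[at + 3 :]
            n_sub += sum(1 for a, b in zip(ref.sequence[at : at + 3], "TAA")
                         if a != b)
    if mutate_frac > 0:
        chars = list(element)
        sites = rng.choice(len(chars), size=int(round(mutate_frac * len(chars))),
                           replace=False)
        for site in sites:
            new = chars[site]
            while new == chars[site]:
                new = _BASES[rng.integers(4)]
            chars[site] = new
            n_sub += 1
        element = "".join(chars)
    label = "none"
    if truncate is not None:
        kind, frac = truncate
        cut = int(len(element) * frac)
        if len(element) - cut < 0.05 * len(element) or (
                kind == "internal" and cut > 0.95 * len(element)):
            raise ValueError("truncation removes more than 95% of the element")
        if kind == "5p":
            element = element[cut:]
        elif kind == "3p":
            element = element[: len(element) - cut]
        elif kind == "internal":
            keep = (len(element) - cut) // 2
            if keep < 30:
                raise ValueError("internal truncation leaves ends too short")
            element = element[:keep] + element[-keep:]
        else:
            raise ValueError(f"unknown truncation kind {kind!r}")
        label = kind
    if strand == "-":
        element = revcomp(element)
    return element, label, n_sub


def _longest_terminal_dup(seq: str, s: int, e: int, kmax: int = 20) -> int:
    for k in range(min(kmax, s, len(seq) - e), 1, -1):
        if seq[s - k : s] == seq[e : e + k]:
            return k
    return 0


def implant_is(
    genome: str,
    ref: ISReference,
    pos: int,
    dr_len: int,
    mutate_frac: float = 0.0,
    truncate: tuple[str, float] | None = None,
    strand: str = "+",
    pseudogenize: bool = False,
    rng: np.random.Generator | None = None,
    implant_id: str = "imp",
    annotate: str | None = None,
) -> tuple[str, GroundTruth]:
    """Insert one (optionally mutated/truncated) element with target site
    duplication mechanics and return the genome plus its ground truth."""
    if rng is None:
        rng = np.random.default_rng(0)
    if not dr_len <= 20:
        raise ValueError("dr_len must be <= 20")
    if not dr_len <= pos <= len(genome):
        raise ValueError("insertion position out of range")
    element, label, n_sub = _prepare_element(
        ref, mutate_frac, truncate, strand, pseudogenize, rng
    )
    dr = genome[pos - dr_len : pos] if dr_len else ""
    new = genome[:pos] + element + dr + genome[pos:]
    identity = 100.0 * (1.0 - n_sub / len(element))
    truth = GroundTruth(
        implant_id=implant_id, reference_is=ref.name, family=ref.family,
        start=pos, end=pos + len(element), strand=strand, identity=identity,
        dr_seq=dr, truncation=label, pseudogenized=pseudogenize,
        n_substitutions=n_sub, annotate=annotate,
    )
    return new, truth


def _scrub_spurious_dr(
    genome: str, s: int, e: int, dr_len: int, rng: np.random.Generator,
    editable: tuple[int, int] | None = None,
) -> str | None:
    """Resample flanking bases until the longest exact terminal duplication at
    [s, e) equals ``dr_len``.  Only positions outside ``editable`` protection
    (the element and its DR copies) are touched; returns None when a clean
    state cannot be reached by editing (nested sites: caller retries)."""
    for _ in range(60):
        k = _longest_terminal_dup(genome, s, e)
        if k == dr_len or (dr_len < 2 and k < 2):
            return genome
        # break the offending duplication at its outermost compared base
        pos = e + k - 1 if k > 0 else e
        if editable is not None and not (editable[0] <= pos < editable[1]):
            return None
        old = genome[pos]
        new = old
        while new == old:
            new = _BASES[rng.integers(4)]
        genome = genome[:pos] + new + genome[pos + 1 :]
    return None


def generate_test_genome(
    spec: FixtureSpec, seed: int, out_dir: str | Path | None = None
) -> tuple[Replicon, list[GroundTruth]]:
    """Build a replicon from a fixture spec: seeded background, implants in
    ascending position (nested entries applied right after their parent),
    optional decoy CDS annotations, and the ground-truth record.

    Deterministic for a given (spec, seed).  Overlapping non-nested implants
    are rejected.
    """
    rng = np.random.default_rng((seed, 104729))
    genome = _random_dna(rng, spec.background_length, spec.gc)
    truths: list[GroundTruth] = []
    order = _application_order(spec.implants)
    shift = 0  # total bp inserted so far; valid because insertions ascend
    last_pos = -1
    for idx in order:
        imp = spec.implants[idx]
        ref = spec.library[imp.ref]
        dr_len = (ref.dr_length or 0) if imp.dr_len is None else imp.dr_len
        implant_id = f"imp{idx + 1:02d}"
        if imp.nest_in is None:
            if imp.pos <= last_pos:
                raise ValueError("top-level implant positions must ascend")
            if last_pos >= 0 and imp.pos - last_pos < 50:
                raise ValueError(
                    f"implant {implant_id} overlaps the insertion site of the "
                    "previous implant (leave >= 50 bp of background between "
                    "non-nested implants)"
                )
            last_pos = imp.pos
            pos = imp.pos + shift
            for t in truths:
                if t.start < pos < t.end:
                    raise ValueError(
                        f"implant {implant_id} overlaps {t.implant_id} "
                        "without nesting"
                    )
            genome, truth = _apply_implant(genome, ref, pos, dr_len, imp, rng,
                                           implant_id, truths, editable=None)
        else:
            parent = next(
                t for t in truths
                if t.implant_id == f"imp{imp.nest_in + 1:02d}"
            )
            genome, truth = _apply_nested(genome, ref, dr_len, imp, rng,
                                          implant_id, parent, truths)
            truth.nested_in = parent.implant_id
        shift += (truth.end - truth.start) + len(truth.dr_seq)
        truths.append(truth)
    features = _decoy_features(spec, truths, rng, len(genome))
    features += _implant_features(spec, truths)
    rep = Replicon(
        id=spec.replicon_id, sequence=genome, features=features,
        topology="linear",
    )
    if out_dir is not None:
        write_fixture(rep, truths, out_dir)
    return rep, truths


def _application_order(implants: list[ImplantSpec]) -> list[int]:
    """Top-level implants in ascending position; nested implants directly
    after their parent, recursively (supports multi-level nesting)."""
    children: dict[int, list[int]] = {}
    for j, imp in enumerate(implants):
        if imp.nest_in is not None:
            children.setdefault(imp.nest_in, []).append(j)

    order: list[int] = []

    def visit(i: int) -> None:
        order.append(i)
        for j in children.get(i, []):
            visit(j)

    top = sorted(
        (i for i, imp in enumerate(implants) if imp.nest_in is None),
        key=lambda i: implants[i].pos,
    )
    for i in top:
        visit(i)
    if len(order) != len(implants):
        raise ValueError("nest_in must form a tree over the implant list")
    return order


def _truncation_constraints(
    truth: GroundTruth, ref: ISReference, truncate: tuple[str, float] | None,
    strand: str, genome_len: int,
) -> list[tuple[int, str]]:
    """(position, forbidden base) pairs keeping a truncation scar sharp: the
    two background bases beyond the scar must not continue the reference, or
    the implant boundary would be ambiguous by construction."""
    if truncate is None or truncate[0] not in ("5p", "3p"):
        return []
    cut = len(ref.sequence) - (truth.end - truth.start)
    out = []
    comp = str.maketrans("ACGT", "TGCA")
    for i in range(2):
        if truncate[0] == "5p":
            base = ref.sequence[cut - 1 - i]
            pos = truth.start - 1 - i if strand == "+" else truth.end + i
        else:
            base = ref.sequence[len(ref.sequence) - cut + i]
            pos = truth.end + i if strand == "+" else truth.start - 1 - i
        if strand == "-":
            base = base.translate(comp)
        if 0 <= pos < genome_len:
            out.append((pos, base))
    return out


def _apply_implant(genome, ref, pos, dr_len, imp, rng, implant_id, truths,
                   editable):
    new, truth = implant_is(
        genome, ref, pos, dr_len, imp.mutate_frac, imp.truncate, imp.strand,
        imp.pseudogenize, rng, implant_id, imp.annotate,
    )
    added = (truth.end - truth.start) + len(truth.dr_seq)
    constraints = _truncation_constraints(truth, ref, imp.truncate, imp.strand,
                                          len(new))
    scrubbed = None
    for _ in range(80):
        candidate = _scrub_spurious_dr(new, truth.start, truth.end, dr_len,
                                       rng, editable)
        if candidate is None:
            break
        new = candidate
        dirty = False
        for p, forbidden in constraints:
            if new[p] == forbidden:
                repl = forbidden
                while repl == forbidden:
                    repl = _BASES[rng.integers(4)]
                new = new[:p] + repl + new[p + 1 :]
                dirty = True
        if not dirty:
            scrubbed = new
            break
    if scrubbed is None:
        raise ValueError(f"could not scrub insertion site of {implant_id}")
    for t in truths:
        if t.start >= pos:
            t.start += added
            t.end += added
        elif t.start < pos < t.end:
            t.end += added
    return scrubbed, truth


def _apply_nested(genome, ref, dr_len, imp, rng, implant_id, parent, truths):
    parent_len = parent.end - parent.start
    for attempt in range(25):
        frac = imp.offset_frac + 0.015 * attempt * (1 if attempt % 2 else -1)
        offset = int(parent_len * min(max(frac, 0.2), 0.8))
        pos = parent.start + offset
        new, truth = implant_is(
            genome, ref, pos, dr_len, imp.mutate_frac, imp.truncate,
            imp.strand, imp.pseudogenize, rng, implant_id, imp.annotate,
        )
        if _longest_terminal_dup(new, truth.start, truth.end) == max(dr_len, 0) or (
                dr_len < 2
                and _longest_terminal_dup(new, truth.start, truth.end) < 2):
            added = (truth.end - truth.start) + len(truth.dr_seq)
            for t in truths:
                if t.start >= pos:
                    t.start += added
                    t.end += added
                elif t.start < pos < t.end:
                    t.end += added
            return new, truth
    raise ValueError(f"no clean nested insertion site for {implant_id}")


def _implant_features(
    spec: FixtureSpec, truths: list[GroundTruth]
) -> list[GenomeFeature]:
    features = []
    by_id = {f"imp{i + 1:02d}": imp for i, imp in enumerate(spec.implants)}
    for truth in truths:
        imp = by_id[truth.implant_id]
        if imp.annotate is None or imp.truncate is not None:
            continue
        ref = spec.library[imp.ref]
        length = len(ref)
        for orf in ref.transposase_orfs():
            if truth.strand == "+":
                s, e = truth.start + orf.start, truth.start + orf.end
                strand = "+"
            else:
                s = truth.start + length - orf.end
                e = truth.start + length - orf.start
                strand = "-"
            quals: dict[str, str] = {
                "locus_tag": f"{truth.implant_id}_tnp",
                "product": {
                    "transposase": "transposase",
                    "hypothetical": "hypothetical protein",
                    "pseudo": "transposase",
                }[imp.annotate],
            }
            kind = "CDS"
            if imp.annotate == "pseudo":
                quals["pseudo"] = ""
                kind = "pseudogene"
            features.append(
                GenomeFeature(kind=kind, start=s, end=e, strand=strand,
                              qualifiers=quals)
            )
    return features


def _decoy_features(
    spec: FixtureSpec, truths: list[GroundTruth], rng: np.random.Generator,
    genome_len: int,
) -> list[GenomeFeature]:
    features: list[GenomeFeature] = []
    forbidden = [(t.start - 200, t.end + 200) for t in truths]
    tries = 0
    while len(features) < spec.n_decoys and tries < 500:
        tries += 1
        length = 3 * int(rng.integers(100, 250))
        start = int(rng.integers(100, max(101, genome_len - length - 100)))
        span = (start, start + length)
        if any(max(span[0], s) < min(span[1], e) for s, e in forbidden):
            continue
        if any(max(span[0], f.start) < min(span[1], f.end) for f in features):
            continue
        features.append(
            GenomeFeature(
                kind="CDS", start=span[0], end=span[1],
                strand="+" if rng.random() < 0.5 else "-",
                qualifiers={
                    "locus_tag": f"decoy{len(features) + 1:03d}",
                    "product": "hypothetical protein",
                },
            )
        )
    return features


def write_fixture(
    rep: Replicon, truths: list[GroundTruth], out_dir: str | Path
) -> None:
    """Emit genome.gbk + genome.fasta + truth.json + truth.bed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_annotated_genbank(rep, [], out / "genome.gbk")
    fasta = [f">{rep.id}"]
    fasta += [rep.sequence[i : i + 70] for i in range(0, len(rep.sequence), 70)]
    (out / "genome.fasta").write_text("\n".join(fasta) + "\n")
    (out / "truth.json").write_text(
        json.dumps([t.to_dict() for t in truths], indent=2) + "\n"
    )
    bed_lines = [
        f"{rep.id}\t{t.start}\t{t.end}\t{t.implant_id}:{t.reference_is}\t0\t{t.strand}"
        for t in truths
    ]
    (out / "truth.bed").write_text("\n".join(bed_lines) + "\n")


# --- canned scenarios --------------------------------------------------------


def acceptance_scenario(seed: int) -> tuple[FixtureSpec, ReferenceLibrary]:
    """The full implant-and-recover study condition: a 200-kb replicon with 12
    implants at 100% identity — seven complete copies across three families
    (one of them nested inside an interrupted parent), one pseudogenized copy,
    two truncated partials and one MITE-like derivative."""
    lib = generate_reference_library(n_families=3, n_is=6, seed=seed)
    names = sorted(lib.references)
    r = {i: names[i] for i in range(6)}
    # the nested child's insertion duplicates part of the parent; keep that
    # duplication within the reconstruction tolerance
    child_dr = min(lib[r[2]].dr_length or 6, 8)
    implants = [
        ImplantSpec(ref=r[0], pos=12_000, annotate="transposase"),
        ImplantSpec(ref=r[1], pos=30_000, strand="-"),
        ImplantSpec(ref=r[2], pos=48_000, annotate="hypothetical"),
        ImplantSpec(ref=r[3], pos=66_000, annotate="transposase"),
        ImplantSpec(ref=r[0], pos=84_000, strand="-"),
        ImplantSpec(ref=r[1], pos=102_000),  # interrupted parent
        ImplantSpec(ref=r[2], pos=0, nest_in=5, offset_frac=0.5,
                    dr_len=child_dr),  # nested child (complete copy 6)
        ImplantSpec(ref=r[4], pos=126_000, annotate="transposase"),
        ImplantSpec(ref=r[3], pos=144_000, pseudogenize=True, annotate="pseudo"),
        ImplantSpec(ref=r[0], pos=158_000, truncate=("5p", 0.4), dr_len=0),
        ImplantSpec(ref=r[1], pos=170_000, truncate=("3p", 0.4), dr_len=0),
        ImplantSpec(ref=r[2], pos=182_000, truncate=("internal", 0.85)),
    ]
    return (
        FixtureSpec(
            replicon_id="synrep1", background_length=200_000, library=lib,
            implants=implants, n_decoys=6,
        ),
        lib,
    )


def negative_scenario(seed: int) -> tuple[FixtureSpec, ReferenceLibrary]:
    """Decoy-only genome: annotated hypothetical CDSs, no IS content."""
    lib = generate_reference_library(n_families=2, n_is=4, seed=seed)
    return (
        FixtureSpec(
            replicon_id="synneg1", background_length=60_000, library=lib,
            implants=[], n_decoys=8,
        ),
        lib,
    )


def small_scenario(seed: int, n_implants: int = 3) -> tuple[FixtureSpec, ReferenceLibrary]:
    """A compact genome with a few complete copies (used for fast sweeps)."""
    lib = generate_reference_library(n_families=2, n_is=4, seed=seed)
    names = sorted(lib.references)
    implants = [
        ImplantSpec(ref=names[i % len(names)], pos=8_000 + 9_000 * i,
                    annotate="transposase" if i % 2 == 0 else None,
                    strand="+" if i % 3 else "-")
        for i in range(n_implants)
    ]
    return (
        FixtureSpec(
            replicon_id="synsm1",
            background_length=8_000 + 9_000 * n_implants + 6_000,
            library=lib, implants=implants, n_decoys=3,
        ),
        lib,
    )
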