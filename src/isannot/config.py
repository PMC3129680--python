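"""Pipeline configuration: every search and annotation threshold in one place.

Defaults follow the published operating point of the method this package
implements: protein-level attribution at e-value <= 1e-5 with a 97% amino-acid
similarity cutoff for same-IS assignment, nucleotide identification at >95%
identity, 90% single-linkage clustering of candidate regions with no length
coverage requirement, and 49-bp flanks in reports.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    # protein stage
    protein_evalue: float = 1e-5
    protein_word_size: int = 3  # honored by the external BLAST backend
    same_is_similarity: float = 97.0  # % aa similarity for same-IS attribution
    complete_cov: float = 0.95  # global subject coverage for a complete ORF
    len_tol: float = 0.05  # length tolerance (fraction of subject length)
    orf_min_len: int = 150  # nt, de novo ORF calling
    group_max_gap: int = 1500  # bp between ORFs grouped into one element
    accessory_subjects: tuple[str, ...] = ()  # extra "name_orfid" accessory tags

    # nucleotide stage
    nt_identity: float = 95.0  # % identity, hits retained when strictly above
    nt_word_size: int = 7  # honored by the external BLAST backend
    nt_min_hit_len: int = 40  # bp, shortest reportable nucleotide hit
    cluster_identity: float = 90.0  # % identity for single-linkage clustering
    cluster_length_coverage: float = 0.0  # no coverage requirement
    copy_complete_cov: float = 0.95  # subject coverage for a complete copy
    region_margin: int = 500  # bp added around the ORF span of a region
    copy_merge_gap: int = 30  # bp, same-subject hit/copy merging distance

    # element features
    flank_len: int = 49
    is_min_len: int = 700  # warning bounds only
    is_max_len: int = 3500
    ir_window: int = 50
    ir_min: int = 10
    ir_max_mismatch_frac: float = 0.3
    dr_min: int = 2
    dr_max: int = 20

    # structure / context
    nest_tolerance: int = 10  # bp absorbed at reconstructed junctions
    composite_max_distance: int = 20000
    composite_same_family: bool = False
    context_window: int = 5000
    dr_match_min: int = 4

    backend: str = "builtin"  # or "external" (NCBI BLAST+)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.backend not in ("builtin", "external"):
            raise ValueError(f"unknown backend {self.backend!r}")
        for key in ("protein_evalue", "complete_cov", "len_tol"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be non-negative")
        for key in ("same_is_similarity", "nt_identity", "cluster_identity"):
            v = getattr(self, key)
            if not 0 <= v <= 100:
                raise ValueError(f"{key} must be a percentage, got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "accessory_subjects" in data:
            data["accessory_subjects"] = tuple(data["accessory_subjects"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["accessory_subjects"] = list(data["accessory_subjects"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
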