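# isannot

**Offline identification and annotation of insertion sequences (ISs) in
prokaryotic replicons, driven by a curated IS reference library.**

Insertion sequences are the smallest autonomous mobile genetic elements of
bacteria and archaea: 0.7–3.5 kb transposable segments, usually a single
transposase gene delimited by short terminal inverted repeats (IRs) and
flanked by a short direct repeat (DR, the target site duplication created on
insertion). They are abundant, they rearrange genomes, and they are chronically
under- and mis-annotated: transposases hide behind labels like "integrase" or
"hypothetical protein", partial copies and MITE-like derivatives are skipped
entirely, and the DNA-level features (boundaries, IRs, DRs) that indicate
whether an element is intact are almost never recorded.

`isannot` re-annotates replicons against a reference library of expertly
described ISs, for microbial genomicists who need IS content at both the
protein and the nucleotide level. The pipeline:

1. **Protein stage** — collects candidate coding regions from the input
   annotation (GenBank), a de novo ORF enumerator (FASTA input; genetic code
   11), and a seeded six-frame translated search of everything left over.
   Candidates are compared with the library protein set by Smith–Waterman
   (BLOSUM62, affine gaps; significance as a Karlin–Altschul expectation
   value, e ≤ 1e−5), then classified by a decision tree over local and global
   alignments: **complete** (global subject coverage ≥ 0.95, length within
   ±5% of the subject), **partial**, **pseudogene** (internal stop or
   frameshift signature), or **unknown** (accessory-domain-level evidence
   only, kept for curator review). Attribution to *the same IS* requires
   > 97% amino-acid similarity; below that the ORF is a putative new IS of
   its family.
2. **Nucleotide stage** — classified ORF groups become candidate regions
   (ORF span ± 500 bp); regions are searched against the library nucleotide
   set (hits retained at > 95% identity), clustered by 90% single-linkage
   identity, and projected into genomic element boundaries. IRs are located
   reference-guided or de novo (reverse-complement match ≥ 10 bp, ≤ 30%
   mismatches), DRs as the longest exact duplicated flank word (2–20 bp),
   and 49-bp flanks are recorded. Genome regions with no IS-associated ORF
   are re-scanned for ORF-less partial copies and MITE-like derivatives.
3. **Structure & context** — intercalated clusters (an IS interrupted by the
   insertion of further ISs) are resolved into one interrupted parent plus
   nested children; DR words are cross-matched between copies (rearrangement
   evidence); composite-transposon candidate pairs are scanned; flanking and
   disrupted genes are reported per copy.
4. **Export** — a Table-1-style prediction summary, an editable TSV
   annotation table (every copy `pending` until a curator validates or
   rejects it), GFF3, per-IS JSON/text reports and a corrected GenBank file
   in which generically-labelled transposases are renamed
   `"<IS> transposase, <family> family"`.

A deterministic synthetic-fixture generator (`isannot.synthetic_fixtures`)
builds reference libraries and test genomes with implanted complete, truncated,
pseudogenized, nested and MITE-like copies plus machine-readable ground truth,
so the whole pipeline is testable offline.

## Worked example

```bash
# generate a small fixture: 3 implanted IS copies + decoy genes + library
isannot fixtures --preset small --seed 1 --out demo

# annotate it
isannot run -g demo/genome.gbk -l demo/library -o demo/out --mode annotate
```

which prints:

```
IS ORFs: 3 (complete 3, partial 0, pseudogene 0, unknown 0); total IS 3, different IS 3
```

meaning three IS-associated ORFs were found and all classified complete, and
they define three genomic IS copies of three distinct reference elements.
`demo/out/annotation_table.tsv` then holds one row per copy — for example

```
is_name  family  copy_id  start  end   strand  identity_nt  completeness  dr_seq ...
ISSyn1   ISF1    ISC0001  8001   9402  -       100.0        complete      TCGGAT
```

an `ISSyn1` copy on the minus strand at 8001..9402 (1-based inclusive) at
100% nucleotide identity, with the 6-bp target site duplication `TCGGAT`
recovered on both flanks. `demo/out/` also contains `summary.json`,
`copies.gff3`, per-IS reports under `reports/`, and `genome.annotated.gbk`
with `mobile_element` and `repeat_region` features added.

Prediction-only mode (`--mode predict`) stops after the protein stage and
region clustering and emits just the summary — a rapid estimate of IS content.

## Layout

```
src/isannot/
  reference_library.py   # the three-file IS library: load, validate, write
  genome_io.py           # GenBank/FASTA input, annotated GenBank export
  alignment.py           # pairwise alignment primitives + e-value scale
  protein_stage.py       # ORF discovery, library search, decision tree
  nucleotide_stage.py    # regions, clustering, boundaries, IR/DR detection
  structure_context.py   # nested-IS resolution, DR matches, genome context
  reporting_export.py    # summary, annotation table, GFF3, per-IS reports
  synthetic_fixtures.py  # deterministic fixture generator + ground truth
  pipeline.py            # orchestration (predict / annotate)
  cli.py                 # `isannot run | fixtures | validate-library`
```

See `docs/methods.md` for the model, the thresholds and their defaults, and
known limitations.
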