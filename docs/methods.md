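# Methods

## The annotation model

`isannot` treats IS annotation as homology transfer from a curated reference
library, in two coupled layers. At the **protein layer**, transposases are
the diagnostic molecules: a genomic coding region is IS-associated exactly
when it has a significant local alignment to a reference IS protein, and its
*state* (complete, partial, pseudogene, unknown) is decided from the geometry
of that alignment. At the **nucleotide layer**, the element — not the gene —
is the unit: boundaries are the genome projection of an alignment to the
reference element, and the DNA-level features that indicate mobility
(terminal inverted repeats, target site duplication) are derived directly
from the replicon sequence at those boundaries. Everything downstream
(nesting, composite candidates, counts) operates on these per-copy records.

The pipeline is deliberately semi-automatic in spirit: every automatically
produced copy carries `validation_status=pending`, borderline calls (e.g.
conflicting family assignments at one locus) are reported and flagged rather
than suppressed, and a curator's edited table can be re-applied
(`apply_validation`) to drop rejected rows.

## Search machinery

**Pairwise alignment.** Local alignments are Smith–Waterman with affine gaps
(BLOSUM62, open −11 / extend −1 for proteins; +2/−3 with open −5 / extend −2
over the `ACGTN` alphabet for nucleotides, N scoring as a mismatch against
everything including itself). Global alignments are end-to-end
Needleman–Wunsch. Identity is matches over aligned columns, gaps included.

**Significance.** The builtin backend expresses local protein scores as
Karlin–Altschul expectation values, `E = K·m·n·exp(−λS)` with gapped BLOSUM62
constants (λ = 0.267, K = 0.041), thresholded at the configured
`protein_evalue` (default 1e−5). This places the builtin scorer on the same
scale as BLAST; seeded shuffled-protein nulls fall 2–3 orders of magnitude
short of the cutoff (exercised in the test suite). An external backend
(NCBI BLAST+, word sizes 3/7, low-complexity filters off) is available behind
the same hit contract; a scaled test asserts top-subject agreement ≥ 95% on
near-identical queries.

**Seeding.** The translated genome search and the nucleotide search are
seed-and-extend: exact words (4 aa / 11 nt) chained on diagonals (band 8 aa /
20 nt), with each chain verified by local alignment of a padded window. At
region scale this is exhaustive in effect while keeping a 200-kb annotate run
in a few seconds. Nucleotide hits are then trimmed to their outermost 8-bp
exact-match runs, so a hit never ends on chance matches straggling past a
biological boundary — this is what keeps boundary and truncation-scar
placement at single-base accuracy on high-identity copies.

## The decision tree (protein classification)

Order matters; the first matching rule wins:

1. no hit at `protein_evalue` → **none** (not IS-associated);
2. internal stop codon, or a frameshift signature (adjacent-frame or
   stop-split translated hits to one subject ORF merged into one candidate)
   → **pseudogene**;
3. global alignment against the best subject: subject coverage ≥
   `complete_cov` (0.95) *and* query length within `len_tol` (5%) of the
   subject → **complete**;
4. all significant hits are to accessory/passenger subjects at partial
   coverage (domain-level evidence, e.g. an IstB-like ATP-binding domain or a
   tyrosine/serine recombinase) → **unknown**, retained for review — a full-
   coverage match to an accessory gene is a genuine IS gene and classifies
   under rule 3/5 instead;
5. otherwise → **partial**.

Attribution: the best hit's family is assigned; `same_is` requires > 97%
amino-acid similarity (`same_is_similarity`), below which the ORF is tagged
"putative new IS" (or "putative new family" when nothing hits at family
level). Whether the 97% figure should be read at the nucleotide or amino-acid
level is ambiguous in the field's usage; it is treated as amino-acid
similarity (positive-scoring BLOSUM62 columns) here, and it is a config key.

Same-strand ORFs attributed to the same reference within `group_max_gap`
(1500 bp) are grouped into one element candidate (multi-ORF elements,
programmed frameshifts).

## Nucleotide stage

A group's **candidate region** is the span from the first ORF's start to the
last ORF's end, extended by `region_margin` (500 bp) each side: IRs and
element ends lie outside the ORFs, and the margin makes their search local
rather than genome-wide. Retained nucleotide hits need identity strictly
above `nt_identity` (95%). Regions are clustered by single-linkage at
`cluster_identity` (90%) with no length-coverage requirement; pairwise
identity is `1 − edit_distance / max(length)` (best strand), computed with
edlib, and the clustering is union-find (an independent BFS oracle checks it
in the tests).

**Copies.** Per subject, colinear hits separated by ≤ `copy_merge_gap`
(30 bp) on the genome merge into one copy (an internal deletion — a MITE —
appears as exactly such a pair); a candidate overlapping a better one by
≥ 50% is dropped if same-family, kept-but-flagged if contradictory.
Completeness requires aligned subject coverage ≥ `copy_complete_cov` (0.95).
Copies clipped at a region margin are joined with their ORF-less remainder by
the same adjacency-merge rule, with a guard that merged fragments must cover
near-disjoint reference intervals (so genuine tandem copies never collapse).

**IRs.** Reference-guided mode places the reference's IRs in the terminal
windows (`ir_window` = 50 bp) by best ungapped placement, accepting ≤
`ir_max_mismatch_frac` (0.3) per side; de novo mode scans the left window
against the reverse complement of the right window for the best ungapped
segment of ≥ `ir_min` (10 bp, score = matches − 2·mismatches). Either way the
reported pair satisfies, verbatim on the replicon, "right = reverse
complement of left up to the reported mismatch count". A consequence of the
10-bp default minimum is that very short IRs (< 10 bp) are only found in
reference-guided mode or with a lowered `ir_min`.

**DRs.** The longest k ∈ [`dr_min`, `dr_max`] = [2, 20] with the k bases
immediately 5′ of the element exactly equal to the k bases immediately 3′ of
it. Exact identity is demanded — mismatched "DRs" are biologically ambiguous
— and searches truncate at replicon edges.

## Intercalated clusters

Fragments of one reference element are joined when (i) the genomic gap
between them is tiled by intact copies (chains allowed; innermost structures
resolved first, so nesting of any depth reduces level by level) with
junctions within `nest_tolerance` (10 bp), and (ii) their reference intervals
are contiguous within the same tolerance. Before measuring the reference
junction, any genome overlap between a fragment's alignment and the inserted
copies is trimmed off — alignments habitually run a few bases across the
duplicated target site — so the recorded `junction_gap` is the inner
element's DR length, not DR plus jitter. The resolved parent spans all its
fragments and children, is marked `interrupted`, and counts **once** in
`total_is` (naive fragment counting would report it twice).

## Synthetic fixtures: what they emulate, and what they do not

The generator emulates the *structure* of the problem: elements 0.7–3.5 kb
with 10–25 bp terminal IRs, one or two ORFs (transposase always; an accessory
gene in ~40% of elements) and a characteristic DR length of 2–12 bp;
family structure via founder transposases mutated codon-wise (within-family
identity ≥ 50%, across-family < 30%, verified after generation and
regenerated on violation); insertion with real target-site-duplication
mechanics; 5′/3′ truncation, internal (MITE-like) deletion, pseudogenizing
stop substitutions, and nesting with per-level bookkeeping of spans.

Two anti-ambiguity rules make ground truth exact rather than approximate:
background bases adjacent to an insertion are resampled if they would, by
chance, extend the terminal duplication beyond the one created (so the
recorded DR *is* the longest detectable one), and the two background bases
beyond a truncation scar are forced to mismatch the reference continuation
(so the truncation boundary is well-defined). Nested insertion sites that
cannot be made clean are retried at a shifted offset instead of edited,
because their flanks are parent sequence.

What the fixtures do **not** emulate: realistic codon usage or GC skew,
transposase sequence families as they actually diverge (substitution only,
uniform rates), insertion-site preference, tandem arrays, or repeats in the
background other than the implants. Passing the implant-and-recover tests
therefore demonstrates the machinery — search, boundary projection, repeat
detection, nesting resolution, bookkeeping — not robustness to the full
messiness of real genomes; on real data, recall is bounded by library
coverage (an element with no relative in the library is invisible, by
design), and borderline identities near the 95%/97% cutoffs will behave less
crisply than the fixtures.

Study-condition sizes: the full scenario is a 200-kb replicon, twelve
implants at 100% identity over a 3-family/6-element library; sweeps use
20–40-kb genomes with 1–3 implants; clustering oracles use 300–600-bp
regions. These sizes make the whole suite run in well under a minute while
exercising every code path; all of them are ordinary function arguments and
scale up without code changes.

## Numerical and design choices

* Coordinates are 0-based half-open internally, 1-based inclusive in files.
* Ties in hit lists break on (e-value, −score, subject name); region-cluster
  output preserves first-appearance order; all randomness is injected
  `numpy` generators seeded from function arguments — identical inputs give
  byte-identical outputs.
* Circular topology is read and preserved, but candidate regions and
  features are not wrapped across the origin; an origin-spanning element
  would be reported as two fragments.
* The e-value constants are fixed scale factors, not fitted quantities; with
  the external backend, BLAST's own e-values are used unchanged.
* The prediction-only path counts `total_is` as the number of element
  candidates (ORF groups); ORF-less copies are only discoverable in full
  annotate mode, so predict ≤ annotate on genomes containing MITEs or
  ORF-less fragments.
* `composite_max_distance` (20 kb) has no field-standard value; pairs beyond
  it that still share a DR word are emitted as rearrangement notes instead
  of candidates.
* Degenerate inputs: empty replicons are rejected at parse time; an empty
  library is a fatal error; searches shrink their windows at replicon edges
  (flanks shorter than 49 bp are reported at their actual length, never
  padded).

## Known limitations

* No profile/HMM remote homology: detection requires a relative in the
  library at local-alignment significance.
* De novo discovery of entirely novel families from IR/DR signatures alone
  is out of scope, as is genome-wide solo-IR cataloguing.
* The ORF enumerator is a plain stop-to-stop scanner with a homology filter,
  not a trained gene model; unusual starts or very short transposases rely
  on the translated search to be recovered.
* Alternative genetic codes are not supported (code 11 is fixed).
* The external BLAST backend covers blastp/blastn; the translated search is
  always builtin.
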