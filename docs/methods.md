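# Methods

This note documents the models, rules and numerical choices behind each
stage, what the synthetic generators emulate (and deliberately do not),
and the design decisions taken where the problem was genuinely open.

## Coordinates and formats

Internally every interval is 0-based half-open; external formats keep
their native conventions (GFF3 and the orthologue table are 1-based
inclusive, FASTA domain hits 1-based inclusive). The conversion happens
exactly once, in `io_formats`, so no downstream module reasons about
off-by-ones. Minus-strand CDS segments are stored in transcription order
(highest genomic coordinate first) so intron logic never branches on
strand. Overlapping domain hits on one protein are merged to the widest
envelope, reflecting the single-bHLH-domain family model.

## Domain anchoring

Residue-position rules are defined on a canonical 60-column frame.
Each extracted domain is globally aligned (BLOSUM62, affine gaps open
10 / extend 1, biopython's deterministic first optimal alignment)
against a single reference domain; reference residue *i* defines
column *i*, query residues inherit the column of the reference residue
they pair with, and residues opposite reference gaps are recorded as
insertions without a column. Records covering < 50% of the columns are
flagged "poorly anchored" but kept.

The default reference (`DEFAULT_REFERENCE_DOMAIN`) is a **synthetic
consensus anchor**: a 60-mer assembled from the family's per-column
consensus residues (H-9, E-13, R-14/15/16/17 in the basic region,
N-21/L-27/P-32 in helix 1, K-36 in the loop, K-39/L-43/I-47/Y-49/L-53
in helix 2), with unconserved columns filled deterministically. It is
not a database sequence. Single-reference anchoring can differ from a
full-MSA numbering near indels; for exact reproduction of published
column numbers, ingest the published alignment via
`anchor_from_msa_row` (the reference row then defines columns) or swap
a real reference domain into `CanonicalScheme`.

Region boundaries default to basic 1–17, helix 1 18–33, loop 34–38,
helix 2 39–60 — consistent with every labelled consensus position —
and are configurable.

## DNA-binding classification

The decision tree is: basic-residue count (H/K/R over columns 1–17)
< `min_basic_count` → NON_BINDING; else E-box rule (Glu-13 **and**
Arg-16) → else NON_EBOX_BINDER; among E-box binders His-9 →
GBOX_BINDER else EBOX_NON_GBOX. A gap at a required column counts as
absent — non-binders are typically proteins lacking the basic region
altogether.

`min_basic_count` defaults to 5 of {H,K,R} across the 17 basic columns.
The classical criteria this family of surveys builds on never print the
exact threshold; 5 is the established value in that lineage, and the
CLI exposes `--min-basic-count` because reproducing a specific
published binding/non-binding split may require sweeping it. Only
columns 9/13/16 participate in the E-/G-box rules by default; columns
14/17, though conserved, are not part of the printed rules and are left
out (the rule set is data, not code).

## Intron patterns

For each junction between consecutive CDS segments, the coding offset
*o* gives phase *o* mod 3. The domain covering amino acids
*s*..*e* owns coding nucleotides [(s−1)·3, e·3) — half-open, so a
junction exactly at the domain's first codon boundary is inside and one
at the last codon's end is outside (the boundary must be fixed for
counts to be deterministic). For phase-0 junctions the domain codon
index is the codon after which splicing occurs; phase-1/2 junctions
interrupt their codon. The codon index is translated to a canonical
column through the protein's anchoring.

The pattern catalog is configuration, not code: the conserved slots are
defined graphically in this kind of survey and no coordinates are
printed, so the package ships an editable TSV
(`data/pattern_catalog.tsv`) with package-chosen defaults — three
conserved phase-0 slots at columns 10/27/50 (patterns I–VI are their
non-empty combinations), two less-conserved phase-1 slots at columns
20/40 (patterns VII–IX), and X for intron-free — with a ±2-codon
matching tolerance. Patterns are assigned by matching each observed
(column, phase) to a distinct slot; an empty list is X; no catalog
entry matching yields "unclassified" rather than a forced label.

## Phylogeny

*Distances.* p-distance under pairwise deletion (sites gapped in either
sequence are ignored; zero comparable sites → undefined), then Poisson
correction d = −ln(1 − p). Saturated or undefined pairs are capped at a
configurable maximum (default 5.0 substitutions/site) with a warning —
a finite cap keeps NJ defined where a strict implementation would fail.

*Neighbor joining* is authored here (Saitou–Nei, Studier–Keppler
update). Exact Q-ties are broken toward the lexicographically smallest
pair of cluster labels (each cluster labelled by its smallest leaf
name), which makes the topology deterministic and independent of input
row order up to floating-point summation order; the Q matrix is
computed as (k−2)·d − (r_i + r_j) with the row sums added first so it
is exactly symmetric in floating point. Negative branch lengths are
clamped to zero with the deficit moved to the sibling edge. On additive
matrices the algorithm is exact (tested against a brute-force
least-squares topology search and dendropy's independent NJ).

*Bootstrap.* A single seeded generator pre-draws an
(n_reps × L) column-index array; replicate *r* consumes exactly row
*r*, so supports are reproducible and invariant to leaf order. Support
for an internal edge is the percentage of replicate NJ trees containing
its bipartition (compared by normalized split bitmask on a shared taxon
namespace).

*Subfamily extraction.* Clades need a root. The root is placed at the
**internal node nearest the tree midpoint** (two-sweep diameter walk,
deterministic tie-breaks), giving a basal multifurcation the way family
trees are usually displayed. Bisecting the midpoint edge instead would
duplicate that edge's split across both root edges, letting a supported
clade's complement masquerade as a huge supported "clade" and swallow
the real structure under maximal-clade extraction. Subfamilies are then
the maximal clades whose subtending edge support meets the threshold
(default 50%); uncovered leaves are singletons, and the clusters always
partition the leaf set.

## Orthologue mapping

Global identity uses Needleman–Wunsch (match 1 / mismatch 0, affine
gaps open 10 / extend 0.5) with identity = matches / alignment columns.
The gap-inclusive denominator is the stricter convention and the
default (a gap-excluded mode exists); published tables rarely state the
denominator, so it must be pinned for determinism. A pair qualifies
when **both** CDS and protein identity reach the threshold (default
80%). Each gene keeps its best partner on the other side and the union
of both directions is returned, so duplicates produce one-to-many pairs
— the packaged 120-pair table shows five such genes. Synteny is
operationalized as equal chromosome numbers, which exactly reproduces
the printed syntenic count (101 of 120; 19 printed pairs cross
chromosome numbers); genes without a chromosome get an "unknown" flag
and are excluded from syntenic counts. A shared-12-mer prefilter skips
clearly unrelated pairs before alignment; at the 80% threshold true
pairs share many exact 12-mers while background-level pairs share
almost none, so the filter is a speed knob, not a sensitivity one.

## Expression rules

All calls operate on raw RPKM; log2(v + 1) is only an export for
heat-map-style downstream use. *Expressed* is strict: max RPKM > 2
(a gene peaking at exactly 2.0 is not expressed). *Tissue-specific*
aggregates to tissue means and requires the top tissue to exceed both
the floor (2) and 2× the maximum of all other tissue means — the
strictest natural reading of "2-fold higher than in other tissues"; a
sample-max variant sits behind a flag, and at most one tissue per gene
can qualify by construction. *Stage trends* are made explicit since
"gradual increase/decrease" is informal: stage means must be monotone
within a tolerance (default 0), the endpoint ratio must reach the fold
threshold (default 2), and the gene must be expressed. Orthologue-pair
correlation is Pearson's r on log2(v + 1) profiles (the conventional
default for unspecified correlation analyses); constant profiles are
undefined (NaN), not zero. 2^−ΔΔCt returns exactly 1 for the
calibrator by construction. The equal-variance t-test handles the
zero-pooled-variance degeneracy explicitly (equal means → p = 1,
unequal → p = 0) instead of emitting NaN.

## Synthetic data: what it emulates, and what it does not

Every generator is a bit-reproducible function of (spec, seed), and
every planted truth is recovered by its paired analysis module at the
default settings — by construction, with margins, not by luck:

- **Families** (`generate_family`): random flanks + a reference-derived
  domain whose rule columns force the planted category; substitutions
  (default rate 0.15) touch only columns 18–60 so planted basic counts
  survive. The guaranteed basic count is 6 for binders and 0 for
  non-binders, hence `min_basic_count` > 6 is rejected as impossible.
  The default simulated AA-like family plants 75/24/5/28 across the
  four categories (a 132-protein family: 104 binding, 99 E-box, 75
  G-box).
- **Loci** (`generate_gene_models`): one contig per locus, alternating
  strands, exons = CDS (no UTRs), fixed-length GT…AG introns planted at
  the catalog slots; proteins reverse-translated with one preferred
  codon per amino acid. Domain substitution rate 0.05 without indels,
  so anchoring is gapless and the slot→column round trip is exact.
- **Subgenome pairs** (`generate_subgenome_pair`): codon-level
  mutations at the requested divergence with a 0.5 synonymous bias, so
  CDS identity stays above what the protein changes alone imply —
  mirroring the CDS-vs-protein identity gap real orthologue tables
  show. Decoys are independent random genes (background identity far
  below threshold). Chromosomes are assigned round-robin with a
  configurable number of cross-chromosome (non-syntenic) pairs; the
  defaults used in the acceptance run plant 120 pairs with 19 crossing,
  i.e. 101 syntenic.
- **Expression** (`generate_expression`): 22 samples = 8 tissues
  (1 sample each) + stages S1–S6 with 2–3 replicates; log-normal
  multiplicative noise, σ = 0.15 on the natural-log scale. Margins are
  structural: silent genes peak below 0.8 RPKM (vs the threshold of 2),
  plain expressed genes sit at 4–40, specific genes at 30 vs 1.2
  elsewhere (≈ 25-fold vs a 2-fold rule), trend genes double per stage
  and hold near-peak levels in all non-stage tissues so they can never
  double as tissue-specific calls. The default allocation plants 99
  expressed genes of 132, 22 tissue-specific across six tissues, and
  8 + 8 stage trends.
- **Subfamily alignments** (`generate_subfamily_alignment`): group
  marker blocks plus one private column per member and **no** iid
  noise. The construction is exactly symmetric — all within-group
  member distances equal, all between-group member distances equal — so
  the only bootstrap-consistent signal is the group clades themselves.
  This is deliberate: under column resampling, any fixed asymmetry
  (even one coincidental residue match between two groups) recurs in
  every replicate, and measurement showed such accidents can push a
  spurious super-clade past 50% support. With the symmetric design the
  worst super-clade support observed across 20 seeds is 28%.

None of the generators emulate indels inside domains, UTRs or
alternative splicing, genome-level features (repeats, GC skew),
read-level RNA-seq noise, or realistic phylogenetic depth. Passing
round-trips therefore demonstrate the correctness of the rules and
coordinate logic under the stated statistical structure — not
robustness to misannotated gene models, fragmented domains, or
biological noise beyond the planted models.

## Problem sizes

The simulated conditions mirror the study's printed margins: a
132-protein family, 104 gene models across the ten intron patterns, a
120-pair subgenome bundle (~100-codon genes) plus 12 decoys per side,
a 132 × 22 expression matrix, and a 20-taxon subfamily alignment with
200 bootstrap replicates (1000 remains the CLI default for real
analyses). The whole test suite and the acceptance script each run in
well under a minute on one CPU.

## Known limitations

- Single-reference anchoring can misnumber columns near indel-rich
  domains; prefer MSA ingestion for published numbering.
- The binding rules are sequence heuristics; no structural or
  partner-dependent binding is modelled.
- Orthology is identity-threshold-based; it does not chain collinear
  blocks, estimate Ks, or use tree reconciliation, so tandem arrays may
  produce extra qualifying pairs by design.
- Subfamily counts are alignment- and threshold-sensitive; the package
  guarantees the extraction semantics, not any particular published
  subfamily count.
- No multiple-testing correction is applied to t-tests (single-gene
  qPCR comparisons).
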