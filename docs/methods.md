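# Methods

## Model

Mapping contamination is a property of the reference sequence: if a
read of length k originating inside gene *A* can also be placed inside
gene *B* within the aligner's mismatch tolerance, quantified expression
leaks from *A* to *B* regardless of sample quality. We summarise this
risk with two quantities computed from genome FASTA + GTF alone.

**Mappability.** Every k-mer starting inside a gene's exonic (k = 75)
or UTR (k = 36) intervals is aligned genome-wide, gaplessly, on both
strands, allowing up to m = 2 mismatches. A k-mer with C placements has
mappability 1/C; a region's mappability is the mean over its k-mers; a
gene's is the length-weighted average of its exonic and UTR components
(components with no k-mer are dropped from the average together with
their weight). A gene in which every exon is shorter than 75 bp *and*
every UTR shorter than 36 bp hosts no k-mer at all and is
**undetermined**: it is reported as `NA` and excluded from the
cross-mappability computation as both source and target, since no
k-mer evidence exists in either direction.

**Cross-mappability.** crossmap(A, B) counts the k-mers of *A* (exon
k-mers and UTR k-mers pooled) with at least one alignment whose
leftmost genomic coordinate falls inside *B*'s collapsed exon∪UTR
intervals. Each k-mer contributes at most once per target gene even if
it aligns to several positions in that gene. Pairs with count 0 are
omitted from the resource. The measure is directional; both directions
are computed.

**Flagging.** A trans test (variant v, gene T) is *cross-mappable* when
some gene with TSS within 1 Mb of v cross-maps to T. The default
direction is `either` (crossmap(G, T) > 0 or crossmap(T, G) > 0):
contamination physically flows source→target, but annotation
truncation and assembly asymmetries make the observed direction
unreliable, so the symmetric test is the safer screen; `a_to_b`
restricts to the mechanistic direction. `refilter_and_reassess` drops
flagged tests and recomputes Benjamini–Hochberg FDR on the remainder,
so the multiplicity burden reflects only the tests actually retained.

## Algorithms and numerical choices

- **Alignment** is exact Hamming search, not a heuristic: the k-mer is
  split into m + 1 disjoint seed blocks of length ⌊k/(m+1)⌋; by the
  pigeonhole principle any placement with ≤ m mismatches matches at
  least one block exactly, so candidates found through an exact q-gram
  hash index and verified by early-exit Hamming comparison recover the
  complete placement set. Reverse-complement placements are found by
  aligning the reverse complement and reporting the leftmost
  coordinate. `N` never matches anything, including another `N`.
  k-mers containing `N` fall back to an exhaustive scan when the `N`
  count is within budget, otherwise they have no placements.
- A **brute-force oracle** (`brute_force_oracle`, a vectorised full
  scan independent of the seeded path) exists purely for verification;
  the test suite asserts set-equality of (position, strand, mismatch
  count) over hundreds of randomized genomes.
- **Shortcuts** (skipping genes with mappability exactly 1, and
  skipping k-mers with a unique placement) are provably
  output-preserving — a uniquely-placed k-mer can only land in its own
  gene — and the `use_shortcuts=False` path is kept and tested for
  equivalence.
- **Association** uses OLS with optional covariates. The matrix scan
  residualises expression and genotypes on the covariates and converts
  correlations to t statistics (Frisch–Waugh), with
  df = n − n_covariates − 2; the suite verifies equality with per-pair
  OLS. FDR is Benjamini–Hochberg (`statsmodels`). The co-expression
  comparison uses |Pearson r| on residualised expression and a
  one-sided Wilcoxon rank-sum test (exact for tiny inputs, asymptotic
  otherwise); weighted pair sampling without replacement uses
  exponential-key (Efraimidis–Spirakis) sampling, which matches
  sequential conditional draws.

## Parameters and defaults

| parameter | default | unit | rationale |
|---|---|---|---|
| k (exon) | 75 | nt | typical RNA-seq read length used for exonic quantification |
| k (UTR) | 36 | nt | shorter k for UTRs, which are shorter and lower-complexity |
| mismatches m | 2 | nt | common aligner tolerance for these read lengths |
| cis window | 1,000,000 | bp from TSS, inclusive | standard cis-eQTL window; also the flagging neighbourhood |
| MAF threshold | 0.05 | fraction, inclusive | conventional common-variant cut-off |
| FDR level | 0.05 | — | conventional BH level |

Annotation handling: GTF coordinates (1-based, inclusive) are converted
to 0-based half-open; exon intervals per gene are unioned; UTR
intervals are subtracted from exons by default (`utr_subtraction`
switch) so every base belongs to exactly one component and gets exactly
one k; TSS is the 5′ end of the collapsed span by strand.

## The synthetic generator

`crossmappability.simulate` builds study-scale instances that emulate
the contamination mechanism: i.i.d. uniform-ACGT chromosomes; genes
with configurable exon/UTR structure; *planted duplications* that copy
a segment from a source gene into a target gene at a chosen Hamming
distance (collisions with spontaneous repeats trigger regeneration
under a shifted seed); a *truth table* of exact crossmap counts per
mismatch budget computed by an independent naive route; expression in
which the target receives α × source plus noise; and a cis variant at
TSS − 1000 of the source with dosage ~ Binomial(2, MAF = 0.3 — common
enough that a 500-sample study is well powered without being tuned)
and additive effect β on the source, hence αβ on the contaminated
target. The study-level defaults (n = 500 samples, α = 0.5, β = 1) are
the generator's fixed conditions.

What the generator does **not** emulate: realistic base composition or
repeat families, splicing/isoforms, read-level sampling noise
(contamination is injected at the expression level, which is the
quantity the downstream statistics see), population structure or LD,
and indels (the alignment model is gapless by design).

## Limitations

- Hamming-only alignment ignores gapped placements; counts are a lower
  bound relative to an indel-aware aligner.
- Flagging is conservative in the `either` direction: it removes true
  trans signals between sequence-similar genes along with artifacts.
- The per-gene mappability average weights components by interval
  length, not k-mer count; the two differ at interval edges.
- Genome-scale runs are CPU-bound in the alignment step; the
  implementation is single-threaded and sized for study-scale and
  method-evaluation use.
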