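# Methods

This note documents the models, numerical choices, and deliberate
simplifications behind `introshift`, in the spirit of a package vignette.

## Coordinate conventions

All internal coordinates are 0-based, half-open. GTF I/O is 1-based
inclusive; BED and UCSC rmsk genoStart/genoEnd are 0-based half-open. The
conversion happens exactly once, at parse/write time. The rmsk reader
accepts the 17-column UCSC table dump (with `bin`), the 16-column variant,
a simplified 7-column seq/start/end/strand/name/class/family layout, or a
GTF; auto-detection is by file extension and column count and can be
overridden.

## Negative-annotation construction

Intron space is `subtract(union of gene spans, union of all exons)`,
computed with the package's own merge/subtract primitives (sorted-sweep on
integer breakpoints). Properties that the tests enforce per-base on random
genomes:

- merged exon bases and intron bases are disjoint and their union equals the
  merged gene-span bases (exact partition);
- a gene whose exons tile its whole span contributes no intron;
- the construction is idempotent and order-independent.

Subtraction is strand-blind by default: an exon removes intronic bases from
overlapping genes on either strand, which matches `bedtools subtract`
without `-s` and makes the construction safe for overlapping genes. A
strand-aware mode subtracts per strand (unstranded records participate in
both groups); it exists because the strand convention of the original
procedure is not documented anywhere, and neither mode is claimed to be
"the" published one.

Intron intervals are split wherever the set of containing gene spans
changes, so every stored interval is wholly inside each of its host spans
and carries all host gene ids comma-joined. Per-gene counting treats such a
shared interval as a single joint key; this over-fragmentation is merged
back wherever adjacent pieces share a host set. No minimum intron length is
imposed.

## Fragment filtering and counting

A record is *uniquely mapped* when its NH tag equals 1, or, if NH is
absent, when MAPQ ≥ 30 (configurable). Secondary, supplementary, unmapped
and duplicate-flagged records are dropped. Mates of a pair on one sequence
are merged to the hull interval (one unit per sequenced fragment); mates on
different sequences are discarded. Counting is unstranded.

Assignment follows featureCounts defaults: ≥ 1-base overlap; a fragment
overlapping features of two or more distinct grouping keys (gene id for
exon/intron, locus for repeats) is ambiguous and assigned to nothing; a
fragment overlapping several features of one key counts once. The
implementation labels disjoint breakpoint segments with their covering key
sets and unions the labels each fragment touches; the tests compare it
against all-pairs overlap enumeration. Feature length is the merged base
count per key.

Compartment percentages are three *independent* counting passes (exon,
intron, repeat annotations each against all fragments), mirroring an
analysis that runs the counter once per annotation. Because repeats are
largely intronic, intron and repeat percentages overlap and the four
compartments do not total 100; this is intentional and is what makes the
intron percentage a usable intron-retention proxy.

## Paired shift test

Per compartment, per-subject percentages at T0 and T1 enter a paired
Student t-test: t = d̄/(s_d/√n), df = n − 1, p from the t CDF (no normal
approximation). The default is one-sided in the direction of the observed
mean difference because that is the variant consistent with the published
p-values this package reproduces (0.029/0.008/0.028 at three decimals; the
two-sided values are 0.058/0.017/0.057 and are always reported alongside).
Zero-variance difference vectors are flagged degenerate and carry no
p-value. Percentages are kept at full precision; rounding (2 decimals for
means/deltas, 3 for p) happens only in report rendering.

## Differential expression

The DE stage is a deliberately compact re-implementation, comparable in
kind — not numerically identical — to DESeq2:

- **Filter:** a feature is excluded when its FPKM
  (count / (length/10³ · library/10⁶)) is below 5 in ≥ 80 % of samples.
  The published filter sentence conflates a mean criterion with a
  per-sample one; the per-sample reading is the default and the mean-based
  reading is available via `mode="mean"`. The same filter is applied to
  repeats.
- **Normalization:** median-of-ratios size factors (median over features
  nonzero in every sample of count/geometric-mean). With no such feature,
  upper-quartile factors scaled to geometric mean 1 (logged fallback).
- **Test:** Wald test on log2(m₁+½) − log2(m₀+½) of normalized condition
  means. Per-feature NB dispersion is a pooled within-group
  method-of-moments estimate α̂ = (s² − μ)/μ², shrunk 50/50 toward the
  across-feature mean and floored at 0.01 — a pragmatic stabilizer at
  n = 5 + 5 (both knobs configurable). The variance of a group mean uses
  the delta method: Var(m) = (m·Σ1/s_i + α m² n)/n². The 0.5 pseudocount
  guards zero-containing features; all-zero features are reported NS with
  p = 1.
- **Calls:** UP iff log2FC ≥ +1 and BH q < 0.05; DOWN iff ≤ −1; the
  inclusive ≥ follows the results-section convention. BH adjustment is
  statsmodels' step-up.
- **Pairing:** off by default (two-group), since the original design
  matrix is not documented; `paired=True` tests per-subject log2 ratios
  with a one-sample t-test.

Not replicated from DESeq2: dispersion trend fitting and MAP shrinkage,
Cook's outlier filtering, independent filtering, shrunken LFCs. On data
where most effects point one way, median-of-ratios factors absorb part of
the signal and fold changes shrink toward zero — visible in this package's
own tests and a caveat shared with any global-scaling normalization.

Full-length LINE-1 testing reuses the same stage restricted to the supplied
L1 annotation, with one important difference: size factors come from the
*full* repeat matrix, because a handful of L1 loci moving coherently would
otherwise normalize their own signal away. Loci removed by the expression
filter are reported NS so every annotated locus appears in the output. When
no curated full-length annotation exists, a heuristic selector (family L1,
length ≥ 6 kb) is provided for synthetic runs; it is a stand-in, not a
definition of retrotransposition competence.

## Repeat integration

Modulated repeats are classified by ≥ 1-base overlap with precedence
exonic > intronic > genic-other > intergenic (a repeat touching exon
sequence is exonized by definition); the classes partition the repeat set.
Host gene ids and their modulation status (from the exon-compartment DE)
are attached; location is counted per locus, not per base. Modulated
repeat × modulated intron matches are all overlapping pairs, verified
against all-pairs enumeration. Gene-set overlap partitions the DEG union
into exon-only / intron-only / both ("full gene"); gene sets are plain id
lists, with no ontology traversal.

## Synthetic data generator

The generator emulates the structure of the motivating study, not its
sequences: 5 subjects × 2 conditions; three 100 kb chromosomes; 36
multi-exon genes (2–5 kb, 3–7 exons, 10 % placed overlapping another gene);
repeats nested entirely inside intron or intergenic intervals at 0.5 loci
per kb of eligible space, class-weighted LINE 47 % / SINE 24 % / DNA 12 % /
LTR 9 % with class-typical lengths; three full-length L1 loci (6–7 kb)
placed in intergenic space *before* the small repeats so large gaps remain
available.

Fragments are drawn per sample as a multinomial over five disjoint spaces —
exon, intron-minus-repeats, intronic repeats, intergenic repeats,
intergenic-minus-repeats — with the condition's target proportions
(defaults: T0 exon .563/intron .232/repeat .143; T1 .534/.276/.158; 60 % of
repeat draws go to intronic repeat space, which the intron target already
contains). Fragments (150 bp, clipped to their interval) lie wholly inside
their drawing space, so the observed overlap percentages equal the drawn
shares by construction and the generator's targets are recovered up to
multinomial error. A per-subject offset (sd 0.01, proportion scale) shared
between the subject's two samples plus independent per-sample noise
(sd 0.005) provides realistic between-subject structure; the shared offset
cancels in the paired test, which is exactly why the paired design helps.

Counts are NB draws via the gamma–Poisson mixture, mean
baseline·size·2^(lfc·1[T1]), lognormal baselines (median 100) and sizes,
dispersion 0.1 by default (Poisson below 10⁻⁸); a configurable fraction of
features receives effects of |log2FC| ≥ 1 with random sign. A single seed
drives per-stage `SeedSequence` spawns, so annotation, fragments and counts
are reproducible independently; identical seeds give byte-identical files.

What the generator does **not** emulate — and what passing tests therefore
do not show about real data: sequence content and mappability (fragments
are intervals, not reads; alignment is out of scope), splice-junction
reads, GC and positional bias, per-feature fragment-level DE coupled to the
compartment shift, and the full between-subject heterogeneity of real
cohorts (the observed per-subject spread in the published table, ~2.5
percentage points in the paired differences, is larger than the generator's
default ~0.7; the generator is deliberately conservative here).

## Problem sizes in the tests

Interval-algebra oracles run on 200 random genomes of 2–30 kb; counting
oracles on 50 instances up to 10⁴ fragments × 10³ features; DE error-rate
checks on 2000-feature matrices at three seeds; end-to-end shift recovery
on three replicate simulations at 200 000 fragments per sample. These sizes
make the full suite run in a few minutes while keeping every comparison
against an independent brute-force computation.

## Known limitations

- The NB Wald test is anticonservative for very small dispersions combined
  with tiny counts; the floor and shrinkage mitigate but do not remove
  this. For publication-grade inference on real data, confirm calls with a
  full DESeq2/edgeR analysis.
- Ambiguity handling is per compartment; a read spanning an exon–intron
  junction of one gene legitimately counts in both compartments' separate
  passes.
- Multi-mapper rescue (TEtranscripts-style EM) is out of scope; repeat
  counts reflect uniquely mapped fragments only, which under-counts young,
  high-identity repeat families.
- LiftOver, isoform-level (differential exon usage) analysis, and GO
  enrichment statistics are outside the package; consume pre-lifted
  annotations and export the gene lists instead.
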