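# introshift

Compartment-level transcriptome analysis for paired RNA-seq designs.

Bulk RNA-seq pipelines typically stop at gene-level expression computed from
exon counts. `introshift` is built for the question those pipelines skip:
*where in the genome does transcription move under an acute stimulus?* It was
designed around a paired study design — peripheral blood mononuclear cells
from the same subjects sampled at rest (T0) and immediately after strenuous
exercise (T1) — in which the interesting signal is a shift of aligned
fragments out of exons and into introns and repetitive elements (intron
retention and transposable-element activation), not a change in any single
gene.

The package is aimed at bioinformaticians analysing paired bulk RNA-seq who
want intron- and repeat-aware quantification without assembling a bespoke
chain of `bedtools`/`featureCounts`/DESeq2 glue scripts.

## What it computes

**1. Negative (intron) annotation by interval subtraction.** From an
Ensembl-dialect gene GTF, intron space is constructed genome-wide as

```
introns = (union of all gene spans) − (union of all exons of all isoforms)
```

Both unions are taken before subtracting, so the construction needs no choice
of a representative transcript and is correct for overlapping genes: an exon
of gene B removes bases from an intron of gene A that contains it. Each
intron interval carries the id(s) of every gene span containing it. Exon,
intergenic and repeat (RepeatMasker rmsk table, name/class/family preserved)
compartments are built the same way.

**2. Compartment quantification.** Uniquely mapped fragments (NH tag = 1, or
MAPQ ≥ 30 when NH is absent; mate pairs merged to one interval) are counted
against each compartment with featureCounts-default semantics: ≥ 1-base
overlap assigns, a fragment touching two different grouping keys is ambiguous
and dropped, multiple features of one key count once. Per-sample compartment
percentages are computed against each compartment *independently* — a
fragment inside an intronic repeat counts for both the intron and the repeat
compartment, so percentages are not constrained to sum to 100.

**3. Paired compartment-shift test.** For each compartment the per-subject
percentages are compared between conditions with a paired Student t-test,

t = d̄ / (s_d / √n), df = n − 1,

reported one-sided in the direction of the observed mean difference (the
two-sided value is always reported alongside).

**4. Differential expression.** Features (genes by exon counts, genes by
intron counts, repeat loci) are filtered at 5 FPKM in ≥ 80 % of samples,
normalized with median-of-ratios size factors, and tested with a
negative-binomial Wald test on the log2 difference of normalized condition
means; per-feature dispersions are method-of-moments estimates shrunk 50/50
toward the across-feature mean and floored at 0.01. Calls use
|log2FC| ≥ 1 and Benjamini–Hochberg q < 0.05. Repeat results are
aggregated per class (LINE / SINE / LTR / DNA), modulated repeats are placed
in their genic context (exonic > intronic > genic-other > intergenic) and
intersected with modulated introns, and the same test runs on full-length
LINE-1 loci only (normalized against the full repeat matrix, so a coherent
L1 response is not normalized away).

**5. Synthetic studies with known truth.** A generator emulates the full
design — 5 paired subjects, condition-specific compartment mixing
(exon 56.3 % → 53.4 %, intron 23.2 % → 27.6 %, repeat 14.3 % → 15.8 %),
repeats nested in introns, overlapping genes, full-length L1 loci, NB counts
with a designated DE subset — so every stage is testable without downloads.

## Worked example

Simulate a study and run every stage:

```bash
introshift simulate --out demo/sim --seed 7
# write demo/pipeline.yaml pointing at the simulated files, then:
introshift run-all --config demo/pipeline.yaml
```

`demo/run/shift.tsv` from that run:

```
compartment  mean_T0  mean_T1  delta   t       df  p      p_two_sided  sidedness
exon         57.01    54.36    -2.65   -8.297  4   0.001  0.001        one-sided
intron       23.27    27.34     4.08   10.546  4   0.000  0.000        one-sided
repeat       13.89    15.56     1.67    5.725  4   0.002  0.005        one-sided
```

Reading: averaged over the five simulated subjects, 23.27 % of each T0
sample's fragments fall in intron space versus 27.34 % at T1 — a +4.08-point
paired shift (one-sided p < 0.001), recovering the generator's configured
+4.4-point target within sampling noise, while the exon share drops in step.
The same run writes per-compartment DE tables (`de_exon.tsv`,
`de_intron.tsv`, `de_repeat.tsv` — all NS here, since this simulation shifts
compartment totals rather than individual features), the repeat-class
summary, the repeat–intron match table, and `de_l1_full.tsv` for the three
simulated full-length LINE-1 loci.

Every stage is also runnable standalone (`build-annotations`, `count`,
`summarize`, `shift`, `de`, `integrate`, `report`); see `introshift --help`.

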