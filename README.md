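# mirquant

A desk-scale toolkit for quantifying and testing microRNA expression from
QIAseq-style small RNA sequencing libraries. It is aimed at analysts who
need a transparent, fully testable re-implementation of the common
miRNA-seq workflow — read preparation with UMI deduplication, two-step
quantification, negative-binomial differential expression, pathway
over-representation — together with a synthetic-data generator that
provides exact ground truth for every stage.

## What it does

**Read preparation.** A QIAseq-style read is `insert + 3' adapter +
12 nt UMI + filler` within a 72 nt machine read. `mirquant trim` locates
the adapter (substitutions only, error rate 0.1, ≥ 6 nt overlap at the 3'
end), extracts the UMI, applies BWA-style 3' quality trimming (phred
threshold 10), drops inserts outside 10–40 nt, and collapses PCR
duplicates on the `(insert, UMI)` key.

**Two-step quantification.** Reads are first assigned by *exact
full-length sequence identity* against a mature miRNA reference
("precounting"; identical reference sequences are grouped under one
canonical name). Unmatched reads fall through to an ungapped
seed-and-extend genomic aligner (best mismatch stratum, substitutions
only) — or to externally produced SAM alignments — and uniquely placed
reads are counted against stranded BED features, a read incrementing every
feature it overlaps on its own strand. Precounts and feature counts are
merged into the final miRNA × sample matrix.

**Differential expression.** The two-condition model is the standard
RNA-seq recipe in statsmodels style: `DifferentialExpression(counts,
design).fit()` returns a `DEResults` object. Features with across-sample
variance below the first percentile are removed; size factors come from
the median-of-ratios method

&nbsp;&nbsp;&nbsp;&nbsp;`s_j = median_f ( K_fj / (prod_j K_fj)^(1/m) )`;

a per-feature NB2 dispersion α (Var = μ + αμ²) is estimated by Cox–Reid
adjusted profile maximum likelihood; a negative-binomial GLM with log link
and `log s_j` offsets gives a Wald test of the condition coefficient,
`z = log2FC / SE`; p-values are Benjamini–Hochberg adjusted; and each
miRNA is classified *up* / *down* / *no* by `|log2FC| > 0.6` and
`p_unadj < 0.05`. Paired designs (subject fixed effects) and a
group × time interaction contrast are supported. A post-hoc power helper
for the two-sided independent-samples t-test (noncentral-t) is included.

**Enrichment.** DE miRNAs are mapped to target genes via a user-supplied
annotation and tested pathway-by-pathway with the one-sided hypergeometric
tail P(X ≥ k), BH-adjusted, plus a shared-gene pathway overlap matrix for
network-style displays.

**Simulation.** `mirquant sim` writes self-contained fixture suites
(genome, mature FASTA, BED, per-sample FASTQ, count table, truth JSON)
with known per-miRNA abundances, true log2 fold changes, duplication and
error parameters — everything the tests use as oracles.

## Worked example

Simulate a 200-miRNA, 6 vs 6 experiment with 20 miRNAs spiked at
|log2FC| = 2 and test it:

```python
from mirquant import run_de, simulate_counts
from mirquant.simulate import PRESETS

counts, truth = simulate_counts(PRESETS["de_recovery"])
results = run_de(counts, truth.conditions.to_frame())
print(results.summary())
```

```
Negative-binomial differential expression
=========================================================
features tested:        198
removed (low variance): 2
skipped (all zero):     0
samples:                12
design columns:         intercept, condition[treatment]
classification:         |log2FC| > 0.6, p_unadj < 0.05
up: 16   down: 16   no: 166
```

All 20 spiked miRNAs are recovered (some at attenuated estimated effect,
e.g. `sim-miR-034`: log2FC 1.266, p_unadj 0.0003, p_adj 0.0004, "up" with
true log2FC 2.0), plus a handful of false classifications consistent with
the unadjusted 5% level — 6–7% of the 178 null features in this run.
`results.table` holds per-miRNA `base_mean, log2fc, lfc_se, wald_stat,
p_unadj, p_adj, change`, `results.volcano_table()` the plot-ready columns,
and `results.size_factors` / `results.dispersions` the fitted nuisance
parameters.

The same workflow runs from the shell end-to-end on raw reads:

```bash
mirquant sim --preset tiny --seed 20770305 --out fix
mirquant trim  --fastq fix/ref_1.fastq --out ref_1.prepped.fq
mirquant quant --prepped ref_1.prepped.fq --mature fix/mature.fa \
               --genome fix/genome.fa --features fix/features.bed \
               --out ref_1.quant.tsv
mirquant matrix --quants ref_1.quant.tsv ... --out counts.tsv
mirquant de --counts counts.tsv --samples fix/samples.tsv \
            --contrast condition:treatment:reference --out de.tsv
mirquant power --n1 6 --n2 9 --d 0.8        # prints 0.2904
```

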