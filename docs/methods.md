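# Methods

This note records the models, algorithms and design choices behind
mirquant, in the spirit of the methods documentation of the established
statistical genomics packages: what is computed, under which assumptions,
and what the synthetic benchmarks do and do not demonstrate.

## Library model and read preparation

The toolkit assumes a QIAseq-style single-end small-RNA read: the mature
miRNA insert (typically 20–24 nt), the kit's 3' adapter, a fixed-length
random UMI, then filler sequence up to the machine read length (72 nt).
Defaults are the published QIAseq miRNA kit adapter
`AACTGTAGGCACCATCAAT` and a 12 nt UMI; both are ordinary configuration,
so the tool is usable with other kits.

*Adapter location* is substitution-only: the adapter is slid over every
start position (truncation allowed at the 3' end) and the leftmost
placement with at most `floor(rate × aligned_length)` mismatches and at
least 6 aligned bases wins (default rate 0.1). Indels are not modelled —
at these adapter lengths and error rates the substitution model is the
standard trimmer behaviour, and an exactly specified contract keeps the
brute-force test oracle exact.

*Quality trimming* is the classic BWA-style rule: cut at the 3' position
maximizing the running sum of `(threshold − q)` over the removed suffix
(threshold 10 by default). Ties keep the longest insert.

*Length filtering* keeps inserts of 10–40 nt inclusive.

*Deduplication* collapses reads on the exact `(insert, UMI)` pair,
keeping the first representative; reads without a complete UMI collapse
on insert alone. No UMI error-correction network is applied: with a 12 nt
UMI and desk-scale molecule counts, UMI collisions and one-off UMI errors
are rare enough that graph-based correction would add machinery without
changing test outcomes. Reads in which no adapter is found are kept and
flagged by default (configurable), on the view that silently dropping
reads is the worse failure mode; they are counted separately.

Stage order is adapter/UMI extraction → quality trim → length filter →
deduplication. Deduplicating after trimming means two reads that differ
only in trimmed low-quality tail bases still collapse, which matches the
UMI's purpose of identifying molecules rather than raw reads.

## Two-step quantification

Precounting assigns a read to a mature reference by exact full-length
string equality. Identical reference sequences are grouped under the
lexicographically smallest name with the rest recorded as aliases, so a
multi-copy mature sequence cannot be double-counted. Exactness is a
feature, not a limitation: it makes the fast path auditable, and
everything inexact is handled by the fallback.

The fallback aligner is ungapped seed-and-extend: the query is split into
`max_mismatches + 1` pieces, every exact occurrence of each piece is
located on both strands, and full-length extensions within the mismatch
budget are verified. By the pigeonhole principle this enumerates *all*
placements within the budget, so the aligner is provably equivalent to an
all-offsets scan (and is tested against one). Only the best (minimum)
mismatch stratum is reported; reads shorter than `k` (default 12) are
treated as unalignable. Gapped alignment, isomiR resolution and
multi-mapper rescue are out of scope; users who want a production aligner
can feed SAM output into the same counting step.

Feature counting takes uniquely placed reads only — multi-placement reads
are dropped as ambiguous and counted, avoiding double-counting of loci —
and increments every same-strand feature overlapped by ≥ 1 bp, so nested
or overlapping annotations each receive the read. Precounts and feature
counts are merged additively per miRNA name (alias-reconciled; names
present only in the feature annotation stay as rows of their own).

All internal coordinates are 0-based half-open; SAM positions are shifted
by −1 exactly once, at ingestion.

## Differential expression

The model for feature *f*, sample *j* is NB2:
`K_fj ~ NB(mean = s_j q_fj, Var = μ + α_f μ²)` with log link and the
design `~ condition`, optionally `~ subject + condition` (paired) or
`~ condition * factor` with the interaction as the tested contrast (the
second factor's baseline is its lexicographically first level).

Pipeline order: variance filter → size factors → dispersion → GLM → Wald
→ BH → classification.

- **Variance filter.** Features with across-sample variance strictly
  below the first percentile of the variance distribution (linear
  interpolation between order statistics) are removed. With the strict
  comparison a degenerate distribution removes nothing.
- **Size factors.** Median-of-ratios over the features positive in every
  sample. Note the exact equivariance property: scaling one of *m*
  columns by *c* scales its factor by `c^(1−1/m)` and the others by
  `c^(−1/m)` (the per-feature geometric means absorb `c^(1/m)`), so
  factor *ratios* — the only identifiable quantity — scale by exactly
  *c*.
- **Dispersion.** Per-feature α ≥ 10⁻⁸, method-of-moments start
  `(s² − μ̄)/μ̄²` on normalized counts, refined by bounded 1-D
  maximization of the **Cox–Reid adjusted** profile log-likelihood on
  log α ∈ [log 10⁻⁸, log 10], group means profiled out by a fixed-point
  solve of the score equation. The CR term (−½ log det X'WX, block
  diagonal per group) compensates the degrees of freedom spent on the
  fitted means; without it the profile MLE is biased low at n ≈ 12
  (measured mean α̂ ≈ 0.16 for true α = 0.2), which makes the Wald test
  visibly anticonservative (empirical type-I ≈ 0.10 instead of ≈ 0.08 at
  nominal 0.05). Underdispersed features land exactly on the floor. There
  is deliberately **no** empirical-Bayes shrinkage toward a dispersion
  trend, no outlier refitting, and no independent filtering — the fitted
  contract is exactly the named components, and the omissions are
  recorded in the results metadata. Consequently estimates are noisier
  than a shrinkage-based tool's and the test remains slightly liberal at
  small n (type-I ≈ 0.07–0.10 at nominal 0.05 in the shipped null
  benchmark).
- **GLM and Wald test.** IRLS via statsmodels' NB family with fixed α and
  `log s_j` offsets (deviance tolerance 10⁻⁸, ≤ 100 iterations);
  coefficients and Fisher-information standard errors are converted to
  log2. Complete separation (a condition group summing to zero) is
  reported as log2FC = ±30 with a flag rather than a divergent estimate.
  `z = log2FC/SE` is referred to the standard normal, two-sided.
- **Multiplicity and classification.** BH step-up across all tested
  (post-filter, non-all-zero) features. Classification is `up` iff
  log2FC > 0.6 and p < 0.05, `down` mirrored, else `no` — strict
  inequalities, unadjusted p by default (switchable to adjusted). The
  0.6/0.05 thresholds are the conventional small-effect screen for
  miRNA panels of this size.

The post-hoc power helper uses the exact noncentral-t formulation:
df = n₁+n₂−2, ncp = d·√(n₁n₂/(n₁+n₂)), power = P(|T′| > t₁₋α/₂). For the
pilot design it reproduces 0.29 (n = 6 vs 9, d = 0.8, α = 0.05); the
lower noncentral tail is treated as zero where scipy underflows (it is
< 10⁻³⁰ whenever that happens).

A documented irregularity: in the published result tables this toolkit's
classification rule was checked against, a few printed (log2FC, p) pairs
contradict the stated rule (one intervention-group row with |log2FC|
0.599 labeled "down"; three control-group rows satisfying the rule but
labeled "no"). The implementation follows the stated rule; those rows are
recorded in the test data as discrepant and excluded from concordance
checks, and two magnitudes with obviously missing decimal separators are
kept only because their labels are rule-consistent regardless.

## Enrichment

Over-representation uses the one-sided hypergeometric tail
P(X ≥ k | N, K, n) via scipy's log-space survival function, BH-adjusted
across the tested pathways, significance flagged at p < 0.01. The
background defaults to all genes carrying at least one pathway
annotation; both annotation tables (miRNA → gene, gene → pathway) are
user-supplied TSVs, deliberately avoiding a bundled target-database
snapshot whose version would silently dominate results. The target-gene
route (miRNAs → union of target genes → pathways) is the implemented
interpretation; testing miRNAs directly against miRNA-annotated pathways
would be an alternative the annotation format does not preclude. The
shared-gene overlap matrix is the adjacency structure behind
pathway-network figures; layout is out of scope.

## The simulator: what it emulates, and what it does not

The generator is the package's source of ground truth, and its defaults
are the study conditions the benchmarks assume: NB counts with dispersion
0.2, log-uniform base means 10–500, 6 samples per condition, 10% of
miRNAs differentially expressed at |log2FC| = 2, duplication rate 0.3,
base error rate 10⁻³, 72 nt reads with the QIAseq adapter and a 12 nt
UMI. Real libraries at full production scale run 4–8 million reads per
sample; the shipped presets scale the same structure down (tiny: 10
miRNAs × 4 samples ≈ 400–500 reads each; de_recovery: 200 × 12;
null_calibration: 500 × 12 at mean 100) so the whole suite runs in
seconds to minutes on one CPU. The count-level presets write reference
files, counts, sample sheet and truth but skip FASTQ synthesis: they
exist to exercise the statistics, and read-level behaviour is fully
covered by the tiny preset.

Faithfully emulated: read layout, exact PCR duplicates (copying sequence
and UMI, so deduplication truth is exact), uniform per-base substitution
errors, two-condition NB count structure with known effects,
reproducibility (every operation draws from an RNG stream keyed by
(seed, operation, sample), so outputs are byte-identical per seed and
per-sample streams are independent). IsomiR-style 3' truncation (1–2 nt,
off by default) is available to route reads past the exact-match
precounter into the alignment fallback; the default of zero isolates the
precount path so end-to-end identity is exact.

Not emulated: cycle-dependent error profiles, ligation bias, adapter
dimers, UMI errors, and between-subject
biological correlation structure. Passing the shipped benchmarks
therefore demonstrates algorithmic correctness and statistical
calibration under the NB model — not robustness to every artefact of
production libraries.

Degenerate inputs are defined behaviour throughout: empty FASTQ yields
empty output with zero counters; an all-zero feature is skipped with a
report entry; a feature set of size zero yields a valid empty reference;
ties (duplicate mature sequences, equal-p BH ranks, quality-trim ties)
break deterministically as documented above.
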