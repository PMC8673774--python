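# Methods

This note documents the statistical procedures implemented in `cgishift`,
the synthetic data that exercises them, the parameter defaults and the
numerical choices, in enough detail to judge what a passing test suite
does and does not demonstrate.

## Gene classification

CpG islands are detected from sequence alone. A window qualifies when its
length exceeds 200 bp, its GC fraction is at least 0.5 and its
observed/expected CpG ratio (N_CpG · L) / (N_C · N_G) exceeds 0.6; N bases
count toward length but not toward the composition tallies, and windows
that are more than half N are discarded. The caller's output is defined
*declaratively* as the maximal merged intervals of the union of all
qualifying windows, with statistics recomputed on each merged interval.
This definition is deliberately checkable: an exhaustive O(L²) all-window
scan with prefix sums is the oracle in the test suite, and the production
implementation (per-start vectorised scan over ends; the union of
qualifying windows sharing a start is a single interval up to the largest
qualifying end) must reproduce it exactly. The two-pass heuristics used by
genome browsers are approximations of the same criteria and are not
reproduced here. Note that a merged union interval is not itself guaranteed
to satisfy the window criteria; the per-call statistics describe the merged
span as emitted.

Gene classification is dual-evidence. CGI⁺ requires both a sequence CGI
and a consensus CxxC-affinity region (experimental evidence of
unmethylated CpG-rich DNA) overlapping the 1,001-bp window centred on the
TSS; CGI⁻ requires that *neither* element overlap the span from 500 bp
strandwise-upstream of the TSS through the gene end; everything else is
unclassified. Consensus regions are the intersection of coverage across
all input peak sets (configurable via `min_support`); intersection can
only shrink as sets are added, which is asserted as a property. For genes
with multiple annotated TSSs the first record per gene id is used.

## Distribution shift and ΔAUC

Counts are normalized by median-of-ratios: per-gene geometric means are
computed over genes with no zero in any sample, each sample's ratios to
those means are taken, and the per-sample median ratio is the size factor.
This is the standard bulk RNA-seq normalizer; it assumes most genes are
unchanged and acquires a known small bias when a large fraction of genes
moves in one direction (see *Synthetic data* below for how the study
conditions keep that bias negligible).

The reference profile is the per-gene median over young samples. For a
sample-versus-reference comparison, genes expressed in neither vector are
excluded, a pseudocount (default ε = 1) is added, and both vectors are
log₁₀-transformed. The distribution shift is the two-sided Wilcoxon
rank-sum test between the two value sets: exact enumeration when both
sides have ≤ 25 values and the pooled values are untied, otherwise the
normal approximation with tie-corrected variance and continuity
correction. The shift score is −log₁₀ p; affected/unaffected calls use
thresholds 0.5 and 0.25 on the all-genes score (both configurable — the
score scale is a package convention).

ΔAUC is computed from the closed form

    ΔAUC = (Σ log10 Exp_i^S − Σ log10 Exp_i^R) / (n · log10 Exp_max^Both) × 100,

which equals the difference of the areas under the two sorted
log-expression curves drawn with both axes scaled to 0–10 (rectangle rule;
the test suite verifies agreement with the explicit geometric computation
to < 10⁻⁹). The pseudocount is a parameter: closed-form identities such as
"a uniform 10-fold shift gives exactly 50" hold in the ε = 0 limit on
strictly positive data, while ε = 1 is the default for count data. ΔAUC is
antisymmetric under swapping sample and reference, and the shared-maximum
term makes it covariant rather than invariant under common rescaling; both
properties are asserted numerically.

The all-pairs harness forms every (group A, group B) sample pair within
each sex, drops pairs whose mapped-read totals differ by more than
1.5-fold (the boundary itself is kept), removes Y-chromosome genes when
gene coordinates are available, and emits the full per-stratum statistics
for each surviving pair. The CGI⁻-versus-CGI⁺ contrast across comparisons
uses a one-tailed paired t test (alternative: CGI⁻ ΔAUC larger).

A caveat on calibration: when a sample is compared against the median of
samples from the same experiment, the two vectors share per-gene
baselines, so the rank-sum test's iid null variance overstates the true
null variance and the p-values are conservative (measured null minimum
≈ 0.47 across 200 exchangeable samples at the default study conditions).
The affected/unaffected caller therefore has an essentially zero false
AFFECTED rate under the null; p-values should be read as conservative
bounds, not calibrated tail probabilities.

## Consensus chromatin domains

One representative Hi-C dataset per cell type (most aligned reads; ties
break lexicographically, with a warning) contributes a PC1 track binned at
50 kb. Per bin, the fraction of non-missing cell types with PC1 > 0 is
computed; labels are cEu when that fraction is ≥ 0.95, cHet when the
non-positive fraction is ≥ 0.95 (PC1 = 0 counts as non-positive — the
dichotomy must place zero deterministically), Eu-Het otherwise. Bins
missing in more than half of the cell types are left unlabeled. The Y
chromosome is excluded. Genes take the label of their TSS bin, falling
back to the labeled bin with the largest gene-body overlap.

The consensus rule has an intrinsic noise ceiling worth stating: with 30
cell types, a constitutive bin keeps its label only if at most one track
has the wrong sign, so with independent per-track sign-flip probability f
the expected recovery is (1−f)³⁰ + 30 f (1−f)²⁹ — about 0.88 at f = 0.02.
Recovery of a noisy consensus is binomial, not near-perfect, and the test
suite checks the classifier against that binomial prediction rather than
against an unattainable figure.

## Single-cell transcriptional noise

Cells with fewer than 1,000 detected genes or fewer than 10⁵ reads are
removed; if any group then retains fewer than 10 distinct individuals the
dataset is rejected with a typed error naming the group. Counts become
log₁₀(1 + CPM). Noise is (1 − Pearson r) × 100 between a cell's profile
and the young-group mean profile, per stratum (all / CGI⁺ / CGI⁻ genes);
the group comparison is the shared rank-sum test plus the sign of the
median difference.

The young reference is leave-one-out for young cells: a cell included in
its own reference mean is correlated with it by construction
(cov(Xᵢ, Ȳ) = var/n), which depresses the reference group's noise and
makes any non-member group look noisier even at identical dispersion. With
the leave-one-out mean the equal-dispersion null behaves correctly
(measured: 1/20 seeds significant at α = 0.05). The literal shared mean
remains available (`leave_one_out=False`) for comparison with analyses
that used it.

## Synthetic data and study conditions

All generators are pure functions of their parameters and a seed; a global
seed expands to per-component streams via
`numpy.random.default_rng([seed, code])` with fixed codes (bulk 1, sc 2,
pc1 3, pileup 4, genome 5). Truth objects record everything the tests
assert against.

**Bulk.** 6,000 genes, 8 young + 8 aged samples. Gene baselines are
log-normal (log₁₀ mean 1.5, sd 0.7 — a realistic expressed-transcriptome
spread with median ≈ 30 counts); counts are gamma–Poisson (negative
binomial) with dispersion 0.05; per-sample depth factors are log-normal
(sd 0.1). 25 % of genes are CGI⁻, matching the minority share of
CGI-less promoters in mammalian genomes, and by default 30 % of CGI⁻
genes are up-regulated in aged samples by fold changes drawn log-uniform
on [2, 4] — the ≥ 2-fold global misexpression regime the statistics
target. With these conditions the planted genes are 7.5 % of the
transcriptome, small enough that median-of-ratios size factors stay
essentially unbiased; at implausibly high CGI⁻ shares (e.g. half the
transcriptome up-shifted) the normalizer visibly drags the CGI⁺ stratum
downward, which is a property of the normalizer, not of the test
statistic. Genes receive synthetic coordinates, one per consecutive 50-kb
bin of chr1, so domain layouts over the same bins apply directly.

**Single cell.** 2,000 genes, 60 cells per group drawn from 12
individuals per group, mean library 3×10⁵ (so the QC floors pass with
margin). A cell's expected profile is the shared baseline (log₁₀ sd 0.5)
times a *mean-one* log-normal perturbation, 10^(N(0, sd) − sd²·ln10/2),
with sd the group dispersion (young 0.15, aged 0.30 — the 2× contrast);
counts are Poisson after scaling to the cell's library. The mean-one
correction matters: without it, higher dispersion mechanically inflates
mean expression and a "noise-only" difference also shifts the library
composition. With `cgi_minus_only` the extra aged dispersion applies only
to CGI⁻ genes, the stratum-confined scenario.

**PC1 tracks.** A layout of 50-kb-aligned intervals with labels and, for
Eu-Het entries, a per-cell-type probability of a positive sign (default
0.5). Constitutive bins emit the label's sign flipped with `flip_prob`;
magnitudes are uniform on [0.2, 1.5].

**Pileup.** Per ≤ 50-bp bin, value = Poisson(rate × length)/length with
rate `rate_in` inside the (merged) peaks and `rate_out` outside, so the
expected track integral inside peaks is rate_in × peak bp exactly.

**Genome sequence.** Background is a first-order Markov chain at GC 0.3
with the C→G transition down-weighted to 0.15 of its base probability
(obs/exp ≈ 0.17, far below the 0.6 calling threshold, and 20 random
backgrounds yield zero calls). Planted islands emit a CG dinucleotide
with probability 0.4 and otherwise single bases at GC 0.6, giving
GC ≈ 0.83 and obs/exp ≈ 1.5–1.8, comfortably inside the calling
criteria.

**What the synthetic data does not model:** batch structure, sex mixtures
within a dataset (samples default to one sex; the sex-split logic is
tested with crafted metadata), gene length and GC biases, correlated
gene programs, cell types within a single-cell sample, ambient RNA and
doublets, and read-level artifacts. Passing recovery tests therefore
demonstrate correctness of the statistics and their plumbing under the
stated generative models, not robustness to every failure mode of real
data.

## Numerical and edge-case conventions

- Coordinates are 0-based half-open internally; GTF (1-based inclusive)
  converts only at the I/O boundary; the TSS of a '−' gene is end − 1.
  Chromosome names match exactly; nothing strips "chr".
- Rank-sum: all values tied across both vectors → p = 1 by contract.
- Fold-change rules (≥ 2-fold DE, percent-changed, ≥ 5-fold
  tissue-specific) compare raw values so that exact-boundary cases are
  inclusive (2× reference *is* up-regulated); zeros are handled by
  excluding genes expressed in neither vector and by treating a gene with
  zero elsewhere as specific only if it is expressed at all.
- ChIP SNR: a zero outside-peak integral flags the ratio infinite and the
  pass decision falls to the remaining criteria; snr is compared strictly
  (> 0.01) while coverage (≥ 99.9 %) and reads (≥ 10⁷) are inclusive, and
  the depth-ratio pair filter keeps the exact 1.5× boundary.
- The permutation overlap test randomizes only the query set, uniformly
  from the universe of classified genes, and reports the add-one estimate
  (1 + hits)/(n_perm + 1), so p is never zero and is anti-monotone in the
  observed overlap.
- Size-factor estimation fails loudly when no gene is zero-free or a
  sample is all zeros; log-CPM fails on zero-total cells; noise requires
  ≥ 3 genes of nonzero variance per stratum.

## Problem sizes

The default test suite and the acceptance script run the bulk pipeline at
6,000 genes × 16 samples over 100 seeds, the single-cell pipeline at
2,000 genes × 120 cells over 100 seeds, the CGI caller against the
exhaustive oracle on 20 random 10-kb sequences plus 20 planted-island
genomes, the domain classifier on 200 bins × 30 cell types over 20 seeds,
and 2,000 null simulations for the rank-sum type-I check. These sizes give
each recovery estimate a standard error of a few percent while keeping a
full run within a few minutes on one CPU.
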