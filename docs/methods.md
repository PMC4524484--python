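# Methods

This note documents the statistical procedures, the simulator's model and
its limits, and the numerical choices made where the design was genuinely
open.

## Coordinates and gene models

All internal coordinates are 1-based and fully inclusive (the GFF
convention); BED input (0-based, half-open) is converted on read and
converted back on write, and a round-trip test pins the conversion. A gene
is represented by its *transcriptional unit* — the span from the minimum
start to the maximum end over all of its transcripts — plus the exonic
length (bases covered by the union of its exons across isoforms), which is
the denominator RPKM needs. Strand is parsed but ignored downstream: every
distance rule operates on endpoints only.

Chromosome classification defaults to the *D. melanogaster* convention
(2L, 2R, 3L, 3R, 4 autosomal; X as the X; heterochromatic arms, unplaced
scaffolds and the mitochondrial genome excluded) and is fully overridable.
Unknown names are excluded with a warning rather than guessed, so scaffolds
can never leak into autosomal denominators. Whether noncoding genes are
retained is the caller's choice — the classifiers treat whatever gene set
they are handed as the universe.

## Bias classification

A gene is sex-biased when its p-value clears the configured dialect:
Benjamini–Hochberg-adjusted p < α (default 0.05) for RNA-seq-style inputs,
or raw p < α for microarray-style inputs without FDR estimates (α is
sometimes relaxed to 0.10 for low-power sets). The direction is the sign of
log₂((male + c)/(female + c)); the pseudocount c defaults to 0 for
pre-normalised input and should be 1 for count-scale input. Significant
genes with a ratio of exactly zero have no direction and remain unbiased
(with a warning). There is deliberately no fold-change rescue rule: a
non-significant gene is unbiased regardless of its ratio. An optional
minimum-expression filter (off by default) flags genes below a level in
both sexes as NOT_EXPRESSED and removes them from every downstream
denominator.

Fold-change magnitude bins close at 2-, 4- and 6-fold with boundary values
assigned to the lower bin (so exactly 2-fold is "≤2-fold").

BH adjustment is delegated to statsmodels' step-up implementation and
pinned by enumeration tests; monotonicity in α (lowering α can never add
biased genes) and permutation invariance are property-tested.

The built-in differential-expression test is a two-sided Welch t-test on
log₂(count + 1). It exists so the synthetic pipeline runs end to end and is
approximately calibrated under the null (KS-tested against uniform); it is
*not* a negative-binomial GLM and should never replace a dedicated DE tool
on real counts. Real analyses enter through the DE-table interface.

## Enrichment statistics

For a bias class of size n_class in a data set with n_X X-linked genes out
of n_total expressed genes, the expected X-linked count is
n_class · n_X / n_total; the three class expectations sum to n_X exactly.
The Fisher exact test contrasts the focal class against *all other
expressed genes* ([class_X, class_A; rest_X, rest_A]); a class-vs-UBG-only
variant is available as a sensitivity switch. The two-sided p-value sums
hypergeometric probabilities no larger than the observed table's (the
common "probability mass" rule); the reported odds ratio is the conditional
maximum-likelihood estimate, the convention of R's `fisher.test`.
Degenerate tables (an empty margin) report p = 1 and an undefined (NaN)
odds ratio. Integer percentages round half-up.

The bundled reference count table carries a caveat documented in
`scdc.published`: three of its 42 printed percentage cells are internally
inconsistent with their own printed counts (no rounding rule reconciles
them — the fractional parts printed rounded up overlap those printed
rounded down). Recomputation reproduces the other 39 cells exactly and is
off by exactly one point on those three.

## Distances to DCC binding sites

The distance between a gene and a binding site is the minimum over the four
endpoint pairs |site endpoint − gene endpoint|, with overlap giving zero.
For non-overlapping intervals this equals the gap between closest edges,
which is how the vectorised implementation computes it (sorted site starts,
running maximum of site ends, binary search); a test asserts equality with
the literal four-endpoint rule and with an all-pairs brute-force scan on a
1,000 × 1,000 fixture. Distances are defined only on the X; requesting a
distance where a component has no sites is an error, never a silent NaN.

High-affinity sites (HAS) are derived as the colocalization of MLE and
MSL-2 intervals: one HAS per overlapping pair (≥ 1 bp), spanning the
intersection, with overlapping results merged. Because HAS coverage is a
subset of MLE coverage, HAS distances dominate MLE distances gene-by-gene —
a property test.

Spearman's ρ uses tie-averaged ranks. Its p-value switches to exact
permutation enumeration for n ≤ 10 (batched vectorised enumeration of all
rank permutations) and uses the t-approximation above. The Wilcoxon
rank-sum test uses exact enumeration when the pooled sample is ≤ 12 and
tie-free, otherwise the tie-corrected normal approximation with continuity
correction.

## Tissue specificity

τ = Σᵢ (1 − xᵢ/x_max) / (N − 1) over N ≥ 2 tissues: 0 for uniform
expression, 1 for single-tissue expression, scale-invariant, and monotone
under mass transfer toward the maximal tissue (all property-tested).
Atlas preprocessing follows the usual microarray conventions: per-gene
probe collapsing keeps the probe with the highest mean intensity across
tissues (highest-single-tissue is a config option, since "highest
intensity" is ambiguous in the literature); composite structures can be
excluded; replicate conditions can be averaged into one column. Negative
intensities (possible after background correction) are clamped to zero
with a logged count; all-zero genes have no τ and are skipped, not imputed.
Raw intensities are used by default — published τ variants disagree about
log-transformation, so log₂(x+1) is offered as a switch rather than
imposed. The conventional interpretation bands are τ < 0.4
(housekeeping-like) and τ > 0.7 (tissue-specific).

## Dosage and bookkeeping analyses

RPKM is 10⁹ · reads / (exonic_length · library_size). The X:A comparison
takes median male expression per chromosome class over genes passing an
RPKM floor (default 1) and optionally a housekeeping filter (τ < 0.4),
reporting the A/X median ratio and a rank-sum p. Gene-set overlap uses the
upper-tail hypergeometric test; the universe is the genes expressed in
*both* data sets under comparison (the conservative choice — a larger
universe would only inflate significance). Mean gene age averages age
classes 0–6 over genes present in the age table, reporting coverage rather
than imputing. The remove-and-recompute analysis drops a removal set from
both the focal class and the totals, which a test shows is identical to a
from-scratch run on the reduced universe.

## The simulator

For gene g and sample s, counts are negative binomial with
variance μ + μ²·φ and

log₂ μ_gs = b_g + [s male] · (Δ_g + log₂ m_g),

where b_g ~ N(7, 1.5²) is the baseline (mean count ≈ 128), Δ_g is the
sex-regulation effect, and m_g = 1 + a·e^(−d_g/λ) is the overcompensation
multiplier for X-linked genes at distance d_g from the nearest DCC site
(m = 1 on autosomes). Genes are placed uniformly without overlap on one X
(default 2 Mb, 16% of genes — the X-linked fraction of the genome) and one
autosome (12 Mb); 60 sites of 500 bp are placed uniformly on the X, giving
nearest-site distances on the same few-kb scale as the decay length
λ = 5 kb. Dispersion defaults to φ = 0.05, a typical bulk RNA-seq scale.

Sex regulation: each gene is a candidate with probability
`frac_sex_regulated`, with effect Δ ~ N(2, 1²) on the log₂ scale — a wide
magnitude spectrum that populates all four fold-change bins, as observed
magnitude distributions do. On the X, a candidate is *accepted* with
probability q^(β·Δ/2), where q is its distance quantile and β is
`sexreg_distance_bias`: the depletion force scales with the required male
upregulation, so strong male effects are both thinned from the X and pushed
far from sites, while weak effects keep near-random positions. This is the
operational form of the interference/germline-suppression mechanism; a
side effect is that the realised X rate of sex-regulated genes falls below
the autosomal rate, which is exactly the demasculinisation the mechanism
predicts.

Two named regimes bracket the mechanisms:

- `brain_like()`: a = 0.35, λ = 5 kb, no sex regulation, 10 replicates per
  sex at φ = 0.01. The deep replication and low dispersion model an
  isogenic single-tissue design — necessary, because the overcompensation
  signal is at most 1.35-fold and sub-1.5-fold effects are undetectable at
  5% FDR under ordinary replication (a power calculation and the
  simulator's own null confirm this). Typical output: 40–60 MBG, ~95%
  X-linked, O/E ≈ 6, ρ ≈ −0.78.
- `gonad_like()`: a = 0, 30% sex-regulated genes at Δ ~ N(2, 1), β = 2,
  5 replicates at φ = 0.05. Typical output: ~500 MBG, X-depleted
  (O/E ≈ 0.4), ρ ≈ +0.15.

The atlas generator assigns each gene a *broad* (Dirichlet(50) profile,
mean τ ≈ 0.2) or *specific* (one-hot profile, τ = 1) stratum and scales by
a log-normal overall level; τ separates the strata with AUC > 0.9.

Everything is deterministic given (seed, config); each stage draws from its
own numbered seed stream, and file output is byte-identical across runs.

### What the simulator does not capture

No read-level effects (mapping bias, GC, positional coverage), no strain or
batch structure, no gene-length or expression-level dependence of
dispersion, no correlation between tissue specificity and sex bias, fixed
gene lengths, a single autosome, and equal library sizes by default
(unequal sizes are a switch). Passing the simulation-based tests therefore
demonstrates that the *pipeline* recovers the encoded mechanisms — it is
not evidence about real tissues, for which the pipeline consumes real DE
tables, annotations and ChIP-derived site files.

## Problem sizes and runtime choices

The default simulated data set is 2,000 genes (320 X-linked), which makes
enrichment and correlation signs stable seed-to-seed while keeping a full
20-seed, two-regime recovery experiment under ten seconds. The
magnitude-bin distance comparison runs at 5,000 genes so each fold-change
bin holds ~15 X-linked MBG and per-bin medians are stable. Exact
(enumeration) p-values are used precisely where they are feasible — n ≤ 10
permutations for ρ, pooled n ≤ 12 for the rank-sum test, and all
hypergeometric tail sums — and approximations elsewhere, each pinned
against its enumeration oracle in the tests.

## Known limitations

- The Welch stand-in DE test is underpowered relative to NB-GLM tools at
  low replication; simulated MBG counts are conservative.
- The conditional-MLE odds ratio is undefined for empty margins and
  reported as NaN rather than a pseudo-count estimate.
- τ preprocessing assumes tissues are columns of a dense matrix; sparse
  single-cell atlases are out of scope.
- The exact Spearman permutation p enumerates n! permutations and is
  intentionally capped at n = 10.
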