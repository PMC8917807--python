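# Methods

This package implements a pipeline for studying the expression behaviour of
paralog gene pairs — duplicated genes that can substitute for one another in
protein complexes — across development-style time courses, tissues and
species. All statistics operate on feature-by-sample abundance matrices
(transcript TPM/FPKM or protein iBAQ/LFQ/TMT quantities) together with a
paralog pair table, a protein-complex catalog, and (for the cross-species
part) a gene-to-orthogroup map. Because the statistics are the object of
interest rather than any one dataset, every analysis is exercised on a
seeded synthetic-data generator that plants the structure each statistic is
supposed to detect; recovery of the planted truth is what the test suite and
the acceptance script check.

## Pair co-expression and divergence

For each canonically ordered pair (lexicographic on gene id) the Pearson
correlation R of the two expression profiles is computed over
pairwise-complete samples. Pairs with R > 0 are *co-regulated*; pairs with
R ≤ 0 are *divergent*. Correlation (and the coefficient of variation,
sd/mean on the linear scale, sample sd with ddof 1) requires at least
`min_obs = 5` observed samples; constant series give a missing R rather
than 0, so the divergent class is not inflated by unquantifiable pairs.
Correlations are computed on the dataset's native scale as loaded (TPM
linear for development-style transcriptomes, log2 for proteomes). The
per-pair Δ score is R_protein − R_rna; negative Δ indicates divergence
arising post-transcriptionally. The random-pair null redraws `n_draws`
(default 10,000) uniform pairs of distinct genes and scores them
identically. Identity bins are left-closed `[edge, next)` with the last bin
right-closed.

## Complex variability and stoichiometric stability

Complex co-expression is the median of all pairwise member correlations;
*variability* is 1 − median R. Complexes need ≥ 5 quantified members and at
least half of C(5,2) defined pairwise correlations to be scored. The top and
bottom quartiles of the median-R distribution define stable and variable
complexes; boundary ties fall to intermediate (conservative class sizes).
*Paralog content* is the fraction of members with at least one paralog in
the genome (or, in the stricter variant, with a paralog inside the same
complex). Randomly assembled complexes matching the real size spectrum give
the complex-level null.

The fold-change statistic works per comparison: for every subunit the median
Euclidean distance of its log2 fold change to each co-member is compared to
2,500 distances from random complexes of equal size drawn from the
quantified proteins, giving the empirical probability

    p = (#{null < observed} + 1) / (n_null + 1)

of observing a lower distance. Add-one smoothing avoids p = 0 and makes the
floor 1/(n_null+1) exactly attainable — with certainty only by zero-distance
subunits, since no null distance can be negative. Strict `<` follows the
definition of "observing lower distances"; a `≤` variant is a flag. One null
is drawn per complex-size class and comparison and shared by all subunits of
that size (random complexes of equal size; linear cost); per-subunit draws
are available by flag. Because subunits of one complex share co-members and
a pooled null, their p-values are mutually correlated even under the null —
calibration checks therefore sample one subunit per random complex. The
complex-level co-expression score is 1 − median of member p's (median over
mean: robust to a single outlier subunit).

## Differential analysis and PSM processing

The internal differential test is Welch's t on log2 values with
Benjamini–Hochberg adjustment; significance needs |log2 FC| > 0.58
(strictly) and adjusted p < 0.05. Precomputed DE tables can be supplied
instead to reproduce any upstream choice. Among pairs with both members DE,
same-sign fold changes are *concordant* and opposite-sign *opposite*; exact
zeros are excluded with a warning. The NED/ED analysis runs a Fisher exact
test on the degradation-class × complex-membership table and a two-sided
rank-sum comparing Δ between pairs with ≥ 1 NED member and both-ED pairs.

TMT PSM tables pass, in order: removal of reverse/contaminant hits, of
search scores < 15, and of PSMs with reporter intensity < 10³ in all 10
channels; survivors are log2-transformed, channel-median-subtracted
(location normalization; "normalized" is otherwise unspecified upstream),
restricted to peptides complete in all 10 channels, summarized to protein
groups by the median, and proteins with < 2 unique peptides are dropped.
The all-channels reading of the intensity floor is a documented choice;
per-channel masking is the alternative.

## Cross-species conserved substitutions

Per species, log2 paralog ratios log2(A) − log2(B) are formed per replicate
wherever both genes are quantified. Ratio changes between a comparison's
condition and its reference are tested with a moderated t: the pooled
two-sample variance s² (d residual df) is shrunk toward a prior s0² with d0
prior df estimated from the ensemble of per-pair variances by the method of
moments on the scaled-F marginal of s²,

    s²_post = (d0·s0² + d·s²)/(d0 + d),  df = d0 + d.

When the moment equations have no solution with d0 > 4, the prior is treated
as infinitely informative (s_post = s0); `d0 = 0` recovers the ordinary t
for sensitivity analysis. p-values are BH-adjusted within species ×
comparison. Gene pairs are mapped to unordered orthogroup pairs (pairs with
an unmapped gene, or both genes in one orthogroup, are dropped); multiple
gene pairs on one orthogroup pair are averaged — arithmetic mean of deltas
and of p-values, per comparison, before combination. Fisher's method
combines the per-comparison p-values (X² = −2Σln p against χ² with 2k df),
BH adjusts the combined p across pairs, and a pair is *conserved* when it is
quantified in all species, its deltas share the majority sign in ≥ 5 of the
7 comparisons (after orienting each pair so its summed delta is positive;
exact zeros count as inconsistent; for pairs quantified in only 5–6
comparisons the ≥ 5 count still applies to the quantified ones), and the
adjusted combined p is ≤ 0.05. The replicate design is unpaired by default.
The PCA of ratio differences uses complete-case pairs, centering, and SVD,
with signs fixed so each component's largest-magnitude score is positive.

Fisher's combination assumes the per-comparison p-values of a pair are
independent. The synthetic multi-species design therefore gives every
comparison its own independently acquired reference batch (conditions
`<cmp>_ref`): if comparisons of one species shared reference replicates,
their deltas would correlate at ρ ≈ 0.5 and the combined p would be
anticonservative in the tail (in our experiments the null-effect
any-detection rate rose from ~2% to ~22%). With time-course data that share
a first time point, `ratio_change_test` still supports the all-vs-first
convention, but combined p-values should then be read as approximate.

## Promoter motif scanning

JASPAR PFMs (parsed with Biopython) are converted to probabilities with a
pseudocount of 0.8 distributed by the background composition (uniform by
default). A window's log2-odds score is min-max rescaled to the motif's
achievable range (*relative score*: consensus = 1, anti-consensus = 0); a
promoter's score for a TF is the maximum over all windows on both strands of
the 2,000-bp upstream region, set to 0 below the 0.8 threshold — so absent
TFs score 0 by construction. Windows containing ambiguous bases are skipped.
Shared-TF fractions are computed over the union of hits (presence =
score > 0), making shared + exclusive = 100%. Per-TF score-difference
distributions use the upstream pair orientation and require the TF present
in ≥ 10 pairs (configurable).

## Enrichment

Over-representation uses the one-sided hypergeometric upper tail per gene
set (two-sided by flag); ranked enrichment uses the two-sample KS between
in-set and out-of-set scores (exact small-sample p from scipy). Adjustments
are BH or Hommel via statsmodels; tests verify both against brute-force
oracles (step-up by hand; exhaustive closed testing with Simes local tests).
GO structure is treated as pre-flattened annotations; no DAG propagation or
term reduction is performed.

## Synthetic-data generator

Latent pair profiles are standard-normal random walks over conditions,
standardized to unit sd, so `noise_sd` is the noise-to-signal ratio in log2
units (default 0.3). Divergence is planted as a sign flip of the shared
latent in an exact round(n_pairs × fraction) of pairs (default fraction
0.35). Complexes draw a complex-level latent; members mix it with private
noise whose share grows with the complex's paralog-content target when
`content_coupling` > 0, so variability and content are positively coupled by
construction. Content targets are spread evenly over [0, 1] across
complexes. The protein layer is the rna layer plus independent noise; pairs
containing a NED-labelled gene have the second member's protein profile
mixed with an independent latent (weight `ned_delta_mix`), lowering
protein-level co-expression and hence Δ. A `paralog_var_boost` > 1 gives
pair genes larger latent amplitude (higher CV than singletons). The
multi-species generator plants `n_conserved` of `n_orthogroup_pairs`
(defaults 50 of 1,000) orthogroup pairs with a ±`effect_size` (default 1.0)
ratio shift consistent in sign in ≥ 5 of 7 comparisons (0–2 randomly
flipped), replicate noise N(0, 0.25), 3 replicates, comparisons partitioned
2+2+2+1 over 4 species. Non-planted pairs get per-comparison shifts of sd
`null_shift_sd`, default 0: a nonzero default would make non-planted pairs
genuinely change ratio, so "false" discoveries would be ground-truth
labelling artifacts rather than pipeline errors. Promoters are i.i.d.
background (configurable composition) with motif consensus sequences
embedded at random non-overlapping positions. The PSM generator assigns
violations (reverse, contaminant, low score, all-channel low intensity) to
disjoint PSMs so survivor counts are exact. A single seed expands into
per-stage substreams; everything is bitwise reproducible.

What the generator does *not* emulate: instrument-level MS noise (ion
statistics, missing-not-at-random dropout), multi-mapping RNA-seq reads,
isoform structure, genuinely nonlinear mean-variance relations, shared
regulatory programs across complexes, or real promoter base composition.
Passing recovery tests therefore shows the statistics are implemented
correctly and calibrated under their own assumptions — not that those
assumptions hold in any particular real dataset.

## Problem sizes and numerical choices

The packaged end-to-end study (`paraflux.pipeline.run_synthetic_study` and
the `analysis/` drivers) uses 400 pairs + 600 singletons × 10 conditions × 3
replicates, 40 complexes of 8, 1,000 orthogroup pairs across 4 species, 500
stoichiometry null draws and a 30–40-gene promoter set — sizes chosen so the
whole chain runs in seconds while every statistic remains well-powered; the
recovery checks in `tests/test_acceptance.py` and `scripts/acceptance.py`
use the full study conditions (2,000 pairs; 2,500 null draws; 20 null
seeds). Degenerate inputs (constant series, empty complexes, single
replicates, all-NaN columns) yield missing values or validation errors, not
silent zeros. Ties in stability quartiles go to intermediate; p-value floors
are 1/(n_null+1) for permutation p's and 1e-300 before log-transformation in
Fisher's method.

## Known limitations

- The moderated-t prior is a method-of-moments fit, not the full
  empirical-Bayes machinery of dedicated DE packages; with few pairs the
  prior df estimate is noisy (it then falls back to full shrinkage).
- Orthogroup-level averaging of p-values (mean before combination) follows
  the documented upstream convention but is not a calibrated combination
  rule in itself.
- Per-subunit stability p-values within a complex are correlated (shared
  co-members and pooled nulls); complex-level summaries use medians but no
  explicit dependence correction.
- The 80% PWM threshold is a hit-calling convention; scores between motifs
  of very different widths and information content are not directly
  comparable.
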