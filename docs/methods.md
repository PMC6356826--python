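# Methods

## Study design emulated

The package targets the classic two-inbred-line design: lines F and L are
crossed reciprocally (FL, LF), RNA-seq counts are obtained for a small
number of biological replicates per group (defaults: 2 F, 2 L, 4 FL,
4 LF), and the reciprocal crosses — which in this design rarely differ —
are pooled into a single Cross group for all inheritance inference.  The
FL vs LF contrast is still computed and reported, but does not feed the
classifier.

## Differential-expression engine

The two-group test is a fully specified negative-binomial Wald pipeline.

**Normalization.** Median-of-ratios size factors: reference genes are
those with strictly positive counts in every sample; the factor of sample
*j* is the median of counts[i, j] / geometric-mean_i over reference genes.
Factors are not rescaled, so multiplying one library by *k* moves its
factor by *k* relative to every other library while all factors absorb a
common k^(1/n); downstream results are invariant up to the pseudocount's
effect at very low counts (covered by tests).

**Dispersion.** Per gene, a method-of-moments estimate per group with
≥ 2 replicates, `alpha_g = max((v − m)/m², 0)`, combined across groups
with weights (n_g − 1) and floored at 1e-8.  By default the per-gene
estimate is then *moderated* toward the across-gene mean with prior
weight 10 (relative to the contrast's residual degrees of freedom).  At
the replicate numbers of this design the raw per-gene estimate is so
noisy that the Wald test's type-I error inflates to ≈ 0.09 at nominal
0.05; moderation restores ≈ 0.05–0.06 while leaving power at large
effects essentially unchanged.  Raw estimates remain available
(`moderate=False`), and the moderation washes out as replication grows.

**Test.** `log2FC = log2((mean_b + c)/(mean_a + c))` with pseudocount
c = 0.5 (configurable); the standard error is the delta-method variance
of the log of an NB mean, `se = sqrt(w_a + w_b)/ln 2` with
`w_g = (1/max(mean_g, c) + alpha)/n_g`; p-values are two-sided normal
tails of log2FC/se, adjusted by Benjamini–Hochberg over the testable
genes.  A gene is DE when `q < 0.05` and `|log2FC| ≥ 1` (both
configurable).  Genes with zero counts in both groups are flagged
untestable, kept in the output, and excluded from the number of BH
hypotheses.  No independent filtering, no covariates, no shrunken LFC.

## Mid-parent pseudo-group

MPV pseudo-samples are built on the normalized scale as the elementwise
mean of one F and one L sample, labeled group MPV with size factor 1.
Two pairing schemes exist: a seeded random perfect matching
(min(nF, nL) pseudo-samples, each parental sample used at most once) and
the full Cartesian product (nF × nL pseudo-samples, the pipeline
default — with 2 + 2 parental replicates it yields 4 pseudo-samples and a
steadier MPV dispersion estimate).  When the MPV group enters the NB
contrast its values are rounded half-to-even; everywhere else they stay
real-valued.  No variance-propagation correction is applied for the fact
that pseudo-samples are averages — a known caveat: the MPV group's
sampling variance is roughly half a real group's, which makes the
MPV-vs-Cross test slightly anticonservative relative to a true
biological group.

## Inheritance-mode classifier

Decision order per gene, given the F vs L, F vs Cross, L vs Cross and
MPV vs Cross contrasts and the group means: untestable → additive gate
(not DE vs MPV) → over-dominance (DE above the high parent) →
under-dominance (DE below the low parent) → dominance (DE vs exactly one
parent; the resembled parent names the mode, and the sub-mode is
enhancing iff the resembled parent is the higher-expressed one) →
non_additive_unresolved.  Over/under-dominance is tested against the
single relevant parent only, and takes precedence over dominance so the
categories are mutually exclusive.  Ties in the parental means resolve
to F as the high parent.  Genes that are significantly non-additive but
fit no category are reported as unresolved rather than forced into a
class.

### A structural limit on enhancing-dominance recovery

Under the generative model where a dominance gene's Cross mean sits
exactly at one parent and the parents differ by δ (log2), the true
MPV-vs-Cross effect for *enhancing* dominance is
`log2(2/(1 + 2^(−δ)))`, which is below 1 for **every** δ (0.913 at
δ = 4).  The `|log2FC| ≥ 1` DE rule therefore structurally withholds the
non-additive call from these genes; only estimation noise lets a
minority (~10–25 %) cross the threshold.  Suppressing dominance (Cross
at the low parent, true effect ≈ δ − 1) is recovered at ~95–99 %.  On
balanced simulations at δ = 4 this caps overall dominance recovery near
0.5–0.65 while additive, over-dominance (~0.98–0.99) and
under-dominance (~0.87) recover well.  This is a property of the
classification rule itself, not of the estimator; it should be kept in
mind when interpreting dominance counts from any analysis using this
threshold.

## Synthetic data generator

Per gene: a baseline mean m from a natural-log-normal
(log-mean log 100, log-sd 1.5 — a realistic bulk RNA-seq spread), a true
mode drawn from configurable proportions (defaults: 70 % null, 10 %
additive, 8 % + 8 % parental dominance, 2 % + 2 % over/under-dominance —
a transcriptome-realistic mix in which most genes do not differ between
lines), parental divergence δ = 4 split symmetrically
(`mu_F = m·2^(±δ/2)`), and the Cross mean set by the mode equations
(MPV for additive, a parent for dominance, ±Δ = 2 beyond the extreme
parent for over/under-dominance).  Counts are NB with variance
μ + αμ² (α = 0.1 by default, optionally log-normal per gene), scaled by
per-sample size factors drawn uniformly from (0.7, 1.3).  Reciprocal
crosses share the Cross mean by default; `reciprocal_log2fc` injects an
FL/LF difference when that contrast needs exercising.  Allele-specific
expression is gene-level: 15 % of genes get an allelic ratio of 0.8
(side randomized), the rest 0.5, and per-cross-sample F-allele counts
are binomial on Poisson totals.  Phenotypes are normal draws around
group means (embryo 3.53 / 4.03 / 3.75 g for F / Cross / L, egg
39.7 / 37.1 / 33.1 g, SDs 0.45 g and 2.5 g) with group sizes 14 F, 16 L,
14 FL, 4 LF.

What the generator does *not* emulate: gene–gene correlation, GC or
length biases, outlier replicates, SNP-level allelic data, and any
cis/trans mechanistic coupling between the simulated ASE flags and the
simulated inheritance modes (the two are drawn independently).  Passing
recovery benchmarks therefore demonstrates correctness of the inference
machinery under the stated NB model, not robustness to those real-data
features.

## Clustering

Genes are clustered on group-average (F, Cross, L) `log2(normalized + 1)`
profiles — a simple variance-stabilizing transform used purely for
profile comparison — under Pearson correlation distance `1 − r`.  After
per-gene standardization (center, unit norm) this distance is half the
squared Euclidean distance, so Lloyd iterations with mean-then-renormalize
centroids monotonically decrease the objective; the best of `restarts`
seeded initializations is kept, assignment ties go to the lowest cluster
index, and constant profiles (undefined correlation) sit in a dedicated
overflow cluster 0.  The cluster-number scan is a leave-one-condition-out
figure of merit: cluster on all columns but one, score the RMS deviation
of the left-out column from its cluster means, adjust by
`sqrt(n/(n − K))`, sum over left-out columns, and suggest the K with the
largest second difference (the knee).  The pipeline's default K is 12
(configurable).  Clusters are labeled non-additive only when the share of
non-additive member genes strictly exceeds 50 %.

## ASE overlap and independence

The overlap matrix cross-tabulates the DE-pattern categories (additive,
over-dominance, two parental dominances — restricted to the compiled DE
gene list, i.e. the union of DE genes over F vs L and Cross vs
{F, L, MPV}) against ASE categories split by preferred allele; genes with
conflicting SNP-level preferred alleles are excluded.  The DE∩ASE share
of the DE list measures how much differential expression is plausibly
cis-driven.  Independence is tested with a Pearson χ² (1 df, no
continuity correction by default) on the 2×2 DE × ASE table over the
universe of all testable genes — the standard framing; the universe and
correction are configurable, and a warning is attached when an expected
cell falls below 1.

## Phenotype statistics

Embryonic efficiency is 100 × embryo weight / egg weight per embryo.
Egg weight, embryo weight and efficiency are screened with Shapiro–Wilk,
then compared across F, Cross, L and the mid-parent group (random
pairing of parental embryos, seeded) with one-way ANOVA and Tukey–Kramer
all-pairs comparisons (statsmodels' studentized-range implementation,
which honors unequal group sizes and reduces to plain Tukey HSD at equal
n).  The compact letter display assigns letters to maximal runs of
mutually non-different groups ordered by mean, so groups sharing no
letter differ at the chosen level.  Standard routines (ANOVA, Tukey,
Shapiro–Wilk, χ²) are delegated to scipy/statsmodels; the module's
contribution is the result schema, group construction and letter logic.

## Problem sizes and determinism

Every stochastic component takes an explicit seed and is bit-reproducible
given it.  The bundled benchmarks use 2,000-gene simulations at the
default design (three seeds for mode recovery), 1,000 replicates for the
χ² calibration, and 60-gene three-profile data for the figure-of-merit
check — sizes at which the Monte-Carlo error of each reported rate is
well below the decision tolerances used in the tests.
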