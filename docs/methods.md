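# Methods

This note documents the statistical procedures implemented in
`chromage`, the design of the synthetic study generator, the defaults
and why they were chosen, and what the tests do and do not establish
about real data.

## Normalization and differential enrichment

Library-size **size factors** use the median-of-ratios estimator: for
region *g* with counts *x<sub>gs</sub>*, the reference is the geometric
mean over samples (rows containing any zero are excluded), and the
factor of sample *s* is the median over reference rows of
*x<sub>gs</sub>* / ref<sub>g</sub>. The estimator assumes most regions
are unchanged between samples; when a large fraction of regions trends
with a covariate, part of that trend leaks into the factors (see
*Limitations*). Note that multiplying one sample's column by *c* moves
its factor by *c*<sup>1−1/n</sup> and every other factor by
*c*<sup>−1/n</sup> — equivariance is exact for factor *ratios*, which
is what the tests assert.

**Differential enrichment** between two sample groups is a
moment-based negative-binomial Wald test on normalized counts. With the
NB mean/dispersion parameterization (var = μ + αμ²), group means
μ̂<sub>A</sub>, μ̂<sub>B</sub> and pseudocount *pc* (default 1, on the
normalized-count scale, to bound fold changes at zeros):

- LFC = log2((μ̂<sub>B</sub> + pc)/(μ̂<sub>A</sub> + pc))
- SE = (1/ln 2) · √( Σ<sub>g∈{A,B}</sub> (1/n<sub>g</sub>)(1/(μ̂<sub>g</sub> + pc) + α) )
- z = LFC/SE, two-sided normal p-value, Benjamini–Hochberg adjusted.

The delta-method SE uses var(log x) ≈ var(x)/x², i.e. (1/μ + α) per
observation. Regions are flagged up/down at adjusted *p* < 0.1 by
default — the working threshold for differentially enriched regions
throughout. Dispersion is estimated per region by pooled
within-group method of moments, α̂ = max(α_min, (s² − μ̄)/μ̄²), with
optional shrinkage toward the median (weight 0.3); α_min = 1e-8 keeps
downstream SEs finite. This is deliberately simpler than a full NB GLM
with per-gene dispersion shrinkage: the downstream biology consumes
normalized counts plus a significance threshold, and the simple test's
type-I error is calibrated on its own simulated null (empirical
P(p < 0.05) ≈ 0.046 at 5,000 regions, 3 vs 3).

BH adjustment is the step-up rule implemented directly (sorted p,
adj<sub>(i)</sub> = min<sub>j≥i</sub> p<sub>(j)</sub>·m/j, capped at 1)
and cross-checked in tests against both a brute-force transcription of
the definition and `statsmodels.multipletests`.

Rank tests wrap SciPy: two-sided Mann–Whitney U (exact enumeration when
both groups have ≤ 8 untied observations, tie-corrected normal
approximation otherwise) and Kruskal–Wallis with Bonferroni-scaled
post-hoc pairwise MWU. Percent signal change is
100·(B − A)/(A + pc).

## Euchromatin score and pairing

Per-gene z-scores use the population SD across the chosen samples;
constant genes map to all-zero z rows so they stay neutral in every
downstream sum. z-scores are computed per mark across **all** samples —
both genotypes and all ages jointly — so WT and HD scores share one
scale; this is required for cross-genotype comparison and is the
package's documented convention (a per-genotype option exists via
`sample_subset`). The euchromatin score is z(H3K27ac) − z(H3K27me3)
per (genotype, age, replicate)-matched sample pair; pairing at
replicate level is justified by the assay design, in which one nuclear
extract is split across the two antibodies.

## Chromatin-state clustering

k-means (k-means++ initialization, Lloyd iterations, best inertia of 10
restarts, fixed seed) is provided through scikit-learn. The feature
space for promoter-state clustering represents each gene, per mark, on
the log2(normalized + 1) scale by (a) its per-(genotype, age) group-mean
trajectory centered on the gene's own mark mean and scaled by the
mark's pooled deviation SD, and (b) one cross-mark *relative level*
(the gene's mark mean minus its mean over all marks, standardized
across genes). Centering removes the per-gene coverage component that
all marks share (region length, mappability, accessibility); the
relative level retains mark-usage signatures such as joint
H3K4me3/H3K27me3 elevation at bivalent promoters.

Bivalency clustering uses only the two bivalency-defining marks
(H3K4me3, H3K27me3), so PRC1-dependent and -independent bivalent genes
fall in a single cluster; the **bivalent cluster** is selected by
standardizing per-cluster mean H3K4me3 and H3K27me3 signals across
clusters and taking argmax of min(z̄_K4, z̄_K27me3), with ties broken by
larger sum then smaller label. The selected cluster is then split by
two-way k-means on the H2AK119ub level *relative to the gene's
cross-mark mean*; the higher-mean subcluster is always "cluster 1
(high)". Downstream logic never depends on raw k-means label numbers.

## The epigenetic-age clock

`EuchromatinClock` holds per-pair mean euchromatin scores over a
reference gene set (the H2AK119ub-high bivalent subcluster in the
pipeline), with each pair's age and genotype; `fit()` runs OLS of score
on chronological age over WT pairs and returns `ClockResults` (slope in
score units/month, intercept, r², residual SD, `summary()`).
Epigenetic age is read off by inverting the calibration line,
predicted = (score − intercept)/slope — the calibration-curve
convention — and acceleration is predicted minus chronological age. A
slope below 1e-6 score/month refuses prediction: the clock is
uninformative. Per-pair (replicate-level) scores feed the fit so the
residual SD is estimable.

Under a multiplicative planted acceleration (effective age = κ·age),
the clock should predict κ·age for HD samples. The aging slope default
(0.1 log2/month) was fixed by a noiseless design analysis: after
z-scoring, the exponential mean trajectory must be near-linear over
effective ages 2–20 for inversion to be unbiased, and at 0.1 the
noiseless inversion bias is < 0.01 months at κ = 1.5 (≈ 0.2 at κ = 2).
With estimated size factors a small upward bias (≈ +0.2 months at
κ = 1.5) remains from the trend fraction of the gene set (below).

## Score modules

The co-regulation module detector keeps the top 20 % of genes by
across-pair score variance, represents each gene by its standardized
(genotype, age) group-mean trajectory, clusters trajectories with
k-means over k = 2..8 and picks k by maximum mean silhouette, reporting
per-module mean trajectories per genotype. This is a deliberately small
stand-in for full co-expression-module machinery (soft thresholding,
module eigengenes): deterministic, seedable and sufficient to separate
the two planted archetypes (accelerated monotone gain vs inverted-U).

## Trajectories, paralog switch, overlap tests

Three-point trajectory shapes are called by fixed rules evaluated in
order (ε > 0): *peaked* if m₂ > max(m₁, m₃) + ε; *dipped* if
m₂ < min(m₁, m₃) − ε; *up* if m₃ − m₁ > ε and m₂ ≥ m₁ − ε; *down* if
m₁ − m₃ > ε and m₂ ≤ m₁ + ε; else *flat*. The rules partition all
inputs. The default ε is data-driven: the pooled between-replicate SD
of the group means (RMS of SD/√n over cells), overridable.

The paralog-switch score formalizes a coordinated family flip as
mean LFC(up set) − mean LFC(down set), with a one-sided resampling
null: B draws of |up|+|down| genes without replacement from the
background, randomly split into same-sized sets;
p = (1 + #{null ≥ observed})/(B + 1), so p ∈ (0, 1] and is exact-valid.
The score is antisymmetric under swapping the sets.

Gene-set overlap significance offers a binomial upper tail
(k successes in |A| draws at rate |B|/|U|) as the default and the exact
hypergeometric tail as the alternative; fold enrichment is
k/(|A||B|/|U|). GMT enrichment applies the hypergeometric test per set
(sets intersected with the universe) with BH across sets.

## Synthetic study generator

The generator emulates post-alignment per-gene counts for a WT vs HD
knock-in design at 2, 6 and 10 months, 3 replicates per cell, four
marks. Counts are NB(μ, α) with
μ = 2^(baseline + class effect) × size factor, α = 0.05 shared across
genes, size factors uniform on [0.6, 1.6]. Baselines share one
per-gene coverage component across marks (uniform over the mark's
baseline range, default ≈ 5–8 log2) plus mark-specific N(0, 0.3)
jitter — real region-level signal is strongly correlated across assays
via length/mappability/accessibility, and this correlation is what
makes within-gene mark comparisons informative. One RNG stream per
mark (split from the master seed) keeps each mark's data invariant to
the mark set; a fixed seed reproduces byte-identical output.

Planted classes and defaults (slopes in log2/month of effective age;
the source literature reports significance, not effect sizes, so these
are calibration choices, not estimates):

| class | signature | dynamics |
|---|---|---|
| background (300) | none | flat |
| identity (20) | H3K27ac +1.5, H3K4me3 +1.0, H3K27me3 −1.0 | HD-only: ac −0.1·age, me3 +0.1·age |
| bivalent_c1 (30) | H3K4me3 +1.5, H3K27me3 +1.0 | ac +0.1·effage, me3 −0.1·effage, H2AK119ub −0.08·effage |
| bivalent_c2 (20) | as c1, H2AK119ub pinned at log2 ≈ 2 | ac/me3 as c1, ub flat |
| stress (20) | H3K27ac/H3K4me3 +0.5 | ac ±A(1−((effage−6)/6)²), A = 1.5; me3 mirrored |

Effective age is κ·age for HD (κ default 1.5; an additive mode is also
provided). The stress quadratic peaks at effective age 6, so WT samples
it as a 6-month peak while HD (effective ages 3/9/15) reads a
non-increasing section of the same curve — one mechanism for both
phenotypes. The background class dominates (≈ 75 % of genes) because
median-of-ratios normalization presumes most regions unchanged; a
signal-dominated gene set would leak the aging trend into the size
factors. For clustering benchmarks, where a genome-wide promoter
heatmap shows every profile as a sizeable block, the balanced
`StudyConfig.five_profile_benchmark()` configuration is used instead.

The two slope-like defaults that govern trajectory recovery
(`stress_amplitude` = 1.5, `slope_identity` = 0.1) come from a power
rule: the planted shape margin (e.g. m₂ − max(m₁, m₃) for *peaked*)
must exceed ε plus 1.5 SD of a group-mean difference at the design's
replicate noise (log2 group-mean SD ≈ 0.2 at n = 3).

## What the synthetic data does not emulate

Peak calling and region definition, fragment-level coverage structure,
per-gene dispersion heterogeneity, batch effects, cell-type mixtures,
CAG-repeat instability, and any real genomic coordinates or gene
identities. Passing recovery tests therefore demonstrates estimator
correctness and calibration under the stated model, not performance on
real libraries — in particular, real bivalency calling depends on peak
quality, and real clock accuracy on how well the reference gene set is
identified.

## Numerical choices and degenerate inputs

Population (not sample) SD for z-scores; zero-SD rows → zeros.
Constant signals: the high/low split refuses to split; the module
detector raises on all-constant scores; Kruskal–Wallis on identical
observations returns H = 0, p = 1. k-means ties and restarts are
resolved by scikit-learn under a fixed `random_state`; all pipeline
seeds derive from the study seed. bedGraph ingest produces real-valued
signal; raw `CountMatrix` construction enforces integer counts, and
real-valued inputs must be declared normalized. Promoter windows clip
at coordinate 0 (default TSS ±2000 bp, configurable). BH on an empty
vector returns empty; a single p-value is returned unchanged.

## Limitations

- The NB Wald test has no design matrix: covariates beyond the two
  groups are out of scope, as are shrunken LFC estimators and
  independent filtering.
- Size-factor estimation under many trending regions biases the clock
  slightly upward (≈ +0.2 months at κ = 1.5 under the defaults); using
  known size factors removes most of it.
- Inverting the WT line extrapolates beyond the fitted age range for
  strongly accelerated samples (HD at 10 months with κ = 1.5 has
  effective age 15 vs a 2–10 calibration range), where the z-scored
  exponential trajectory departs from linearity and predictions
  overshoot; the 6-month quantity reported throughout sits inside the
  calibrated range.
- The silhouette-selected module count is reliable only when the
  planted archetypes are well separated; real score data may need the
  full co-expression toolchain.
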