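# chromage

Cell-type-specific histone-modification analysis for aging and
neurodegeneration studies: from region × sample count matrices of
H3K27ac, H3K27me3, H3K4me3 and H2AK119ub signal to bivalent-promoter
chromatin states, per-gene euchromatin scores, and an epigenetic-age
clock that quantifies accelerated epigenetic aging.

## The problem

In aging neurons, and dramatically faster in Huntington's-disease (HD)
striatal neurons, polycomb-repressed developmental genes lose their
repressive marks (H3K27me3, deposited by PRC2; H2AK119ub, deposited by
PRC1) and gain histone acetylation — they *euchromatinize*. Tracking
this erosion per cell type and over time requires a small set of
quantitative tools downstream of alignment and peak counting:

- **median-of-ratios normalization** of per-region read counts across
  libraries, with a moment-based negative-binomial Wald test for
  differential enrichment (regions called at BH-adjusted *p* < 0.1);
- the **euchromatin score** of gene *g* in paired sample *s*,

  `E(g, s) = z_ac(g, s) − z_me3(g, s)`,

  where `z_ac` and `z_me3` are per-gene z-scores of normalized H3K27ac
  and H3K27me3 counts, computed across all samples of a mark, and
  H3K27ac/H3K27me3 samples are paired by (genotype, age, replicate)
  because both derive from one split nuclear extract;
- **bivalent chromatin-state calling** by k-means over promoter mark
  profiles (the bivalent cluster is jointly high in H3K4me3 and
  H3K27me3) and a two-way split of bivalent promoters into
  H2AK119ub-high ("cluster 1") and -low ("cluster 2") subclusters;
- the **epigenetic-age clock**: OLS of the mean cluster-1 euchromatin
  score on chronological age, fitted on wild-type samples; epigenetic
  age of any sample is `(score − intercept)/slope` and *age
  acceleration* is predicted minus chronological age;
- trajectory-shape calls (up / down / peaked / dipped / flat) for
  stress-response dynamics, a permutation-tested **paralog-switch
  score** for coordinated gene-family flips (e.g. polycomb CBX
  paralogs: Cbx2/4/8 up, Cbx6/7 down), and binomial / hypergeometric
  gene-set overlap and GMT enrichment tests.

Because deposited sequencing data are not required to exercise any of
this, the package ships a **synthetic study generator** that emulates
the post-alignment shape of a two-genotype (WT vs HD knock-in), 
three-age (2/6/10 months) design: negative-binomial counts with
library-size factors and planted gene classes (background, SPN
identity, two bivalent developmental-TF subclusters, stress response),
plus a known multiplicative aging acceleration κ — HD effective age =
κ × age, so κ = 1.5 plants a 3-month age distortion at 6 months.

## Worked example

```python
from chromage import pipeline
from chromage.synthetic import StudyConfig

analysis = pipeline.run_study_analysis(StudyConfig(seed=1))
print(analysis.clock.summary())
print(analysis.clock.group_summary().round(2).to_string(index=False))
```

prints

```
Euchromatin-score epigenetic clock (OLS)
----------------------------------------
fitted on genotype : WT (9 pairs)
slope              : +0.30856 score units / month
intercept          : -2.42496
r-squared          : 0.9577
residual SD        : 0.24014
genotype  chronological_age  n  predicted_mean  predicted_sd  acceleration_mean  acceleration_sd
      HD                2.0  3            3.19          0.50               1.19             0.50
      HD                6.0  3            9.28          0.61               3.28             0.61
      HD               10.0  3           16.68          0.14               6.68             0.14
      WT                2.0  3            2.12          1.24               0.12             1.24
      WT                6.0  3            5.77          0.51              -0.23             0.51
      WT               10.0  3           10.12          0.43               0.12             0.43
```

Reading the output: the WT euchromatin score of the bivalent cluster-1
genes rises by ≈0.31 score units per month (r² = 0.96), so the score is
an informative age proxy. Inverting that calibration line for HD
samples predicts an epigenetic age of ≈9.3 months at chronological age
6 — the planted κ = 1.5 acceleration, i.e. a ≈3-month age distortion —
while WT samples show no systematic acceleration. The same run yields
the bivalent promoter cluster (51 genes, of which 32 H2AK119ub-high and
19 H2AK119ub-low) and two euchromatin-score modules with distinct
trajectories (monotone accelerated gain vs an inverted-U that declines
under acceleration).

A command-line interface mirrors the library
(`chromage simulate | normalize | diff | cluster | bivalent | euscore |
clock | switch | trajectory | enrich`), e.g.:

```bash
chromage simulate --seed 3 --out study/
chromage normalize --counts study/counts_H3K27ac.tsv --mark H3K27ac --out norm_ac.tsv
chromage diff --counts study/counts_H3K27ac.tsv --samples study/samples.tsv \
    --mark H3K27ac --padj 0.1 --out ders.tsv
```

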