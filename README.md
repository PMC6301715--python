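# prandialreg

Feeding, not just the circadian clock, drives a large share of diurnal gene
expression in the liver. `prandialreg` re-implements, as a tested and
reusable pipeline, the integrative analysis that separates feeding-driven
from clock-driven hepatic gene expression and enhancer activity: mice
trained to night-restricted feeding are sampled at ZT10 (preprandial) and
ZT14 with or without food, and every downstream question — which genes need
food to change, which enhancers lose H3K27 acetylation on feeding, which
transcription-factor motifs and occupancy patterns explain it, and which
hormone (glucocorticoid via dex, insulin via the receptor antagonist S961)
restores each repressed gene — is answered with an explicit statistical
procedure.

Because the original sequencing data are not required to exercise the
procedures, the package ships a first-class synthetic cohort generator that
emulates the study's statistical structure (negative-binomial replicate
counts, cosine circadian profiles, enhancer–gene coupling, occupancy-coupled
acetylation loss, planted motifs, hormone-response classes) together with
ground-truth labels, so every stage is verified as a parameter-recovery
problem.

## The statistics at the core

- **Differential testing.** Two-group negative-binomial comparison:
  median-of-ratios size factors, per-feature method-of-moments dispersion
  α (variance m + αm²) shrunk 50/50 toward a log-linear mean–dispersion
  trend, Wald statistic log2FC/SE referred to a moderated-t with
  2(n₁+n₂−2) df, Benjamini–Hochberg FDR.
- **Feeding-dependence quintiles.** Genes differential across ZT10→ZT14-fed
  (FDR < 0.01) are ranked by |log2FC(ZT10 vs ZT14-unfed)|: a change that
  persists without food is clock-driven (Q1), one that vanishes is
  feeding-driven (Q5). Bins are equal-sized, remainder to lower bins.
- **Circadian phase.** Least-squares cosinor fit
  y = m + a·cos(2π(t−φ)/24) on 2-h-resolution profiles; rhythmic when
  a exceeds a threshold multiple of the residual sd.
- **Enhancer activity.** H3K27Ac and DNase tags counted in an 800-bp window
  centered on each DHS; differential acetylation at FDR < 0.1; Pearson
  correlation of DNase vs acetylation fold changes on differential DHSs
  (r_de) vs all DHSs (r_all); two-sample Kolmogorov–Smirnov test on
  cumulative TSS-distance curves; Ward hierarchical clustering of z-scored
  profiles.
- **Motifs.** Log2-odds PWM scanning (best window over both strands,
  background = empirical base composition of sampled DHSs); binomial
  enrichment against a random-DHS background; Kruskal–Wallis plus gated
  pairwise Mann–Whitney across clusters; motif activity as a ridge
  regression of per-DHS acetylation change on binary motif occurrence with
  residual-bootstrap standard errors.
- **Occupancy.** ≥1-bp-overlap co-occupancy with Venn accounting; ROC/AUC
  of tag density predicting acetylation loss (AUC ≡ Mann–Whitney
  U/(n₁n₀)); proximity enrichment of peaks within 50 kb of TSSs relative
  to seeded random gene sets (relative enrichment = observed / mean null).
- **Hormone decomposition.** Feeding-repressed genes (fed < unfed, FDR
  < 0.05) classified by a decision table over dex/S961/combination
  de-repression flags into clusters 1–5; sample PCA with chi-square 0.9
  error ellipses; per-cluster resampling enrichment; eight-cluster Ward
  analysis of the lean/obese arms.

## Worked example

The numbered scripts under `analysis/` run the full study on the synthetic
cohort (2,000 genes, 3,000 DHSs, seed fixed in `01_simulate.py`):

```bash
python analysis/01_simulate.py
python analysis/02_feeding_classification.py
python analysis/03_enhancer_activity.py
python analysis/04_motif_analysis.py
python analysis/05_tf_occupancy.py
python analysis/06_hormone_decomposition.py
```

Selected output from that run and what it means:

```
differential at FDR<0.01: 421 induced, 360 repressed
planted feeding-driven genes in Q4+Q5: 98.3%
planted clock-driven genes in Q1+Q2: 97.3%
```
The quintile ranking puts nearly all planted feeding-driven genes in the
feeding-dependent bins and clock-driven genes in the feeding-independent
bins.

```
DNase/H3K27Ac fold-change correlation: r_de=0.80 (n=266), r_all=0.55 (n=3000)
```
The planted coupling of 0.8 between accessibility and acetylation changes
is recovered on differential DHSs, and r_de exceeds r_all as expected when
most DHSs are stable.

```
GR binds 1059 DHSs, FOXO1 758; GR co-occupies 60% of FOXO1 sites
  GR     AUC=0.883
median GR density by dex-response bin: high=41.5, medium=14.4, low=5.3
```
Factor tag density predicts which DHSs lose acetylation on feeding, and the
DHSs most induced by dex carry the highest GR occupancy.

```
response clusters (1 none, 2 dex, 3 S961, 4 either, 5 combo only):
  {1: 55, 2: 37, 3: 53, 4: 36, 5: 51}
mean per-cluster recovery of planted labels: 91.3%
combo-arm PCA centroid: 4.6 from unfed vs 34.0 from fed vehicle
```
The decision table recovers the planted hormone-response classes, and
coinjection of dex + S961 moves the fed transcriptome back to the unfed
state in PCA space.

The same stages are available as a CLI
(`prandialreg simulate|classify|enhancers|motifs|occupancy|hormone|run`)
driven by one YAML config with a single master seed.

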