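# Methods

This note documents the statistical model behind each pipeline stage, the
design of the synthetic cohort, the numerical choices, and the known
limitations. It is the package's own account of its science; every number
quoted is computed by the test suite or `scripts/acceptance.py`.

## Study design being modeled

Two liver sampling points bracket the feeding transition under
night-restricted feeding: ZT10 (preprandial, corticosterone high, insulin
low) and ZT14, two hours after food access, with a parallel ZT14-unfed
cohort. A gene whose ZT10→ZT14 change survives fasting is clock-driven; one
whose change requires food is feeding-driven. The same logic applies to
enhancer H3K27 acetylation at DNase hypersensitive sites (DHSs), and the
hormonal basis of postprandial repression is probed by preprandial
injections of dexamethasone (dex, glucocorticoid agonist), S961 (insulin
receptor antagonist), or both.

## Differential count testing

Counts are modeled as negative binomial with variance m + αm². The
two-group Wald test proceeds as:

1. **Size factors** — median of per-feature ratios to the geometric-mean
   reference, over features positive in all samples (error if none,
   suggesting a pseudo-reference).
2. **Dispersion** — pooled within-group method-of-moments estimate
   α̂ = (s² − m̄)/m̄², floored at 0, then blended 50/50 (linear scale) with
   a log-linear trend of dispersion on mean fitted across features.
   Linear blending keeps the floor from dominating when α̂ = 0.
3. **Wald statistic** — log2FC with a +0.5 pseudocount only when a group
   mean is zero (never for testing); delta-method SE propagating both the
   Poisson and overdispersion components and the size factors; the
   statistic is referred to a t distribution with 2(n₁+n₂−2) df. The
   doubling reflects the equal-weight shrinkage: a 50/50 blend with a
   trend estimated from thousands of features behaves like a variance
   estimated at roughly twice the residual df (the moderated-t argument).
   Under the null (5,000 genes, 3v3, dispersion 0.05) the fraction of
   p < 0.05 is 0.047–0.055 across seeds; a plain normal reference is
   anti-conservative (0.086) and a t with the raw residual df
   over-conservative (0.019).
4. **FDR** — Benjamini–Hochberg step-up over tested features; all-zero
   features are excluded and flagged.

One unit test cross-checks fold changes and significance calls against
pyDESeq2 on a shared fixture (correlation of log2FC > 0.98, call agreement
> 90%); the library is never the implementation.

## Feeding-dependence quintiles

Genes differential across ZT10→ZT14-fed at FDR < 0.01 are split by sign
into induced and repressed, then each direction is ranked by
|log2FC(ZT10 vs ZT14-unfed)| and cut into five equal bins. Q1 takes the
largest fold changes — the change persists without food, so the gene is
feeding-independent — and Q5 the smallest. Remainder genes go to
lower-index bins; ties break lexicographically by gene id, making the
assignment a pure function of (ids, statistics).

## Cosinor phase

y = m + a·cos(2π(t−φ)/24) is linear in (cos ωt, sin ωt) and solved by
least squares; φ = atan2 of the two coefficients. A gene is rhythmic when
a > 2.0 × residual sd (config default; the threshold trades sensitivity
against false rhythmicity and has no canonical value). Constant series are
never rhythmic. On noisy synthetic cosines (CV 0.2, 12 timepoints) the
median circular phase error is ≈ 0.4 h.

## Enhancer quantification and structure

Tags are counted in an 800-bp half-open window centered on each DHS
(floor((start+end)/2)), clipped at coordinate 0 rather than erroring — a
degenerate but valid genomic edge. The same window serves H3K27Ac and
DNase. Differential acetylation delegates to the NB test at FDR < 0.1.
Pearson correlations of DNase vs acetylation fold changes are reported with
Fisher-z 95% CIs, separately for differential DHSs (r_de) and all DHSs
(r_all). TSS-distance comparisons use absolute center-to-nearest-TSS
distances (ties toward the smaller coordinate, for determinism) and the
two-sided asymptotic two-sample Kolmogorov–Smirnov test: the distance
samples in this analysis number in the hundreds to thousands, where the
asymptotic p is accurate. The two-sample KS p is discrete over the
attainable-D lattice and therefore mildly conservative; the calibration
suite checks both two-sided uniformity and, one-sided, the absence of
anti-conservatism.

Clustering of z-scored profiles uses Ward linkage on Euclidean distance
(scipy implementation of the Lance–Williams recurrence) cut to k clusters,
with labels renumbered by first appearance for stability. k = 4 for
enhancer dynamics and k = 8 for the lean/obese gene analysis, matching the
study design; planted classes at ≥ 2-sd separation are recovered with
adjusted Rand ≥ 0.8.

## Motif analysis

A PWM stores base probabilities per position with a pseudocount (default
1e-3) applied by row renormalization; the log2-odds matrix divides by a
background that defaults to uniform and, in the pipeline, to the empirical
base composition of the sampled background DHSs (the background set is
GC-matched by construction, mirroring how backgrounds are matched by
sampling DHSs). A region's motif score is the best window score over both
strands; windows containing N are skipped; sequences shorter than the
motif are flagged. Enrichment compares the fraction of target vs
background sequences reaching a per-motif threshold (0.75 × maximal score
in the drivers) with a one-sided binomial test, the background fraction
floored at half a pseudo-hit.

Motif activity is a ridge regression (unpenalized intercept via centering,
λ default 1.0) of per-DHS acetylation log2FC on binary motif occurrence;
standard errors and p-values come from a seeded residual bootstrap
(default 200 replicates). Constant occurrence columns are flagged rather
than fit. With two planted drivers (−1, +0.5) among 20 decoys at n = 2,000
the signs and rank order are recovered and every decoy's |activity| stays
below both drivers'.

## Occupancy and resampling enrichment

A region is "occupied" on ≥ 1 bp of peak overlap; gene proximity uses the
peak center within 50 kb of the TSS (the center is the least ambiguous
anchor). ROC curves use tag density as the score; AUC is computed as
Mann–Whitney U/(n₁n₀), which handles ties and equals the trapezoidal area.
Proximity and cluster enrichments draw seeded random gene sets without
replacement from the supplied universe; relative enrichment is
observed/mean(null), with a one-sample t-test of the null frequencies
against the observed value and a permutation-style count — the latter
because six null sets make a t-test fragile. Under the null both
enrichments center on 1.0 (mean within [0.9, 1.1] over 100+ repeats).

## Hormone decomposition

Feeding-repressed genes are those with fed < unfed vehicle at FDR < 0.05.
"Regulated by an arm" requires FDR < 0.05 *and* log2FC > 0 vs fed vehicle
(de-repression); the decision table is: neither single arm and no combo →
cluster 1; dex only → 2; S961 only → 3; both singles → 4; combo only → 5.
Combo significance is deliberately ignored when either single arm is
significant, so cluster 5 means genes that respond *only* to the
combination. Genes missing a contrast are flagged unclassified. PCA is
mean-centered SVD over samples; 0.9 error ellipses scale the 2-D score
covariance by the chi-square 0.9 quantile (2 df).

## The synthetic cohort

Defaults encode the emulated study: 3 replicates for the time-course arms,
4 per hormone arm, NB dispersion 0.05, baseline mean 200 with lognormal
(sd 0.5 in log space) per-feature variation, gene effect 2 log2 units,
enhancer effect 1 log2 unit with N(0, 0.3) per-DHS jitter, class mix 15%
clock / 15% feeding / 10% mixed / 60% null, enhancer mix 6% up / 8% down /
6% clock / 80% stable, coupling distance 50 kb, 400-bp sequences at 48%
GC, motif planting rate 0.3 in feeding-reduced DHSs (a quarter of that
elsewhere and for decoys). Where the emulated study states no value, the
default was chosen once as a realistic magnitude and not revisited.

Structure worth noting:

- **Gene classes.** Clock-driven genes shift ZT10 relative to both ZT14
  arms; feeding-driven genes shift only ZT14-fed; mixed genes carry the
  full clock effect at ZT10 and half-persistence unfed. Directions are
  random per gene; exact class counts use largest-remainder apportionment
  so bookkeeping assertions are exact.
- **DNase–acetylation coupling.** Over non-stable DHSs,
  d = ρ·a + √(1−ρ²)·sd(a)·w, which fixes the population Pearson r at the
  configured ρ for any class-mixture variance; a shared directional mean
  on both assays would inflate it.
- **Occupancy.** Per-factor log tag density is N(0, 1) shifted by the
  configured separation at feeding-down DHSs, so AUC ≈ Φ(sep/√2) by
  construction; peak membership is density-weighted with the GR/FOXO1
  shared fraction exact.
- **Hormone arms.** Responding clusters return to the unfed mean in the
  fed state (2: dex; 3: S961; 4: either; 5: combination only; 1: none).
  Feeding-*induced* genes additionally revert to unfed level in any
  S961-containing arm — insulin-receptor blockade prevents their
  induction — which is what makes the combination arm resemble the unfed
  transcriptome in PCA, as the emulated experiment shows.
- **Obesity arm.** A configurable fraction (default 0.5) of
  feeding-responsive genes lose their feeding response in the obese
  fed/unfed arm.

All randomness flows from one master seed through named substreams, so a
config+seed pair fully determines every file, and toggling one stage never
perturbs another.

What the generator does **not** emulate: read-level artifacts (GC bias,
mapping, duplicates), correlated gene–gene expression, batch effects,
realistic genome geography (one chromosome, evenly spaced genes), motif
co-occurrence syntax, or dispersion–mean relationships beyond a single
α. Passing recovery tests therefore demonstrates that the procedures are
correctly implemented and statistically calibrated under their assumed
model — not that the biological conclusions of any particular dataset
would be reproduced.

## Problem sizes and numerical choices

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each statistical property is sharp: 5,000 genes
for type-I calibration, 1,500 for quintile recovery, 3,000–4,000 DHSs for
correlation and ROC structure, 2,000 DHSs for motif activity, 200 repeats
for null-uniformity checks, and a 400-gene/500-DHS cohort for the
byte-determinism rerun. TSV outputs are written with %.6g floats so reruns
are byte-identical. Ties are broken deterministically everywhere (gene id
lexicographic in binning, smaller coordinate in nearest-TSS, stable sorts
in bin assignment).

## Known limitations

- The NB test is a two-group Wald test only: no multi-factor designs,
  likelihood-ratio tests, outlier refitting, or fold-change shrinkage.
  Numeric parity with any external differential tool is not claimed.
- The motif-activity regression is a deliberate simplification of
  motif-activity frameworks built on the same idea; it treats occurrence
  as binary and independent across motifs.
- The rhythmicity call depends on a single amplitude/noise threshold; no
  multiple-testing control is applied across genes for rhythmicity.
- Proximity enrichment magnitudes depend strongly on genome density; the
  synthetic genome is far denser than a mammalian one, so relative
  enrichments are compressed toward 1 even when the qualitative pattern
  is clear.
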