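# Methods

## The design and its factors

The Four Core Genotypes (FCG) mouse model places *Sry* on an autosome,
decoupling sex chromosome complement (XX vs XY⁻) from gonadal sex
(ovaries vs testes).  All animals are gonadectomized in adulthood and
implanted with a blank or testosterone capsule, adding an activational
factor.  `fcgnet` treats the resulting 2×2×2 layout as three crossed
binary factors — `chr` (sex chromosome complement), `gon` (gonadal,
i.e. organizational), `act` (activational hormone) — with eight groups.

## Quantification

Quadruplicate CT values are collapsed by the arithmetic mean per
sample × gene.  Because CT is a log2-scale quantity, the mean CT is the
log2 of the geometric mean of intensities, so collapsing before the
delta is consistent with geometric-mean normalization.  Relative
expression is `2^−ΔCt × 10,000` with ΔCt the target CT minus the mean of
the two reference-gene CTs; this is algebraically identical to the
geometric mean of the two per-control relative intensities, and both
forms are implemented as mutual cross-checks.  Whether replicates should
be averaged as CTs or as intensities is not determined by the
quantification convention itself; the mean-CT choice is recorded here as
the package's convention.  Reference-gene stability is not re-tested,
but a QC warning fires when a control's group-mean CT range exceeds 0.5
cycles (~1.4-fold).

## Factorial ANOVA

Each gene is fitted with the full three-way linear model (three main
effects, three two-way interactions, the three-way interaction) under
sum-to-zero (±1) coding.  Each term is tested with a Type-III F: the
residual sum of squares of the full model versus the model with that
term's column deleted, on 1 numerator df.  On balanced designs this
equals the classical factorial decomposition (asserted against a
textbook sums-of-squares oracle and against `statsmodels`' Type-III
ANOVA in the tests); under mild imbalance Type-III remains well defined,
and inestimable terms (empty cells) are reported as NaN rather than
guessed.  Significance is p < 0.05 with a separate trend flag at
p < 0.1.

Tukey HSD follow-ups compare the four gonadal-sex × hormone cells (or
all eight cells on request) using the full model's MSE and the
studentized-range distribution (Tukey–Kramer standard error under
unequal cell sizes).  They are gated on the omnibus model showing at
least one significant term, matching the usual planned-contrast
discipline; with k = 2 cells the p-value reduces exactly to the pooled
two-sample t-test.

Multiple testing is controlled per gene category (GABA-related vs
monoamine-related) with the Benjamini–Hochberg step-up procedure.  The
declared family size *m* may exceed the number of p-values supplied, for
categories whose full membership is larger than the listed tests.  Two
pooling modes are exposed: `per-term` (default; one family per factor
within each category) and `pooled-main` (the three main effects of a
category pooled into one family of size 3m) — the choice between them is
genuinely open, and `per-term` was picked as the more conservative
reading of per-factor correction.

## Emotionality composite

Raw anxiety measures (elevated plus maze: time in open arms, % crosses
into open arms; open field: time in center, % distance in center) are
standardized against the comparison group — XX + blank by default,
configurable — as `z = direction·(X−μ)/σ`, with σ the sample SD (n−1;
the population/sample choice is not dictated by the formula, and n−1 is
recorded as the package's convention).  Directions are flipped so that
larger scores always mean more anxiety.  Composition is strictly
two-level: measures average into per-test scores, per-test scores
average into the overall composite.  Pooling all measures would weight
tests by their measure counts and is deliberately not offered.
Comparison-group members receive scores (their mean is 0 by
construction, asserted at 1e-12).

## Correlation analysis

Pearson r of each gene against the overall composite, in seven strata:
all animals and each side of each factor.  Two-sided p-values via the
t transform with n−2 df (two-sided is the conservative default; the
analysis is not directional a priori).  BH families are
(stratum × category) with declarable m.  Sign classes (+/−) are assigned
only to BH-significant correlations; strata with fewer than 3 animals or
degenerate variance are flagged, not dropped.

## Dimorphism ratio matrix

Per gene and factor, the ratio of the male-phenotype mean (XY⁻, testes,
testosterone) to the female-phenotype mean.  Means are *marginal*:
unweighted averages of the four design-cell means on each side, which
equal pooled sample means when balanced and are robust to group-size
imbalance otherwise (whether the original visualization used marginal or
pooled means is not recoverable; marginal is the declared choice).
log2 of the matrix is antisymmetric under swapping the phenotype labels.
Flags: `*_main` for a significant main effect of the factor, 
`*_interaction` for a significant interaction involving it (raw p < α,
figure-annotation style).  The matrix is exported as TSV; rendering is
left to the user.

## Co-expression networks

Within a group, each gene pair's signed Pearson correlation r gives an
edge weight `w = |r|³` — amplifying strong correlations, shrinking the
weak ones expected from noise.  The sign is annotation only.

* **Density** = mean weighted degree / (n−1); 1 for a complete
  unit-weight graph.
* **Clustering** (weighted, Barrat-style): per node,
  `Σ_{j≠i} Σ_{k≠i,j} w_ij w_jk w_ki / ((Σ_j w_ij)² − Σ_j w_ij²)` with the
  ordered double sum counting each triangle twice, matching the
  symmetric denominator; the global value is the mean over nodes with a
  positive denominator (degree-<2 nodes are excluded and counted, since
  0/0 has no honest value).
* **Assortativity**: Newman's M-edge formula with the edge list = pairs
  of positive (post-threshold) weight and endpoint values = *weighted*
  degrees.  This hybrid is a declared convention: with binary degrees
  every node of a complete weighted graph is identical and the statistic
  is universally undefined.  A perfectly regular graph still has zero
  denominator and is reported undefined rather than 0.  Note a further
  consequence: over the *complete* edge list (τ = 0) the endpoint-degree
  correlation equals −1/(n−1) exactly, whatever the weights (the
  finite-population sampling identity), so assortativity only
  discriminates between groups when a threshold τ > 0 sparsifies the
  edge list.  τ is configurable everywhere and defaults to 0.

The pipeline computes network correlations on **log2-transformed**
expression by default (`network_scale="linear"` available).  Arbitrary
`2^−ΔCt` units are approximately lognormal, and Pearson correlation on
the linear scale is systematically attenuated for lognormal data; the
log2 scale is where the generator's correlation structure (and standard
co-expression practice) lives.

**Permutation comparison.**  For two groups, the observed difference in
a global property is compared with differences obtained by reassigning
the pooled samples at random, preserving group sizes and rebuilding both
networks each time.  The two-sided p is `(1 + #{|Δperm| ≥ |Δobs|}) /
(n_valid + 1)` — add-one smoothing avoids p = 0 from finite permutation
counts.  Permutations with an undefined property are excluded with the
denominator adjusted, and the result is flagged unreliable beyond 20%
exclusions.  Default 1,000 permutations.

**Reference projection.**  The male-phenotype network can serve as the
reference structure: its positive-weight edge set is fixed and weights
and signs are recomputed from the female group's samples.  This is an
export/visualization device; group statistics default to each group's
own full network (`projection="male-reference"` switches the reported
female statistics to the projection, since either reading of the
original procedure is defensible).

## Synthetic data generator

The generator is first-class, tested code, and its defaults define the
study conditions everything else is validated under:

* 8 groups × 7 mice; 16 GABA-related genes (including Sst, Gad67, Gad65)
  and 14 monoamine-related genes, plus Actb and Gapdh as references.
* Latent log2 expression = per-gene baseline (8.5–11.5, i.e. a few
  hundred to a few thousand arbitrary units) + additive effects:
  `β_chr·1[XY⁻] + β_gon·1[testes] + β_act·1[testosterone] +
  β_gxa·1[testes]·1[testosterone]`.  Defaults plant a −0.4 log2 XY⁻
  effect on a broad gene set, smaller gonadal/activational effects, and
  −0.5 log2 gonadal×hormone interactions, mirroring the qualitative
  pattern of the modeled study (XY⁻ consistently lower; testosterone
  lowering expression mainly in gonadal males).
* A single per-sample latent factor F ~ N(0,1) with loading 0.8 enters
  10 signal-transduction genes (Adcy1/2/5/7, Cdk5, Akt1/2/3, Pdyn, App)
  in gonadal-male groups only; with residual SD 0.5 the within-module
  correlation is loading²/(loading²+σ²) ≈ 0.72 where the module is
  active.  One latent factor is the simplest mechanism giving a
  controllable within-module correlation.
* CT construction is the exact inverse of quantification:
  `CT_target = CT_ref − (latent − log2 10,000)` with reference genes at
  CT 20, so zero-noise data round-trips to `2^latent` exactly (asserted
  at 1e-9).  Technical replicate noise SD 0.15 cycles over
  quadruplicates.
* Behavior measures = intercept + slope·latent(coupled gene) + noise,
  coupled positively to Trkb, Htr2c, Adcy5 and App — genes that
  therefore correlate negatively with the anxiety composite, as the
  measures are exploration-positive.
* All randomness derives from one seed through fixed per-stage
  sub-streams, so datasets are bit-reproducible.

What the generator does **not** emulate: amplification-efficiency
differences, missing wells, outlier animals, batch/plate effects,
non-Gaussian behavioral distributions, or any effect of the chronic
stress paradigm itself.  Passing tests therefore demonstrate that the
statistical machinery recovers known structure under clean Gaussian
log-scale noise — not that the pipeline is robust to real-data
pathologies beyond those explicitly handled (missing cells, degenerate
variance, undefined graph statistics).

## Problem sizes and numerical conventions

Simulation-based checks use deliberately modest sizes chosen to balance
statistical resolution against desk-scale runtime: permutation-test
calibration uses 500 null replicates of 10+10 samples × 12 genes at 200
permutations; module-detection power uses 100 replicates at 20 mice per
side; ANOVA type-I calibration uses 1,000 null datasets at 5 mice per
cell; end-to-end recovery uses 200 replicates.  Zero residual variance,
empty cells, missing references, undersized strata and regular graphs
all raise or flag explicitly rather than returning silent zeros.
Permutation p-values are add-one smoothed; p-values from perfect fits
are clamped to the smallest positive float so the BH step-up's (0, 1]
domain holds.

## Known limitations

* The assortativity convention (weighted degrees over a thresholded edge
  list) is one defensible reading of a formula written for discrete
  edges; published values computed under a different convention are not
  directly comparable.
* Tukey p-values use the full-model MSE with the studentized-range
  distribution; under strong imbalance this is the Tukey–Kramer
  approximation, not an exact test.
* The per-factor vs pooled BH family question is exposed as
  configuration rather than resolved.
* qPCR efficiency correction, standard curves and primer QC are out of
  scope; inputs are assumed to be clean CT tables.
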