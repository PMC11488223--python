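# Methods

## The assay model

The pipeline treats a plate as wells × conditions: unstimulated controls
(`NEG_CTL`), cytokine-stimulated controls (`POS_CTL`, IFN-γ + TNF-α), and
stimulated wells treated with MSC-EVs (`POS_EV`).  The biological claim being
operationalized is that EV bioactivity is measurable as the fraction of the
stimulation-induced morphology change that treatment reverses.  The analysis
chain is deliberately affine: per-well medians → control-anchored min-max
normalization → PCA projection.  Because every step after the median is an
affine map of the feature vector, the normalized PC1 of a treatment well is a
direct estimate of its position on the unstimulated(0)–stimulated(1) axis,
and Z′ is invariant to the normalization.

## Morphometry

* **Descriptors.** 7 descriptors × 3 compartments (cell, nucleus, cytoplasm
  = cell minus nucleus): Area (px²), Perimeter (px), Major/MinorAxisLength
  (px, 4√λ of the pixel-coordinate covariance eigenvalues), FormFactor
  (4π·A/P²), AspectRatio, Perimeter:Area ratio — 21 in total, plus Solidity,
  Eccentricity and the nucleus:cell area ratio for QC.  The published
  feature lists at this scale live in supplemental spreadsheets that are not
  redistributable; the 21-descriptor set above covers every named feature
  and matches the stated count.
* **Perimeter estimator.** Crofton estimate with 4 directions.  Chain-code
  boundary length was evaluated and rejected: on rasterized disks
  (r ∈ {20, 50, 100}) it yields form factors of 0.91–0.95 because digital
  staircases overshoot a smooth boundary by up to ~8%, while the Crofton
  estimate converges (FF 1.004–1.009 on the same disks).  A consequence is
  that *pixel-replication* upsampling genuinely lengthens the measured
  boundary; scale invariance of the dimensionless descriptors holds (within
  2%) when the same shape is rasterized at higher resolution.
* **QC.** Reject Solidity ≥ 1 − 1e-6 (perfectly convex blobs are debris or
  failed segmentation; the tolerance absorbs float noise on an intended
  equality cut) and nucleus:cell area ratio ≥ 0.85 (inclusive).  The ratio
  denominator is the whole cell: a cytoplasm-proper denominator can exceed 1
  and makes 0.85 an odd bound.  Both rules toggle independently.  Border
  cells are dropped before QC because truncated silhouettes corrupt every
  descriptor.
* **Mitochondria.** Intensity statistics, mass displacement
  (‖intensity-weighted − binary centroid‖), FracAtD over 4 equal-width rings
  of normalized distance-to-edge (index 1 = outer shell, 4 = core; fractions
  sum to 1), and GLCM texture (8 gray levels, offsets 1 and 3 px, symmetric,
  averaged over 4 directions): contrast, homogeneity, entropy, correlation.

## Scoring

* **Medians** over QC-passed cells; wells with < 50 cells are dropped
  (medians of fewer cells are unstable; real wells carry ~700–1000).
* **Min-max normalization** anchors per-feature control means at 0/1 and maps
  treatment wells by the same affine transform; values outside [0, 1] are
  legal.
* **PCA** is fit on all wells of the analysis by default so controls and
  treatment share one score space (a controls-only fit with projection is
  available).  Raw medians are z-scored first (correlation PCA); min-max
  normalized profiles are used as-is — the two modes mirror the two analyses
  the assay runs.  PC1 is sign-fixed so stimulated controls score high; an
  EV-induced shift toward the unstimulated phenotype therefore reads as a
  decrease.
* **Z′** uses sample (n−1) standard deviations, appropriate at 6–8 wells per
  group.  Labels: optimized (> 0.5), marginal (0, 0.5], unusable (≤ 0).
* **Dose–response**: per-dose mean ± sd of normalized PC1 and a Spearman
  trend statistic with a seeded permutation p-value (10,000 permutations by
  default).

## Synthetic data

The generator is the study-conditions oracle for the test suite, not a
microscopy simulator (no PSF, no illumination artifacts).

* **Latent shape model** per group: body radius, elongation, protrusion
  count, protrusion length (mean ± sd).  Defaults — unstimulated 18 px /
  1.3 / 2 / 8 px; stimulated 28 px / 2.2 / 5 / 25 px — are calibrated to
  reproduce the *ordering* of the real phenotypes (stimulated cells larger,
  more elongated, lower form factor) and optimized-assay Z′ behavior; the
  study does not publish numeric per-group effect sizes, so absolute values
  are not targets.
* **Rendering** draws each silhouette as a star-shaped polygon (ellipse +
  Gaussian radial protrusion bumps), a concentric elliptical nucleus with
  area ratio Beta(8, 12) clipped to (0.1, 0.8), and mitochondrial puncta
  (Gaussian spots, centers sampled from the eroded cell interior) over
  background noise.  Placement is rejection-sampled; > 20% failures raise an
  overcrowding error.
* **Fast path** (`gen_feature_table`) draws feature vectors directly:
  per-group mean vectors come from a deterministic latent→feature geometry
  map, per-cell noise is Gaussian with sd = 35% of each feature's control
  gap, and each well receives a common random offset with sd = 5% of the gap
  (rank-one across features, emulating seeding-density variation).  On the
  PC1 scale this puts the per-group well sd near gap/20, inside the
  calibration band (≤ gap/12) the Z′ acceptance check assumes.  Medians over
  ~850 cells shrink the cell-level noise ~22-fold, so well profiles are
  dominated by the well effect.
* **EV effect**: `ev_effect` ∈ [0, 1] interpolates the *latent* parameters in
  the rendering path but the *feature-scale group means* in the fast path
  (`POS_EV = POS_CTL + δ·(NEG_CTL − POS_CTL)` per feature).  Endpoints
  coincide; midpoints differ by the curvature of the geometry map.  The
  fast-path choice makes "normalized PC1 ≈ 1 − δ" a designed property of the
  generator rather than an accident of nonlinear feature maps — the
  parameter-recovery suite tests estimator bias, not map curvature.
* **Batch effects** are additive latent body-radius shifts per operator /
  experiment index.  In the fast path they are converted once to a common
  feature-space offset (evaluated at the unstimulated reference), applied
  identically to every group, so per-stratum ΔPC1 is exactly
  batch-invariant by construction.
* **QC fodder**: 2% of cells get Solidity = 1 (debris) and 1% a nucleus
  ratio in [0.85, 0.95); bounded auxiliary descriptors carry small fixed
  noise (sd 0.02–0.03) so the realistic few-percent rejection rate does not
  scale with the control gap.
* **Omics**: log-normal abundances with additive log2 group effects, so
  fold-change ground truth is exact.  Defaults mirror the assay's scale:
  200-analyte secretion panel, 94 detected, 40 stimulation-shifted (38 up /
  2 down) and 24 EV-shifted (10 up / 14 down) at |log2| ≈ 2 ± 20%; 2662
  proteins with 100 EV-responsive at |log2| = 2; 9 lipid classes
  (PC, PE, PG, PE-P, SM, Cer, HexCer, TG, LPC) where stimulation raises
  every class total except LPC and EV treatment changes none; residual noise
  sd 0.3 log2 units.  Flagged analytes have nonzero effects; all others are
  exactly zero.  Gene sets are random draws plus two sets loaded with
  EV-responsive proteins as positive controls.

What passing tests show — and don't.  The generator's noise is Gaussian /
log-normal with independent features (plus one rank-one well effect); real
single-cell features are heavier-tailed and correlated, real plates have
edge effects, and real segmentation errors are not independent of phenotype.
Passing recovery and calibration suites demonstrates the estimators are
correct under the stated model, not that real data meet that model.

## Omics statistics

* **Welch tests** per analyte (unequal variances, Welch–Satterthwaite df).
  Degenerate zero-variance cases: equal means → p = 1; unequal → p = 0 with a
  warning.  Panel significance defaults to raw p < 0.05 — the screening
  convention for these panels — with BH correction behind a flag.
* **log2 fold change** on raw abundance means with a pseudo-count (half the
  smallest positive matrix value) so zeros stay finite.
* **Moderated differential abundance**: per-protein group-mean linear model;
  residual variances shrunk toward a scaled-F prior whose (d₀, s₀²) come
  from moment matching of log s² (trigamma inversion by Newton, tol 1e-8).
  If the observed variance of log s² falls below the trigamma floor the
  prior df is infinite and all posterior variances collapse to s₀² (logged).
  Moderated t uses d₀ + d_g df; significance is the joint rule p < 0.05 and
  |FC| ≥ 2.
* **GSVA**: Gaussian kernel-ECDF per gene (bandwidth sᵢ/4), per-sample
  ranking, symmetrized rank weights |p/2 − rank|^τ (τ = 1), random walk with
  in-set increments normalized over the set and out-of-set decrements
  1/(p − |set|); ES = max positive + min negative deviation (`mx_diff`,
  default) or the signed max-magnitude deviation.  Sets are filtered to
  5–500 measured genes; the matrix must carry at least twice the largest
  set.  Exact antisymmetry under rank reversal fails by the half-position
  offset of the symmetrized ranks; tests assert it within 0.12 on a
  60-gene input.
* **Ward.D2** via the Lance–Williams recurrence on Euclidean distances
  (scipy's Ward linkage); heights are on the distance scale and are
  non-decreasing.  Per-set ANOVA → Tukey HSD → BH across sets at q ≤ 0.05.

## Problem sizes and numerical choices

The test and acceptance simulations run at the assay's stated scale (8 wells
per group, 700–1000 cells per well) with 50 seeds for recovery, 8 fixed
seeds for assay quality, and 100 repeats for null calibration; oracle suites
(Welch, BH, Ward, GSVA) run on small exact fixtures.  Scoring requires ≥ 3
wells, ≥ 2 control wells per side, and a non-degenerate control gap per
feature (equal control means raise an error naming the feature).  All
randomness flows from explicit integer seeds through `SeedSequence`; two
same-seed runs are byte-identical, which the suite audits by checksum.

## Known limitations

* The rendered and fast-path feature distributions agree in location and
  ordering but not exactly in higher moments; cross-path tests compare
  orderings, not distributions.
* GSVA is implemented for continuous (log-intensity) matrices only — no
  Poisson kernel for counts.
* No plate-position (edge-effect) correction and no time-course modeling;
  the assay is a single 24 h endpoint.
* STRING/pathway retrieval is out of scope: degree ranking operates on a
  user-supplied edge list.
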