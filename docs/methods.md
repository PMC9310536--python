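# Methods

## Overview

`mitosig` implements two computational arms for studying keratinocyte
metabolic state in vitiligo skin, joined by a synthetic-data module that
supplies ground truth for every stage.

1. **Mitochondrial clustering (imaging arm).** NADH two-photon fluorescence
   texture reports mitochondrial organisation because mitochondria-bound
   NADH fluoresces roughly ten-fold brighter than free cytosolic NADH.
   The clustering metric β is the exponent of an inverse power law fitted
   to the radially averaged power spectral density (PSD) of an en-face
   image, R(k) = A·k^(−β). Fragmented mitochondria (glycolysis-leaning
   cells) produce clumpy textures and high β; fused networks
   (OxPhos-leaning) produce low β. Per-slice β assembled over an epidermal
   z-stack gives a depth profile; stacks are summarised by median β and β
   variability and compared across conditions with a linear mixed model.

2. **Signature scoring (expression arm).** Per-cell gene-set scores with
   bin-matched control genes, a scan of 21 metabolic pathways against a
   stress-keratinocyte signature, differential-expression counting inside
   pathway universes, and cell-state composition tables.

## Beta estimation

* **Radial PSD.** Mean subtraction, optional Hann window, 2-D DFT, squared
  modulus normalised so the PSD sums to the spatial-domain sum of squares
  (Parseval, exact to machine precision), averaged in annuli one frequency
  bin `1/(N·pixel)` wide. DC excluded; annuli extend to the spectral
  corner.
* **Fit.** Ordinary least squares of log power on log k with equally
  weighted annuli: exact on pure power laws and fully reproducible.
  β = −slope, A = exp(intercept). Default band 0.5–5 µm⁻¹ targets
  structures of ~0.2–2 µm while excluding field-scale frequencies; it is a
  configuration field because the optimal band depends on optics. Fits
  with R² < 0.7 are flagged `poor_fit` and report no β (the raw slope is
  kept in `beta_raw` for diagnostics — note a genuinely flat spectrum has
  R² ≈ 0 by construction, so white-noise fields are deliberately not
  assigned a β). Images whose mean intensity is below 1 photon, masks
  covering < 10 % of pixels, or bands with < 5 positive annuli yield
  `low_signal`.
* **Void handling.** Nuclei, borders and background are replaced by
  texture mirrored across the nearest mask boundary (EDT nearest-pixel
  indices, reflected coordinate, fallback to nearest). Zero-filling is not
  used because the void geometry would dominate the spectrum; the mirror
  clone keeps β within 0.1 of the void-free fit on oracle images.
* **Per-cell analysis.** Each labelled cell's bounding box is grown to an
  even square, non-cell pixels treated as void, and the same pipeline
  applied. Cells below `min_cell_px` (default 64², about a 12 µm cell at
  the default sampling) are skipped as `low_signal`.
* **Heterogeneity index.** IQR/median of per-cell β, with type-7 (linear
  interpolation) quartiles — the value depends on the quantile rule, so it
  is fixed and documented. This is a documented stand-in for a dispersion
  summary whose authoritative definition we do not control; it is 0 for
  identical cells and scale-invariant.

## Depth profiles and cohort statistics

* Depth origin is the first analysed slice; depth = slice index × z-step
  (5 µm default, matching clinical acquisition).
* The smooth curve is a cubic smoothing spline with the penalty selected
  by generalized cross-validation (`scipy.interpolate.make_smoothing_spline`),
  overridable; on noiseless schedules it reproduces the programmed values
  to ≤ 0.05. Profile minima are located on a 101-point grid with ties
  broken toward shallower depth.
* β variability defaults to the IQR of per-slice β (robust to stack
  length); SD is available via a flag.
* **Group comparison.** `metric ~ condition + (1|patient) + (1|site)`,
  REML via statsmodels MixedLM (site modelled as a variance component
  nested in patient groups). The condition coefficient is tested with a
  Wald t statistic on residual degrees of freedom (N − 2). We use a t
  rather than a z reference so that the model degenerates *exactly* to the
  pooled two-sample t-test when the variance components vanish; with the
  within-patient designs simulated here this choice keeps the Monte-Carlo
  type-I error within [0.02, 0.09] at α = 0.05 and power ≥ 0.9 at a 0.3
  shift in median β (200 replicates each). Satterthwaite degrees of
  freedom are out of scope.
* **Zero-variance boundary.** Optimisers often stop just inside the
  boundary when the REML optimum is at zero variance. The profiled REML
  log-likelihood is therefore evaluated at (numerically) zero components;
  when it comes within 0.01 of the fitted optimum the likelihood is flat
  against the boundary and inference switches to the exact OLS limit,
  which equals the pooled t-test. Fits with a single patient in a group or
  failed optimisations fall back to the t-test with a logged note.
* **Longitudinal labelling.** Follow-up (treated) profiles are compared
  with the nonlesional reference on both metrics; "normalized" requires
  both p ≥ α, otherwise "persistent".

## Synthetic images

* **Spectral synthesis (default, exact oracle).** Fourier amplitudes are
  set deterministically to k^(−β/2); phases come from a white Gaussian
  field, which guarantees Hermitian symmetry (real output) without
  disturbing the amplitude profile. Shifting to non-negativity and
  rescaling to the target mean touch only DC and overall scale, so the
  non-DC radial PSD slope is exactly −β: the estimator recovers β to
  < 0.001 at 512 px. This exactness is the reason spectral synthesis is
  the default stack generator.
* **Mechanistic textures.** Curvilinear mitochondrial segments in a
  cytoplasm sheet with elliptical nuclear voids, Voronoi cell labels,
  Gaussian PSF blur (σ = 0.15 µm, a clinical two-photon lateral scale) and
  Poisson shot noise at 50 photons mean plus Gaussian read noise σ = 2.
  Fragmentation f ∈ [0, 1] controls three coupled morphology dials:
  segment length (10 µm → 0.6 µm), aggregation of segment origins around
  foci (spread 30 µm → 0.8 µm, geometric interpolation) and structure
  width (0.06 µm → 0.16 µm Gaussian element). Wider, clumpier granules
  concentrate spectral power at low-mid frequencies, so fitted β rises
  monotonically with f (Spearman ρ ≈ 0.97 over 5 levels × 20 replicates).
  Because blur and noise tilt the absolute spectrum, mechanistic analyses
  use a 0.3–1.5 µm⁻¹ band and only order/robustness properties are
  asserted — absolute β values on this generator are not calibrated.
  Melanin puncta are Gaussian spots (σ = 0.2 µm, 5× cytoplasm brightness);
  at ≤ 2 puncta/100 µm² they move median β by ≲ 0.04, mirroring the null
  effect of melanin content differences between sun-exposed and
  non-sun-exposed skin.
* **Stacks and cohorts.** Named depth templates encode the epidermal
  course of β: "nonlesional" (1.6, 1.5, 1.1, 0.9, 1.0, 1.3 anchors,
  interpolated) with its minimum in the mid-stack (spinous-layer
  behaviour), and a flattened "lesional" template (1.3 … 1.15 … 1.25).
  Anchor values are modelling choices shaped to the qualitative curves,
  not measurements. Cohorts draw per-stack median-β targets from
  μ + Δ·1[lesional] + b_patient + b_site + ε with defaults 12 patients,
  2 sites/condition, 3 stacks/site, sd_patient = 0.1, sd_site = 0.05,
  sd_residual = 0.1, baseline 1.2 — a within-patient design mirroring
  matched lesional/control imaging. Monte-Carlo calibration uses the
  metric-level fast path (`cohort_metrics`); rendering all images for
  hundreds of cohorts would add nothing because β estimation is validated
  separately on the oracle, and the fast path is exactly the model the
  mixed model assumes. Full image rendering is exercised end to end in the
  CLI tests and in `synth_cohort`.

## Synthetic expression

Negative-binomial counts (gamma–Poisson): gene-wise base means log-normal
(µ = 1, σ = 1 in natural-log space), dispersion 0.5, library sizes
log-normal around 5000 counts/cell (σ = 0.3) — typical droplet scRNA-Seq
shape. Cell states follow a default template in which stress keratinocytes
appear only under the lesional condition (200 of 1300 lesional cells;
2500 cells and 2000 genes overall — sizes chosen so the whole expression
arm runs in seconds). Stress cells multiply the means of three disjoint
20–30-gene sets by 2^lfc: OxPhos +1, glycolysis −1, stress markers +2 by
default. Non-stress states carry small private marker blocks placed
outside all annotated sets so that the 19 null pathways stay null. The
bundled 21-pathway GMT is a synthetic placeholder collection (named
`metabolic_pathways_synthetic.gmt`) keyed to the generator's gene naming;
any user GMT is accepted.

What the generator does **not** emulate: dropout beyond NB sampling,
batch/chemistry effects, ambient RNA, doublets, cell-cycle structure, or
real marker-gene identities. Passing tests therefore demonstrate that the
analysis recovers programmed signals of realistic magnitude under NB
noise — not that it is robust to every artefact of real droplet data.

## Scoring and testing choices

* **Signature score.** Mean normalised expression (library scaling to 10⁴,
  log1p) of the set minus the mean over controls sampled per set gene from
  the same 25-bin average-expression stratum (100 controls/gene, seeded,
  de-duplicated, never overlapping the set). `n_ctrl=0` degrades to the
  plain mean score. Random sets centre on zero in expectation; single
  draws retain within-bin heterogeneity noise of order ±0.1.
* **Wilcoxon rank-sum.** Exact enumeration of all C(n+m, n) label
  assignments when n+m ≤ 12 and the pooled sample is tie-free; otherwise
  the normal approximation with tie and continuity correction. The exact
  branch matches brute-force enumeration on every split of ≤ 10 values and
  the approximation matches a 10⁴-permutation oracle within 2×10⁻²; both
  branches agree with `scipy.stats.mannwhitneyu` (which serves as an
  independent cross-check, not as the implementation).
* **Enrichment scan.** Pearson r is computed between per-cell pathway and
  stress scores over *all* keratinocytes (stress + other), matching the
  scan's axis definition; rows sort by |Δscore|.
* **DE counting.** Per-gene rank-sum p (vectorised normal approximation),
  log2 fold change of mean normalised expression (ε = 10⁻⁹), and
  Benjamini–Hochberg within the universe; DE = FDR < 0.05 ∧ |lfc| ≥ 0.25.
  Thresholds are flags because no authoritative criterion is fixed; counts
  are validated only against programmed ground truth.

## Numerical and degenerate-input conventions

* Constant images → zero PSD → `low_signal`; flat spectra → `poor_fit`.
* Quantiles everywhere are numpy type-7.
* Ties in profile minima resolve toward shallower depth.
* Seeds: every stochastic routine takes an explicit seed; identical
  spec + seed is bit-identical. Sub-seeds derive via `SeedSequence` and
  stay below 2³¹.

## Known limitations

* The heterogeneity index and the fit band are stand-ins for supplementary
  definitions not available here; both are documented and configurable.
* Mixed-model p-values use residual-dof Wald t, not Satterthwaite or
  Kenward–Roger corrections; with few patients and strong random effects
  they can be anticonservative.
* The mechanistic texture generator is a phenomenological stand-in for
  mitochondrial morphology, tuned only for monotone ordering.
* Absolute β values depend on the configured band, windowing and optics;
  cross-study comparison requires identical configuration.
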