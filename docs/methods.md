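# Methods

## Generative model of a subtractive-proteomics study

The simulator emulates the *measured structure* of a silica-bead PM capture
plus differential-ultracentrifugation experiment, not the physics of
acquisition. For protein *p* in sample *s* (cell line × fraction ×
replicate), the log2 abundance is

    x_ps = b_p + δ · 1[fraction(s) enriches home(p)] + ε_ps,   ε ~ N(0, σ²)

- `b_p ~ N(8.0, 2.0²)` — per-protein baseline on a normalised log2-iBAQ-like
  scale where the low-value imputation band [1.0, 1.2] sits below the
  observed range.
- Every protein has a *home compartment*. Planted PM residents are homed at
  the PM fraction; background proteins are homed uniformly in one of three
  compartments: cytosolic, nuclear, or a mixed *membrane* compartment that
  is co-elevated in both the mitochondria and microsome fractions. This
  yields exactly four abundance classes, matching the four clusters such
  fractionation data resolve (nuclear / cytosolic / mixed membrane /
  surface), and makes k = 4 clustering a well-posed recovery problem.
- `δ = delta_pm` (default 3.0 log2 units) is the home-fraction enrichment;
  `σ = sigma_noise` (default 0.5) the replicate noise. The default design is
  4 cell lines × 5 fractions × 3 replicates (60 runs), 5000 proteins, 50
  planted PM residents, one of them tumour-exclusive.

**Missingness** is missing-not-at-random through a logistic link on the
realised abundance: `P(missing) = expit(slope · (midpoint − x))` with
midpoint 5.0 and slope 1.0 by default, i.e. a soft detection limit around
log2 ≈ 5 giving ~10 % overall dropout. `slope = 0` disables dropout
entirely (the noise-free limit used by several tests). The mechanism of the
real data is unknowable from the processed tables; the logistic detection
limit is an assumption and is exposed as configuration.

**Annotations.** Planted PM proteins always carry GS ≥ 20 and SPC ∈ {3, 4};
a configurable 5 % of background proteins also pass, to exercise
false-positive filtering. Cancer-panel detection is Bernoulli per line
(rate 0.01 for exclusive markers, 0.30 for everything else over 142 lines,
so non-exclusive proteins essentially never pass the ≤ 5-line cut:
P(Bin(142, 0.3) ≤ 5) ≈ 1e-22). Antibody availability is Bernoulli(0.85);
exclusive markers always have a usable antibody — they are defined as the
recoverable planted target, mirroring the fact that a candidate without an
antibody could never have been taken forward. Normal-tissue panels (one
ordinal IHC panel with levels 0–3, two protein panels, one RNA panel; 30
tissues) give exclusive markers all-zero values and background proteins
log-normal values (protein panels: meanlog 5, sdlog 1; RNA: meanlog 3).

**Survival cohort.** Stain positivity is Beta(2, 5) · 100 %. Event times
for PFI and OS are exponential with log-hazard
`log(HR) · 1[upper tertile] − 0.5 · EOR − 0.4 · RT` and baseline hazards
0.02 and 0.01 per month. Censoring is uniform, `C ~ U(0, τ)`, with τ
calibrated by bisection so the expected censored fraction equals
`censor_rate` (default 0.30); given τ, censoring is independent of the
event process, so partial-likelihood estimation remains valid. Defaults:
25 patients (typical of a rare-tumour IHC cohort); recovery experiments use
150–300.

All generator stages draw from independent seed streams derived from the
config seed; identical configs give byte-identical serialized outputs.

## Processing and statistical choices

- **Pipeline order is fixed**: identification filters → log2 →
  median-normalise → impute. Normalisation statistics use observed values
  only; imputation never touches an observed entry.
- **Median normalisation** shifts each sample so its observed median equals
  the global median of per-sample medians (rather than zero-centring), so
  imputed values near 1–1.2 stay "low" relative to the data scale.
- **Imputation** is i.i.d. U[1.0, 1.2] per missing cell, seeded; a constant
  midpoint variant is available (`method="constant"`). The uniform band is
  the simplest distribution consistent with low-value imputation.
- **Protein identifier** is the first entry of "Majority protein IDs"; zero
  intensity means not quantified.
- **Welch tests** use Satterthwaite degrees of freedom
  (scipy's `ttest_ind(equal_var=False)` behind the `welch_t` surface). The
  degenerate zero-variance-both-groups case follows an explicit contract
  (equal means → p = 1; unequal → p = 0) rather than propagating NaN.
- **BH adjustment** (statsmodels `fdr_bh` behind `bh_adjust`) is applied
  within each (cell line, fraction pair) family by default, since the
  subtractive analysis is framed per cell line and per comparison; a
  per-cell-line pooled family is available as configuration. The test suite
  pins the implementation to the literal step-up definition
  `q(i) = min(1, min_{j≥i} p_(j)·n/j)` exhaustively on short vectors.
- **Call rule**: PM-enriched in a cell line ⇔ q < 0.05 *and* signed
  log2FC > 1 toward PM against every non-PM fraction (intersection over
  comparisons). Headline recovery is reported at the protein level as
  "called in ≥ 2 cell lines", the same consistency level the mining funnel
  uses.
- **Clustering** is Ward linkage on Euclidean distances of per-protein
  z-scores (constant rows get z = 0 so no detected protein is dropped);
  linkage and metric are conventional for z-scored abundance heatmaps and
  exposed as arguments.
- **Rank-sum prioritisation** uses average ranks on ties; each panel's rank
  is computed on the across-tissue median (continuous panels) or the
  proportion of tissues at IHC level 0 (ordinal panel, ranked descending).
  Final ties break lexicographically by protein id for determinism. A
  candidate absent from a panel is treated as not detected (best value) by
  default, with `worst` and `exclude` policies available.
- **Tertile cut**: linear-interpolation 2/3 quantile; patients strictly
  above it are "upper". For n = 25 this puts 8–9 patients in the upper
  group.
- **Cox models** (lifelines) use Efron tie handling; non-convergence and
  separation raise explicit errors rather than returning silent estimates.

## Problem sizes used in tests and the acceptance script

Unit tests run on 200–600-protein studies; pipeline-level recovery checks
use the full default design (5000 proteins × 60 samples), 10–20 replicate
studies for funnel/null-calibration rates, and 100–200 replicate cohorts
for CI coverage. These sizes make the whole suite run in well under a
minute of simulation time while keeping Monte-Carlo error small relative to
the asserted margins.

## Known limitations — what recovery on synthetic data does and does not show

- The generator produces clean block-structured compartments with
  homoscedastic noise; real fraction proteomes mix compartments
  continuously, have protein-specific variances, batch structure and
  correlated peptide-level errors. Passing recovery tests validates the
  *logic and calibration* of the pipeline, not its power on any particular
  real dataset.
- **Sensitivity of the subtractive stage at the default design is
  intrinsically limited.** With 3 replicates per group, a planted protein
  whose baseline-level replicates in a non-PM fraction are partially
  imputed gets a group like (8.1, 7.9, 1.1): the variance estimate
  explodes, the Welch degrees of freedom collapse toward 2, and the
  BH-adjusted q lands near the 0.05 boundary even for a 3-log2-unit
  enrichment. Measured at defaults (seed 7): per-comparison pass rate
  ≈ 0.50 for planted proteins, protein-level sensitivity ≈ 0.26–0.40
  depending on the call level, with a false-discovery proportion of 0 and a
  well-calibrated global null. This is a property of few-replicate Welch
  testing after low-value imputation — the same trade-off the real design
  faces — not an implementation artefact; the acceptance suite asserts a
  0.90 sensitivity bound and documents the shortfall rather than relaxing
  the conditions. Recovery is essentially complete when dropout is disabled
  or replicates/effect size increase.
- The funnel's top-1 recovery inherits the subtractive stage's sensitivity:
  the planted exclusive marker is top-ranked exactly when it survives the
  ≥ 2-line enrichment requirement.
- The survival generator uses exponential baselines and independent uniform
  censoring; proportional hazards hold exactly by construction, so Cox CI
  coverage checks calibration, not robustness to misspecification.
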