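# Methods

## Scope and data model

`wheatfusion` operates on plot-level tables: one row per plot × growth
stage carrying five band reflectances (blue, green, red, red-edge, near-IR,
each in [0, 1]), canopy temperature (°C), plot identity (genotype,
irrigation treatment, replicate) and the measured grain yield (t ha⁻¹).
Everything upstream of that table — flight planning, orthomosaics,
radiometric calibration, plot segmentation — is out of scope.

## Vegetation-index registry

The registry holds 21 reflectance indices plus NRCT. Index formulae
circulate in typographically corrupted variants; the registry stores the
canonical form from each index's original developer and records the repair
in `IndexDefinition.note`:

- MSR = (ρ − 1)/√(ρ + 1) with ρ = NIR/R, RDVI = (NIR − R)/√(NIR + R), and
  MTVI2's square-root denominator are restored (the corrupted forms drop the
  roots);
- EVI's denominator is NIR + 6R − 7.5B + 1; OSAVI uses the canonical soil
  constant 0.16 (with the ×1.16 normalization).
- PSRI = (R − B)/NIR, SIPI = (NIR − B)/(NIR + B) and the red-edge MCARI
  variant are kept exactly as used by the source protocol even though other
  published variants exist.

NRCT is min–max normalized within a *flight group*. Default grouping is
stage × treatment (one thermal flight per treatment per stage); a stage-wide
group is selectable. A degenerate group (constant temperatures, or a single
plot) cannot anchor the normalization: library calls raise by default, while
the feature-table builder substitutes 0.5 with a warning so a pathological
synthetic input does not stall the pipeline.

## Gray relational analysis

All series are made dimensionless by dividing by their own mean (hence a
zero-mean series is a hard error naming the series). Δmin and Δmax are
taken globally over all comparison series and samples, not per feature.
γ ties are broken by stable sort in registry order, so rankings are
deterministic. The per-stage feature count is the smallest k whose
training-phase MAE (the best inner-CV MAE of the grid search on the top-k
features) is within a relative tolerance, default 1 %, of the curve minimum
— a monotone-safe reading of "the curve has stabilized". Whether the
original protocol's curve used inner-CV or training-fold MAE is not
determinable; inner-CV MAE is used and the output labelled accordingly.

## Elastic net: parameterization and solver

The estimator minimizes ‖y − Xβ‖² + λ₂‖β‖² + λ₁‖β‖₁ but is exposed through
(λ₂, fraction): fraction s is the coefficient L1 norm relative to the
unconstrained (λ₁ = 0) solution at the same λ₂. s = 0 is the intercept-only
model; s = 1 with λ₂ = 0 is OLS. Predictors are centered and scaled to unit
variance inside the fit (penalty fairness across indices of very different
scales); the response is centered; coefficients are returned on the
original scale; zero-variance columns are dropped with a warning.

Solver: for fixed λ₂ the problem is a lasso on ridge-augmented data (rows
√λ₂·I appended), whose full LARS path is computed once; coefficients along
the path are piecewise linear in the L1 norm, so evaluation at the target
norm is exact interpolation. Final fits add a coordinate-descent polish at
the matched penalty, which restores exact symmetry where LARS tie-breaking
is unstable (e.g. duplicated columns — the grouping effect is verified to
1e−6 in the tests). The contract is on the optimum, not the algorithm.
Grid-search scoring reuses one path per (fold, λ₂) and reads all fraction
candidates off it, which is what makes the 900-candidate grid affordable.

Default candidate lists are 30 λ₂ values (0.05–1.00) and 30 fractions
(0 and a geometric ladder to 0.1), crossed by default (900 candidates) with
a paired mode (30) selectable; both conventions are found in practice and
the original protocol's choice is not determinable. Note the default
fraction ladder tops out at 0.1: with standardized predictors sd(Xβ) ≤
‖β‖₁, so this ladder structurally caps how much of the yield variance a fit
can reproduce. That is appropriate for noisy field data but not for
parameter-recovery experiments, which use `recovery_grid()` (fractions up
to 1) instead.

## Cross-validation protocol

Outer 10-fold CV repeated 50 times (500 outer fits), inner 10-fold grid
search per outer training split; the winning candidate minimizes the mean
inner-test MAE (RMSE selectable). Folds are plot-level, unstratified,
shuffled; all randomness derives from one seed through
`numpy.random.SeedSequence` sub-streams keyed by (repeat, fold), so a run
is exactly reproducible and repeats are mutually independent. Held-out
metrics are R² = 1 − SSres/SStot, RMSE, RRMSE = RMSE/ȳ·100 and MAE; the
headline value of a repeated-CV experiment is the mean over folds.

The multi-stage baseline concatenates stage feature tables column-wise
(names suffixed by stage) and runs the identical protocol.

## Entropy-weight fusion

Within every outer fold, each member stage is tuned and refitted on the
outer-train split only; its training-side errors come from inner
out-of-fold predictions rather than resubstitution (a tuned model's
resubstitution errors understate E and would distort the weights). The
capped relative errors are normalized across plots within each stage
(P rows sum to 1), entropies use k = 1/ln(n_plots) with 0·ln 0 := 0, and
the weight rule wᵢ = (1/m)(1 − dᵢ/Σd) gives the *higher-entropy* (more
uniform-error) stage the larger weight. Raw weights sum to (m − 1)/m by
construction, which would bias every fused yield low by 1/m, so they are
renormalized to sum to one before fusing; both raw and normalized weights
are reported per fold.

Degenerate cases: a stage whose training errors are all zero (to machine
precision, threshold 1e−12) is the limit of uniformly shrinking errors and
is assigned h = 1, d = 0 — the largest weight — with a warning; if every
stage is maximally entropic the weights are uniform. Errors below the
threshold are treated as exact zeros because entropy ratios of rounding
noise carry arbitrary structure.

The index bookkeeping in the published recipe is self-consistent only with
i ranging over stages, j over plots, and n in k = 1/ln(n) the plot count;
that mapping is adopted throughout.

## Synthetic-trial generator

The generator emulates the study design: 30 genotypes × 3 irrigation
treatments (high/moderate/mild) × 2 replicates = 180 plots, observed at six
stages. Yields are treatment-level truncated normals calibrated to means
7.09 / 5.99 / 4.40 t ha⁻¹ and CVs 12.70 / 16.10 / 19.51 % (the moderate CV
is not published; 16.1 % interpolates its neighbours), truncated to the
observed 2.79–8.64 t ha⁻¹ range. Pre-truncation (μ, σ) are moment-matched
with `scipy.stats.truncnorm` so truncation does not bias the calibration
(naively it shifts the high-treatment mean by ≈ 1.2 %).

Sampling scheme: genotype merit scores form a stratified standard-normal
panel (quantile-spaced, randomly assigned to genotype labels), and within
each treatment the latent plot deviations are rank-mapped onto exact
standard-normal quantile scores — randomness lives in the rank assignment,
so a realized trial hits the calibration targets instead of scattering
around them (treatment means and CVs are within 0.1 % of target already at
20 replicates per genotype). `genotype_sd` and `residual_sd` set the
genotype : plot-residual variance split (default 0.6 : 0.3 t ha⁻¹, i.e.
80 % genotypic — a high-heritability, well-managed trial); with
`treatment_cvs=None` they act as absolute sds. Setting both to zero yields
exactly the treatment means.

Canopy observations follow a per-stage greenness link: greenness = a(stage)
+ b(stage)·z with z the standardized yield, rising from jointing
(a = 0.35) to grain filling (a = 0.70) and falling at maturity (a = 0.45)
where the yield slope is also weakest (b = 0.015 vs 0.08 at grain filling)
— the senescence effect that makes late-stage prediction hard. Bands are
affine in greenness (NIR strongly increasing, red/blue decreasing, green
and red-edge mildly increasing), clipped to [0, 1], with Gaussian noise
(default sd 0.01). Canopy temperature is affine in z with a strictly
non-positive slope (default −0.8 °C per yield sd; cooler canopies
transpire and yield more) plus noise (sd 0.5 °C). With all noise knobs at
zero the NIR−red difference is exactly affine in yield, so the full
pipeline must recover the link (out-of-fold R² ≥ 0.99) — the package's
strongest correctness check.

What the generator does *not* emulate: spatial autocorrelation between
neighbouring plots, genotype × treatment interaction, weather, sensor
drift, or saturation of indices in dense canopies. Passing tests therefore
demonstrate the correctness of the machinery under the stated statistical
structure, not field-data performance.

## Problem sizes in the shipped checks

The test-suite and acceptance runs use the full 180-plot design with
reduced resampling (single-digit outer repeats, 3–5 inner folds, compact
grids) — the protocol's structure at a problem size a laptop handles in
seconds to minutes; the 10 × 50 × 10 defaults remain available through
configuration.

## Known limitations

- The fraction parameterization follows one established convention; fitted
  coefficients at intermediate fractions can differ from solvers using a
  penalty-ratio parameterization even when both are correct optima.
- Entropy weights reward error uniformity, not error magnitude: a stage
  predicting near the mean everywhere can out-weight a better but less
  uniform stage. This is faithful to the published rule; the fusion's
  benefit is averaging, demonstrated under equal-variance stage noise.
- Paired significance tests across the eight stage combinations are
  reported without multiple-testing correction, matching the protocol;
  reports note this.
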