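# Methods

This note records the modeling assumptions, default parameters, numerical
choices and known limitations of the package. It states nothing the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic cohort generator (`fhmeth.synthdata`)

The generator emulates the data structure of a two-group blood-methylation
study of familial hypercholesterolemia:

* **Design.** 78 FH mutation-negative and 58 mutation-positive samples
  (all male). Ages are drawn from group-specific normals — mutation-negative
  50.7 ± 12.3 years, mutation-positive 38.1 ± 12.0 — truncated to [18, 90]
  (an adult referral cohort). The published abstract lists 39.1 for the
  mutation-positive mean where the cohort table lists 38.1; the generator
  follows the table.
* **Cell mixtures.** Per-sample proportions of six leukocyte types (CD8T,
  CD4T, NK, B cells, monocytes, granulocytes) are Dirichlet with
  concentrations (10, 10, 2, 2, 2, 30): granulocytes dominate whole blood
  and T cells come next, which gives the regression covariates realistic
  collinearity stress.
* **Probes.** Each probe has a per-cell-type profile: marker probes carry
  the reference panel's discriminating profiles (own type 0.75–0.95,
  others 0.05–0.25, guaranteeing ≥ 0.3 spread and full column rank, as in
  curated sorted-blood panels); other probes get a bimodal baseline
  (logit-normal modes at expit(±2.5) ≈ 0.08/0.92 and a central mode,
  weights 0.4/0.4/0.2 — array betas are bimodal) plus small per-type
  deviations (logit SD 0.15) so cell composition moves every probe a
  little, as on real arrays.
* **Signal and noise.** The mean beta is the mixture mean, plus a spiked
  group difference `delta_beta` (added to mutation-negative samples; the
  generator refuses spikes that push any mean outside [0, 1]), plus an
  optional linear age trend. Noise is added on the logit scale
  (`noise_sd_logit`, default 0.1 ≈ beta SD 0.025 at mid-range — typical
  array probe variability) and results are clipped to [0.001, 0.999];
  beta-scale noise would violate the range.
* **SNP artifacts.** A probe can be overwritten by a three-level genotype
  signal with Hardy–Weinberg frequencies (1−p)², 2p(1−p), p² — the
  two-or-three-cluster pattern that flags an underlying SNP on real
  arrays.
* **Hidden truth** (proportions, ages, spikes, genotypes) is returned and
  serialised so recovery can be asserted.

What the generator does **not** emulate: batch/slide effects (the study
randomised samples across slides), probe-type chemistry differences,
spatial correlation of neighbouring CpGs, genotype–methylation coupling
beyond single artifact probes, and any real biological covariance
structure. Passing tests therefore demonstrate correctness and calibration
of the statistical machinery under the stated generative model, not
performance on real EPIC data.

## Cell deconvolution (`fhmeth.deconv`)

Per sample: minimise ‖y − Xw‖² subject to w ≥ 0 and Σw ≤ 1, where X is
the marker-probe reference. Solved per sample by SLSQP on the quadratic
objective with analytic gradient, `ftol` 1e−14, bounds [0, 1]; solutions
with Σw marginally above 1 (beyond 1e−8) are renormalised. Noise-free
mixtures are recovered to ≈ 1e−8. Both the raw solution and the
renormalised w/Σw are reported; the regression uses the renormalised
proportions by default (whether the original analysis entered raw or
renormalised proportions is not documented; a flag switches).

## Per-CpG statistics (`fhmeth.dmp`)

* **Scale.** Default is the beta scale, so effects read directly as
  methylation-fraction differences (a −0.013 effect is "1.3% lower
  methylation"); M-values are available via `scale='m'`.
* **Design.** Intercept, group (1 = mutation-negative), age, five cell
  proportions (granulocytes, the largest component, dropped — the
  proportions sum to one and would otherwise be collinear with the
  intercept). Rank deficiency raises an error naming the collinear
  columns. Zero-variance probes are flagged degenerate and excluded from
  inference.
* **Moderation.** limma-style: a scaled inverse-χ² prior (d₀, s₀²) fitted
  by method of moments on log variances (trigamma inversion by Newton
  iteration), posterior variance (d₀s₀² + df·s²)/(d₀ + df), moderated t
  on df + d₀ df. d₀ = ∞ (all variances compatible with one pooled value)
  falls back to the normal reference distribution. The implementation is
  cross-checked against Bioconductor limma's `eBayes` (t, prior df, prior
  variance) in `tests/test_dmp.py`.
* **Inflation correction.** Three-component Gaussian mixture EM on the
  z-scores: null N(μ₀, σ₀²) plus symmetric tails at μ₀ ± μ₁ with common
  SD σ₁ and free weights. Identifiability constraints μ₁ ≥ 2σ₀ and
  σ₁ ≥ σ₀ keep the tails from absorbing the shoulders of a pure-null
  input (an unconstrained EM under-recovers σ₀ by ~6%; constrained, the
  recovery error is ~1% at n = 10,000 while a 5% contamination at mean 4
  is still isolated into the tail component). Initialisation from
  median/MAD; 200 iterations max, log-likelihood tolerance 1e−6;
  non-convergence falls back to the median/MAD null with a warning. With
  fewer than 1000 z-scores the fit is unstable and an identity correction
  is applied (logged). λ = median(z²)/0.4549 is always computed on the
  uncorrected scores.
* **FDR.** Benjamini–Hochberg over inflation-corrected p-values;
  within-tier by default for the candidate analysis (`--fdr-scope genome`
  switches), since whether the original FDR was computed within tiers or
  genome-wide is not documented. Tier tables are row subsets of one
  genome-wide fit — no per-tier refitting — and inflation correction is
  applied genome-wide before tier subsetting (it models the full
  test-statistic distribution).

## Candidate tiers (`fhmeth.tiers`)

Tiers 1–2 are fixed (major/minor FH genes); tier 3 (GWAS lipid genes) and
tier 4 (published candidate CpGs, default cg00574958 in *CPT1A*) are
configuration, since their full published lists live in supplementary
material — content is data, not algorithm. Gene windows are
[start − 3000, end + 3000], 1-based, both ends inclusive, clamped at 1;
genes in multiple tiers are analysed independently per tier. Sex-chromosome
probes are retained by default (single-sex design; `drop_sex` available).

## Discriminator (`fhmeth.ml`)

Defaults follow the study protocol: 50 outer repeats of a stratified
80/20 split, 5-fold stratified CV, 1000 label permutations. Choices the
protocol leaves open, resolved here:

* **Booster.** LightGBM, single-threaded and deterministic. Small
  hyperparameter grid (depth 2–3, learning rate 0.05/0.1, 150 rounds):
  with n ≈ 136 ≪ p a larger grid only overfits the CV estimate.
* **"Combination of multiple gradient boosting classifiers".** Per
  repeat, the five CV fold-models' predicted test-set probabilities are
  averaged (a small ensemble). A single refit-on-full-training model is
  the natural alternative; the ensemble uses the models the CV already
  paid for.
* **Stability selection.** Inside each repeat (leak-free), 50
  class-stratified 50% subsamples, selection = nonzero tree gain,
  threshold π = 0.6 (the canonical range for the method); stability fits
  use 60 boosting rounds — selection only needs to know which probes the
  trees use. Empty stable set falls back to all probes (logged), which is
  the expected path on null data.
* **Importance.** Total gain (not split count), averaged over fold models
  and repeats, then rescaled to 0–100 with ties broken by probe id;
  hyper/hypo direction from the sign of the group difference in median
  betas, exact ties withheld.
* **Permutations** rerun the procedure at 5 outer repeats each (a
  documented tractability reduction; `perm_repeats` restores any level)
  without re-tuning hyperparameters. Add-one p-value convention, so p is
  never 0.
* **Determinism.** A master seed spawns substreams for splits, subsamples,
  permutations and booster randomness; samples are canonically ordered by
  id first, so outputs are invariant to input sample order.

## Problem sizes in tests and the acceptance script

The full array (~850k probes) is scaled to what the statistics actually
need: 200–2000 probes where only per-probe behaviour matters, 5000–10,000
where genome-wide calibration or p ≫ n selection behaviour is the claim.
ML checks run at reduced repeat/subsample/permutation counts (e.g. 3
repeats, 15 subsamples, 99 permutations) chosen so the whole suite runs in
minutes on one core; the library defaults remain the full protocol.
One statistical subtlety: conditional on a single finite null cohort, the
mean held-out AUC deviates from 0.5 with SD ≈ 0.06 (chance structure in
one draw of 136 samples), and repeated splits of the same cohort are
correlated — so chance-level discrimination is asserted on the average
over four independent null cohorts.

## Known limitations

* The empirical-null EM is a lightweight surrogate for a full Bayesian
  (Gibbs-sampled) mixture fit; it estimates a single global null and does
  not produce posterior null probabilities per probe.
* The loader rejects missing betas (imputation is upstream of this
  pipeline's scope); no IDAT/GEO parsing, no normalisation, no DMR or
  surrogate-variable methods.
* The correlation-validation module provides the mechanism (Pearson/
  Spearman with the p < 0.05, |r| > 0.1 suggestive-relevance rule) but no
  external expression databases; Spearman p-values use the t
  approximation, adequate for the intended n ≥ 50.
* Spiked effects are additive on the beta scale and constant across cell
  types; cell-type-specific effects are not modelled.
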