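# Methods

This note records the statistical model behind protbridge, the design of
the paired-platform simulator, and every numerical convention a user
needs to reproduce results exactly.

## 1. Measurement model and harmonization

Platform A is an aptamer panel reporting raw, strictly positive RFU
values with no missingness; platform B is a proximity-extension (PEA)
panel reporting log2-scale NPX values with left-censoring below a
per-assay limit of detection (LOD). Both are modeled as distorted
readouts of a shared latent protein level.

The harmonization chain (`harmonize.harmonize_pair`) is:

1. **Panel lift** (optional, platform A): per-assay linear transform
   `value' = scale * value + offset` to reconcile panel versions; assays
   absent from the lift table pass through with a warning.
2. **Missingness QC** (platform B): drop assays, then samples, whose
   missing fraction is **strictly greater than** 10% (an assay missing
   exactly 10% is retained); sample missingness is evaluated over the
   retained assays. Samples failing QC are removed from both platforms
   so the matrices stay aligned.
3. **Duplicate resolution** (platform B): one PEA assay per protein —
   the one with the lowest *pre-imputation* missing fraction, ties
   broken by lexicographic assay id. Aptamer duplicates are retained as
   distinct reagent-specific measurements.
4. **Feature-wise KNN imputation** (platform B, k = 10): a hole is
   filled with the unweighted mean of the k nearest *assays* observed at
   that sample. Distance between assays is NaN-aware Euclidean,
   `d(a,b) = sqrt(n_samples / n_shared * Σ_shared (x_a − x_b)²)`; pairs
   with no shared samples are infinitely far; ties break by column
   order; a hole with no usable donor falls back to the assay mean.
5. **log2 + z-score**: platform A is log2-transformed (raw input must be
   positive); each assay is standardized with mean and **n−1 (sample)
   SD** estimated on the *training* subset only and applied everywhere,
   so held-out samples never leak into the scaler. Golden value: raw
   (8, 16, 32) standardizes to (−1, 0, +1).

Panel-overlap coverage percentages are printed with a two-stage
convention: round to one decimal, then to the nearest integer with
Python's ties-to-even (`_pct_int`); e.g. 1737/4973 → 34.9% → 35 and
1737/2871 → 60.5% → 60.

## 2. Cross-platform imputation

For each destination assay, a scikit-learn
`HistGradientBoostingRegressor` (learning rate 0.1, ≤ 300 iterations,
255 bins, early stopping on a 10% validation slice) is fitted on the
training samples using the **entire opposite panel** as features — never
any destination-platform assay. Both directions (A→B, B→A) are
configuration mirror images.

Samples are split 75/25 by a seeded shuffle (`round(0.75·n)` training
rows). Each target model's random state is
`(CRC32(assay_id) XOR global_seed) mod 2^31`, so targets are mutually
independent: adding or removing targets never perturbs the remaining
models, and a single-target rerun reproduces the panel run bit for bit.

## 3. Fidelity metrics and tiers

Per overlapping (aptamer assay, PEA assay) pair and direction:

- `baseline_r`: Pearson r between the two measured, standardized
  platforms on the **training** samples.
- `post_r`: Pearson r between the imputed destination values and the
  measured **source-platform counterpart** on held-out samples. This is
  the quantity a single-platform cohort could actually check.
- `model_r`: Pearson r between imputed and measured destination values
  on held-out samples (defined for every destination assay).
- `gain = post_r − baseline_r`; `magnitude_gain = |post_r| − |baseline_r|`.

Pearson r is NaN when either vector is constant or has n < 2; such
records get tier 0 (undefined) and are excluded from tier statistics.

Tier rules (defaults t_high = 0.7, t_low = 0.1, t_mid = 0.4) use
**signed** correlations and partition [−1, 1]² exhaustively and
exclusively:

- tier 1 if `baseline_r ≥ 0.7` and `post_r ≥ 0.7`;
- else tier 4 if `baseline_r ≤ 0.1` and `post_r ≤ 0.1`;
- else tier 2 if `post_r ≥ 0.4`;
- else tier 3.

Worked examples: (0.21, 0.61) → gain 0.40, tier 2; (−0.4, −0.50) →
tier 4 (the sign-flip signature of an epitope artifact: imputation
cannot repair a reagent that measures the wrong thing). Multi-reagent
proteins roll up to the pair with the highest `post_r`; bidirectional
consensus reports per-tier agreement between the A→B and B→A labels.

### Where gain comes from

`post_r` compares the *imputed destination* against the *measured
source*. Imputing from the whole opposite panel denoises the
destination reading (panel neighbors share the latent signal), but
`post_r` remains capped by the source measurement's own distortion.
Gain in a direction therefore reflects how noisy the destination
platform's single reagent was — which is why the simulator's
recoverable class (below) is asymmetric by construction.

## 4. Paired-platform simulator

`synth_data.SimConfig` defaults define the package's reference study
condition: 2000 samples, 120 proteins in blocks of 10 with
within-block latent correlation 0.6 (block-exchangeable; factor
construction for ρ ≥ 0, Cholesky otherwise), class proportions
faithful/recoverable/ambivalent/irreconcilable = 0.20/0.35/0.25/0.20
(largest-remainder apportionment, permuted assignment).

Per class, the two platforms read the latent x as (noise SDs on the
unit-variance latent scale):

- **faithful**: affine readout + SD 0.3 noise on both platforms.
- **recoverable** (deliberately asymmetric): platform A reads a
  variance-normalized cubic distortion `(x + 0.4x³)/√5.8` + SD 0.35
  noise; platform B reads x + SD 1.4 noise. The pairwise baseline is
  mediocre, but the A panel retains enough information that A→B
  imputation denoises the heavy-noise B reagent: large positive gain.
- **ambivalent**: SD 2.0 noise on both sides — neither platform is
  informative enough for imputation to help much.
- **irreconcilable**, SD 0.3 noise, two subtypes (default 50/50):
  - *off-target*: platform A reads a different protein's latent (drawn
    from another block), so cross-platform r ≈ 0;
  - *epitope*: with carrier frequency 0.3 and effect size e = 3.5,
    platform A reads `x + e·g` and platform B reads `x − e·g` for
    genotype g ∈ {0, 1}. Analytically
    `r = (1 − e²f(1−f)) / (1 + e²f(1−f) + σ²)` ≈ −0.41 — the PILRA-style
    sign flip.

Platform A is written as raw RFU `2^(signal + 10)`; platform B as NPX
with values below each assay's 5% quantile masked (LOD censoring).
Phenotypes: a continuous outcome that is a sparse linear combination of
latent levels (10 causal proteins, effect 0.5) plus age/sex/group
effects and unit noise; survival from an exponential
proportional-hazards model (baseline hazard 0.02, log HR per SD
log 1.5 for one causal protein by default) with independent exponential
censoring calibrated so the expected censored fraction equals
`censoring_rate` (default 0.3). RNG streams are separated by purpose:
`(seed, 1)`/`(seed, 2)` for the platform readouts and `(seed, 3)` for
phenotypes, so changing one component never reshuffles another.

## 5. Downstream analyses

**Penalized continuous model** (`replication.fit_penalized_linear`):
elastic net over proteins with **unpenalized** covariates, solved
exactly by Frisch–Waugh profiling: residualize the outcome and each
protein on [1, covariates], fit the elastic net on residuals, then
recover covariate coefficients by OLS of the protein-adjusted outcome.
(α, l1_ratio) are tuned by 10-fold `ElasticNetCV` over l1 ratios
0.1–1.0 (step 0.1) and 50 alphas; performance is squared Pearson r² on
a 20% hold-out, where per-protein permutation importance (5 repeats) is
also computed.

**PH scan** (`replication.ph_scan`): one lifelines Cox model per
protein (standardized to SD 1, so hazard ratios are per 1 SD),
covariate-adjusted, Breslow tie handling, Wald 95% CIs. Missing
covariates are KNN-imputed (k = 10). Non-converging fits are flagged
and excluded from the Bonferroni denominator.

**Importance and attribution** (`importance`): permutation importance is
the drop in held-out squared-Pearson r² over 5 seeded shuffles of one
feature column (test set only); ranking breaks ties by SD then assay
id. First-K curves retrain on the top-K ranked features taken in the
source panel's column order — so K = all features reproduces the full
model exactly — at K ∈ {1…5, 50, 100, …, 300} by default.

**Cross-cohort agreement** (`replication.compare_importance`): Spearman
rank correlation of mean importance over shared proteins plus top-k
overlap. The package's replication property: restricting to
high-fidelity (faithful/tier-1) proteins yields higher cross-cohort
agreement than using all overlapping proteins.

## 6. Numerical conventions (summary)

- SDs use ddof = 1 everywhere a scaler or z-score is fitted.
- Missingness QC threshold is strict `>`; order: assays, then samples.
- KNN ties break by column order; duplicate resolution ties break by
  lexicographic assay id.
- Pearson r is clipped to [−1, 1] and NaN when undefined; r² is squared
  Pearson (not 1 − SSE/SST) and 0.0 when the correlation is undefined.
- Tier boundaries: ≥ at t_high and t_mid, ≤ at t_low.
- Coverage percentages: round to 1 decimal, then nearest integer with
  ties-to-even.
- Seeds: any 32-bit non-negative integer; per-target seeds are
  `(CRC32(assay_id) XOR seed) mod 2^31`.
- Problem sizes quoted above (2000×120 reference run; 5000/400-sample
  survival studies; 1200-sample two-cohort replication studies) are the
  package's own desk-scale study conditions, chosen so the full
  acceptance suite runs in minutes on one CPU.
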