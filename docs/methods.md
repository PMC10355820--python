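# Methods

## Model overview

The package treats replicative methylation drift as a latent-factor model on
the M-value scale. For CpG *g* and sample *i*,

    M_gi = mu_g + lambda_g * f_{m(g),i} + eps_gi,      beta = 2^M / (2^M + 1)

where `mu_g` is the CpG's baseline (drawn once per study on the logit-beta
scale, beta 0.1–0.9), `lambda_g` is a signed loading (zero for background
CpGs), `m(g)` the CpG's module, `f_m` a per-module latent factor, and `eps`
i.i.d. Gaussian measurement noise. The M-value (base-2 logit of beta) is the
scale on which additive Gaussian latent structure is natural; the logistic
transform guarantees betas in (0, 1).

Module factors encode the study design:

* **physiological modules** — `f_m = s·(c − c̄) + eta_m`, where `c` is cPD in
  the passaging series and age in the tissue series. The drift term is
  centered on the covariate window midpoint so that drift perturbs the CpG
  around its baseline rather than translating it into the saturated tails of
  the logistic, where beta-scale loadings would silently shrink.
* **artifact modules** — in the passaging series only, a factor correlated
  with cPD (default r = 0.8) and scaled to the same amplitude as the drift
  signal: in vitro, artifacts are nearly indistinguishable from replication
  signal, which is precisely the confound the two-dataset consensus must
  break. In the tissue series, artifact CpGs carry no factor at all.

Each physiological module has its own factor (shared drift plus per-module
noise `eta_m`); without `eta_m` the two physiological modules would be
statistically identical and unrecoverable as distinct modules.

## Pipeline

1. **Global PC clock.** PCA of the training betas, centered per CpG, *not*
   variance-scaled, all min(n_samples, n_CpGs) components retained
   (including the degenerate trailing one — with 31 training samples each
   module later contributes exactly 31 components, and the penalized fit
   leaves useless components at zero). An elastic net (mixing alpha = 0.5 by
   default) regresses cPD on component scores; the penalty descends a
   log-spaced 100-point grid from the smallest all-zero lambda and is chosen
   at the minimum mean squared error of a 10-fold cross-validation whose
   fold assignment is fixed by a seed. Predictors are standardized inside
   each training fold; coefficients are reported on the raw score scale.
2. **Driver CpGs.** Per active component, absolute loadings are z-normalized
   across CpGs; a CpG's importance is the sum over components of
   `|coef_k| · sd(score_k) · z_k(g)`. The `sd(score_k)` factor puts each
   component's coefficient on the standardized scale the fit effectively
   saw — raw-scale coefficients of near-degenerate components are inflated
   by their tiny variance and would otherwise dominate the ranking. The
   driver count is a free parameter of the analysis (a practitioner reads it
   off the importance elbow); the packaged study runs use the planted
   structure size.
3. **Consensus network.** Per dataset: biweight midcorrelation (weights
   `(1−u²)²` for `|u| < 1`, `u = (x − median)/(9·MAD)`; Pearson fallback for
   zero-MAD CpGs), unsigned adjacency `|r|^6`, topological overlap
   `ω_ij = (l_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij)`. The second TOM is
   calibrated by a power transform matching its 0.95 off-diagonal quantile to
   the first's, then the consensus is the elementwise minimum. Calibration
   assumes the quantile falls inside comparable structure in both datasets —
   the reason the consensus runs on driver CpGs, where module pairs dominate
   the upper tail; on an unfiltered universe whose second dataset has little
   comethylation, the transform would inflate its noise floor (the
   calibration can be disabled).
4. **Clustering.** Average-linkage hierarchical clustering of 1 − consensus
   TOM, cut at height 0.95; clusters below 50 CpGs are unassigned (label 0);
   labels are ordered by decreasing size and may be displayed with the
   conventional color aliases. The cut is the static height/min-size rule;
   the `deep_split` parameter is accepted and recorded for provenance but
   hybrid dendrogram refinement is intentionally not implemented —
   synthetic fixtures are constructed so that recovery does not hinge on
   it. Module eigengenes are PC1 of the z-scored member CpGs, unit variance,
   sign fixed so mean member kME ≥ 0.
5. **Module selection.** One PC clock per module (same recipe as the global
   clock, restricted to member CpGs). A module is physiological iff its
   held-out score correlates with cPD in vitro *and* with age in vivo at
   r ≥ 0.5. The default threshold is low enough that genuinely shared drift
   passes while culture-only modules — whose in-vivo correlation is
   approximately zero by construction — fail.
6. **Composite.** Per selected module an independent PCA on its own CpGs;
   component scores concatenated (each module contributes min(n, module
   size) components — equal footing regardless of CpG count) and one elastic
   net fitted over the pool. Provenance maps every pooled coefficient back
   to (module, component).
7. **Evaluation designs.** Scores are residualized by OLS on the configured
   covariates (categoricals one-hot with a dropped reference level), then:
   Kruskal–Wallis with tie correction for group designs; Pearson r with
   two-sided t-based p for correlation designs; Cox partial likelihood
   (Efron tie handling, via lifelines) with the score entered per sample SD
   and age per decade for survival designs. Tests are two-sided and
   unadjusted; phase boundaries for trajectory designs come from an explicit
   sheet column, never inferred.

## Default study conditions

| parameter | default | rationale |
|---|---|---|
| n_train / n_val | 31 / 14 | training and validation passaging series sizes |
| cpd_range | 43–75 | the span of a p13–p27 immortalized series |
| n_tissue | 85, ages 23–83 y | the aging-liver consensus partner |
| modules | 2 physio + 2 artifact, 60 CpGs each | smallest design exercising the confound with modules above the 50-CpG cut |
| n_background | 200 | unstructured CpGs; keeps module pairs a minority of all pairs |
| loading_scale | 1.0 logit | full-strength module membership |
| slope / age_slope | 0.04 / 0.02 logit per unit | drift amplitude ≈ 0.37 logit SD over the covariate span, comparable to the 0.2-logit noise floor |
| noise_sd | 0.2 logit | per-CpG measurement noise |
| module_sd_invitro | 0.05 logit | clonal hTERT lines track cPD tightly |
| module_sd_tissue | 0.35 logit | donor-to-donor heterogeneity; this is what makes the two physiological modules separable and excludes artifacts in the consensus |
| artifact_cpd_corr | 0.8 | culture time confound strength in vitro |
| tumor_shift | 8 cPD-equivalents | group offset in the tumor/normal cohort |
| survival_coef | 0.64 | log of a ~1.9 per-SD hazard ratio, the magnitude such survival designs are built to detect |

All randomness in a generator call flows from one integer seed through a
single `numpy` Generator; `simulate_study` derives its four sub-seeds from
one study seed via `SeedSequence`. Identical (config, seed) is bit-identical.

## What the generator does and does not emulate

It emulates: monotone per-CpG drift with replicative history; block
comethylation with signed loadings; culture-artifact structure confounded
with cPD in vitro and absent in vivo; downstream cohorts (group shift,
proportional-hazards survival with independent exponential censoring,
per-tissue division-rate trends) keyed to the same planted loadings.

It does not emulate: probe-type bias, batch effects, cell-composition
heterogeneity, nonlinear age trajectories, missing values, or realistic
correlation between modules' baselines. Passing tests therefore demonstrate
that the pipeline recovers the assumed structure when present — not that the
structure is identifiable in any real dataset.

## Numerical choices

* Beta matrices are validated to [0, 1] with a 1e-9 rounding tolerance and
  rejected (never imputed) on missing values; file round-trips use
  full-precision text (`float_precision="round_trip"` on read).
* Correlation matrices are computed as a Gram matrix divided by
  `sqrt(G_ii·G_jj)` with the product inside the square root, so exactly
  affine profiles give exactly ±1.
* PCA uses thin SVD of the centered samples × CpGs matrix; loadings are
  right singular vectors; the rank-deficient trailing component is kept.
* Elastic-net columns with variance below 1e-12 (degenerate components) are
  excluded from standardization and fixed at zero.
* Cross-validation folds are positional: the fitted model depends on sample
  order only through fold assignment; scoring is exactly permutation
  equivariant.
* Tree cut uses `scipy` average linkage on the condensed 1 − TOM; module
  ties in size are broken by first member index, kME ties lexicographically
  by CpG id, driver ties lexicographically by CpG id.
* Model archives are versioned JSON with arrays at full double precision;
  loading a mismatched schema version is an explicit error.

## Problem sizes in the packaged runs

The shipped study conditions use 440 CpGs (240 structured + 200 background)
and 31/14/85-sample datasets, sizes at which the full pipeline runs in a few
seconds while preserving every structural property the analysis depends on
(module sizes above the clustering cut, n_samples below module size so
component counts are sample-bound, module pairs dominating the calibration
quantile). Statistical calibration checks use 1000 null replicates
(Kruskal–Wallis level) and 200 replicates at n = 500 (Cox coverage and
recovery).

## Known limitations

* The static tree cut will fragment or merge modules in regimes where the
  hybrid dynamic cut is materially better (nested modules, strongly unequal
  densities).
* Single-quantile TOM calibration is only meaningful when both datasets
  carry comparable structure in the calibration tail (see above).
* The driver-importance aggregation (coefficient-weighted sum of normalized
  absolute loadings; `max` available as an alternative) is one of several
  defensible readings of "normalized loading scores"; rankings from other
  aggregations differ mainly in the background tail.
* Elastic-net CV folds are positional, so refitting after reordering samples
  can select a different lambda; all shipped entry points fix sample order
  and seed.
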