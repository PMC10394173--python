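# Methods

This note records the models behind each `tlskit` component, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical decisions a maintainer would want to know.

## TLS signature scoring

The TLS score is the arithmetic mean of log2 expression over the B-lineage
marker genes present in the matrix — the MCPcounter population statistic.
Scores are comparable across samples within one population but not across
populations (no inter-population normalization is attempted; that is a
non-goal). The bundled GMT ships six populations (B lineage, T cells,
myeloid dendritic cells, monocytic lineage, NK cells, neutrophils) with
canonical marker genes; the file is editable and any GMT can be
substituted. Markers absent from a matrix are ignored with a warning; a
population with no present markers is dropped (scoring it would be
meaningless, failing the whole table would be hostile).

Dichotomization labels the top `1 − high_quantile` fraction TLS-high,
with exactly `ceil((1 − q)·n)` high samples and ties broken by sample-id
order so the split is deterministic and permutation-invariant. The default
`high_quantile = 0.75` reproduces a 57/170 split on 227 samples — the
group sizes of the reference TCGA cohort — but the cut-point is exposed
because quartile splitting is a convention, not a law.

## Survival machinery

* **Kaplan–Meier / log-rank** wrap `lifelines`; the median is the first
  observed time with S(t) ≤ 0.5 (NaN when never reached).
* **Cox PH** is implemented in-package: damped Newton–Raphson on the
  partial likelihood with **Efron's** tie correction, iterating until the
  score sup-norm falls below 1e-8 (or 100 iterations). Efron is the
  lower-bias default when tie handling is unspecified. Wald standard
  errors come from the inverse observed information; CIs are
  β ± 1.96·SE on the log scale. Two safeguards matter in screens:
  step-halving stops when the objective change falls below a
  floating-point floor (1e-12·(1+|ℓ|)), and monotone likelihood
  (complete separation) is detected either by a diverging coefficient
  (|β| > 50) or by the signature |β| > 10 with SE > |β|, and reported via
  `converged=False` — never as a silently absurd hazard ratio. The fitter
  agrees with `lifelines` to ~1e-6 (the cross-check lives in the tests)
  and with a brute-force likelihood grid to 1e-4.
* **Covariate encodings**: stage ordinal 1–4, residual disease binary,
  age continuous in years. These are conventions; nothing downstream
  depends on them.
* **BH-FDR** wraps `statsmodels` `multipletests(method="fdr_bh")`.

## Moderated t on CNA

Per gene, a two-group comparison with pooled variance $s_g^2$ on
$d_g = n_1 + n_2 - 2$ df. Hyperparameters follow the standard
empirical-Bayes moment method on log variances: with
$e_g = \log s_g^2 - \psi(d_g/2) + \log(d_g/2)$,

* $\psi'(d_0/2) = \operatorname{Var}(e) - \psi'(d_g/2)$ (Newton inversion
  of the trigamma function),
* $s_0^2 = \exp(\bar e + \psi(d_0/2) - \log(d_0/2))$.

Conventions match `limma`'s `fitFDist`: zero variances are offset to
1e-5 × median before taking logs (shrinkage then guarantees no division
by zero); when the log-variances are underdispersed relative to
chi-square theory, $d_0 = \infty$ and $s_0^2$ is the arithmetic mean
variance; the total df $d_0 + d_g$ is capped at the pooled residual df
(the prior cannot carry more information than the dataset it was
estimated from). The implementation is verified against Bioconductor
`limma` through `Rscript` to 1e-6 on a fixture, and the $d_0 = 0$ /
$d_0 = \infty$ limits are asserted exactly. The test operates on GISTIC
integers or continuous log-ratios alike; gain/loss frequency thresholds
default to ±1 on the integer scale (±0.3 is the suggested log-ratio
setting).

## TICTOC interaction screen

Each gene is fit with covariates {z(TLS), CNA, z(TLS)×CNA} against
overall survival; the TLS score enters continuous and z-scored (a label
mode exists for sensitivity analysis — the continuous form is the more
powerful and matches how the score is defined). Per-gene Wald p-values on
the interaction term are BH-adjusted **once over all successfully fitted
genes** — never per chunk — and constant or non-converging genes are
flagged and excluded from the FDR set. Classification: gains require
HR_int > 1, losses HR_int < 1, both require q < 0.25 and CNA–expression
Pearson r > 0.3 (Spearman available); HR_int exactly 1 belongs to neither
arm. Direction is assigned by the gene's dominant alteration sign in the
cohort. Druggability annotation comes from a static gene → category
table, keeping runs reproducible offline.

**Known limitation — many simultaneous interactions.** When the true
hazard contains many interaction effects at once, each per-gene model
omits all the others. The omitted sum behaves as a random slope on the
TLS term: with $m$ effects of size $\beta$ on CNA with second moment
$E[c^2]$, about $\sigma^2 = m\beta^2 E[c^2]$ of log-hazard variance is
unmodeled. Two measurable consequences, both reproduced by the package's
own simulations: true interaction coefficients attenuate (to ≈0.45× at
$\sigma^2 \approx 4$), and null Wald statistics overdisperse, inflating
the realized FDR of the q < 0.25 call set well above its nominal level.
The detectable z-statistic has a ceiling of
$\beta\sqrt{D/(1/E[c^2] + m\beta^2)}$ (D = events), which no choice of
planted CNA profile escapes. With few simultaneous effects (m ≤ 5) the
screen recovers planted interactions with sensitivity 1.0 and clean
calibration, so sparse-truth settings — the regime a real cohort is
believed to occupy — are handled well; dense-truth settings are reported
as measured, not corrected (no genomic-control rescaling is applied, to
keep the recorded statistics the plain per-gene Wald quantities).

## Synthetic-data generator

The generator is the package's study design; its defaults are the
conditions under which everything is validated.

* **Expression**: per-gene baseline means N(6, 1.5²) on the log2 scale,
  unit-variance noise. Marker genes additionally carry a per-sample TLS
  abundance $\delta \cdot \mathbb{1}[\text{high}] + \mathcal N(0, 1)$
  shared across markers ($\delta$ = `marker_effect`, default 2.0;
  heterogeneity SD `marker_sample_sd`, default 1.0). The shared factor
  makes the signature score continuous — as real TLS content is — rather
  than an implausibly clean bimodal mixture; group means still differ by
  exactly δ.
* **CNA**: GISTIC integers {−2…2} with background frequencies
  (2, 13, 70, 13, 2)%. The planted deletion locus takes −1 with
  probability 0.8 (TLS-low) vs 0.1 (TLS-high). Interaction genes carry
  background profiles. No linkage or segment structure is simulated
  (declared non-goal); each gene is independent.
* **Survival**: exponential baseline (default 0.02 events/month) with
  log-hazard $\beta_{TLS} z + \sum_g (\beta_c c_g + \beta_{int} z c_g)$;
  $\beta_{TLS}$ defaults to ln 0.55, the protective effect size reported
  for real cohorts. Censoring is uniform administrative, with the upper
  limit bisected so the realized censored fraction matches the request
  (±0.05 guaranteed; the calibration is deterministic given the seed).
  Exponential + uniform censoring is the simplest mechanism that is
  exactly proportional-hazards.
* **CT phantoms**: an ellipsoidal tumor (semi-axes 40% of each extent) in
  a homogeneous background, interior = mean HU + a Gaussian random field
  (white noise smoothed with a Gaussian kernel whose sigma in mm is the
  correlation length, rescaled to the requested SD — so `texture_sd = 0`
  gives an exactly constant interior). TLS-high and TLS-low phantoms
  differ in correlation length (1 vs 4 mm at 60 HU), which separates
  their GLCM entropies cleanly. Default 24×24×12 voxels at 1×1×3 mm so
  resampling is the identity and a 300-phantom experiment runs in
  seconds. The phantoms emulate *texture statistics*, not anatomy,
  scanner physics or reconstruction kernels — a model that passes here
  demonstrates the pipeline's statistical machinery, not clinical
  transferability.
* Every generator is a pure function of (config, seed); truth records
  carry all planted gene ids and betas so screens can be scored without
  re-deriving the simulation.

## Radiomics

* Resampling to 1×1×3 mm: trilinear for intensities, nearest-neighbor
  for the mask; output dims = round(dim·old/target).
* Quantization: fixed 25-HU bins anchored at the in-mask minimum
  (min-anchoring is the common radiomics convention and makes the level
  map invariant to global HU shifts); levels 1..Ng.
* GLCM: counts accumulated over the 13 unique 3D offsets at distance 1,
  symmetrized, normalized once (per-direction averaging is available by
  config). All entropies use log2; `0·log 0 ≡ 0`; the information measure
  of correlation 1 is defined 0 when max(HX, HY) = 0.
* Wavelets: single-level undecimated separable 3D transform, Coiflet-1
  default, subbands named by the filter applied along x, y, z. Undecimated
  means subbands keep the input shape, so the original mask applies
  unchanged; odd dimensions are symmetrically padded and cropped back.
  The reference texture software's exact filter, aggregation and anchor
  are not public, so the three published model coefficients cannot be
  expected to transfer bit-exactly to this extractor; the published model
  constant is therefore shipped for *scoring semantics* (unit responses,
  ranking, aggregation), and new cohorts should train their own model.
* Shape: surface from marching cubes on the padded mask with spacing
  applied; sphericity $\pi^{1/3}(6V)^{2/3}/A$; max 3D diameter from the
  convex hull of mask voxel coordinates.

## Radiomic TLS score

Standardization factors (mean, SD per feature) are computed on the
training cohort only and frozen; test cohorts are transformed with the
training factors (asserted by checksum in the tests). Features with
|Spearman ρ| ≤ threshold against the TLS signature are dropped (0.1
ovarian preset, 0.3 lung preset with 3-fold CV). The LASSO minimizes
$(1/2n)\lVert y - Xw - b\rVert^2 + \lambda\lVert w\rVert_1$ over 100
log-spaced penalties from $\lambda_{max} = \max_j |X_j^T(y-\bar y)|/n$
down to $10^{-4}\lambda_{max}$, with seeded K-fold assignment; λ* is the
minimal mean held-out MSE and the final model is refit on all rows at λ*.
CV-curve fits run at tolerance 1e-6 (they only rank penalties); the final
refit uses 1e-10, which the closed-form oracles (soft-thresholding on
orthonormal designs, the λ = 0 least-squares limit) hold to 1e-8. An
intercept is fitted during training, but the published constant carries
b = 0: the score is used for ranking and dichotomization, which an
intercept cannot affect. Bilateral cases take the maximum over masses.
The survival report dichotomizes at the median by default (configurable —
no principled cut-point exists for a new score).

## Pipeline and I/O

All randomness flows from one top-level seed recorded in the manifest;
reruns are byte-identical. Matrices travel as TSV (genes × samples, first
column the gene id), clinical tables as CSV keyed by `sample_id`, volumes
as NIfTI pairs with spacing from the header. Duplicate ids are hard
errors naming the offenders. Cohort-table percentages are rounded half-up
to one decimal with unknown categories kept in the denominator, matching
how clinical tables are printed. Stage failures abort with the stage
name. CLI exit codes: 0 success, 2 config error, 3 stage failure.

## Problem sizes used in validation

The validation suite runs the moderated-t calibration at 2000 genes ×
(10 vs 10) over 100 replicates, the interaction screen at 500 genes ×
400 samples (60% events, 20 planted ln 2 interactions — the dense-truth
regime discussed above, reported as measured), Cox effect recovery at
n = 2000, and the radiomics end-to-end at 150 phantoms per class with a
100-case held-out evaluation. These sizes make every oracle comparison
exact while keeping a full run around a minute on one CPU.
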