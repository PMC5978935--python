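# Methods

This note documents the models implemented in `ddrmeth`, the synthetic
study the package validates itself on, the defaults and why they were
chosen, and the numerical decisions that matter. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The scientific setting

IDH-mutant low-grade gliomas carry the glioma CpG-island methylator
phenotype (G-CIMP): genome-wide promoter hypermethylation that can silence
DNA-damage-response (DDR) genes such as *MGMT*. Because patients in a
randomized trial receive either radiotherapy or the alkylating agent
temozolomide, silencing of specific repair genes can translate into
*predictive* markers — covariates whose effect on progression-free survival
(PFS) differs by treatment arm. The package implements the full chain
needed to look for such markers on HM-450K-style array data: probe
filtering and batch adjustment, probe-state classification in normal
brain, functional-methylation selection against expression, molecular
subtyping (CIMP, 1p/19q codeletion), methylation scoring and tumor-purity
control, cross-dataset concordance, differential analysis, and Cox
interaction screening.

## Synthetic study generator

The generator (`simulate_study`) emits a study with the structure these
analyses assume. Its defaults ARE the study conditions used throughout the
tests; they are set once and documented here.

**Design.** Four datasets (named after the cohorts such a study would
use: a trial cohort and three external sets) of 60 tumor samples each,
plus 5 normal-brain (NTB) samples — desk-scale stand-ins for cohorts of
one-to-two hundred patients, sized so the full pipeline runs in about a
minute. Subtype mix 20% IDH-wild-type, 40% IDH-mutant non-codeleted, 40%
IDH-mutant codeleted.

**Annotation.** 120 genes with 1–4 promoter CpGs each (even offsets within
±1500 nt of the TSS), distal "other" probes, 300 intergenic probes placed
mid-gap (> 1500 nt from every TSS by construction), chromosome-X probes and
a 2% SNP-flagged subset for the filters; half the genes carry the DDR flag
and 20 DDR genes are designated *functional*.

**Methylation.** Each probe has a trimodal normal-brain state
(unmethylated/hemi/methylated) with M-scale means (−4, 0, 4), state SDs
0.5 and weights (0.50, 0.15, 0.35). Tumor cells add, on the M scale,
a CIMP shift (+2) to normally-unmethylated promoters of IDH-mutant
samples, an extra codeletion shift (+1) creating the subtype gradient, and
a +1.5 drift at unmethylated intergenic sites of all tumor cells — the
signal that makes purity readable from intergenic probes. The magnitudes of
these shifts are the package's own calibration, chosen once so that
downstream recovery is testable at desk scale. Measurement noise: SD 0.3
(tumor) / 0.1 (normal) on M.

**Purity and mixing.** Purity is Beta(5, 2) (mean ≈ 0.71), with a +2
concentration bonus for codeleted samples (they present as purer tumors).
Observed betas are the convex mixture
`β_obs = purity·β_tumor + (1−purity)·β_normal` computed on the beta scale —
fractions of cells mix physically in β, not in M. Batch location/scale
effects (shift SD 0.3, log-scale SD 0.05, two batches per dataset) are
applied on the M scale of both mixture components *before* mixing, matching
where ComBat operates and keeping the mixture identity bit-exact.

**Intensities.** Total intensity ≈ 5000 with log-normal spread; the
channel pair satisfies `β = Meth/(Meth+Unmeth+offset)` exactly (offset
100), with Unmeth floored at 1 and Meth recomputed from the identity for
near-saturated betas. Codeleted samples lose intensity on 1p/19q probes in
proportion to purity (per-copy factor 0.5).

**Expression.** Functional genes follow
`expr = intercept + slope·(mean promoter M) + N(0, 0.5)` with slope −2;
other genes are independent of methylation.

**Survival.** Exponential PFS in months with log hazard
`log(0.015) + β₁·TMZ + β₂·score + β₃·TMZ·score` and independent exponential
censoring (rate 0.01/month). The defaults β₁ = −0.0797, β₂ = 0.0502,
β₃ = −0.2851 are the coefficients of the reference multivariable PFS model
this package is designed to reproduce; the baseline rate gives a median PFS
near 46 months. Arms are assigned 1:1 at random.

**Seeding.** One master seed; each stage (annotation, methylation,
expression, survival) derives a child seed via `SeedSequence([seed, k])`,
so stages regenerate independently and identical configs are byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not establish about real arrays: Infinium I/II chemistry and dye bias,
FFPE degradation, detection-p structure beyond random failures, spatial
correlation of neighboring CpGs, copy-number effects on beta values,
non-exponential hazards, and informative censoring.

## Models and estimators

**Beta/M transforms.** `M = log2(β/(1−β))` with β clipped to
[1e−6, 1−1e−6]; 450K betas never reach 0/1 in practice, so the clip only
guards degenerate input. The transforms are exact inverses on the clipped
range.

**Probe filtering.** A probe is dropped when detection p > 0.01 in *any*
sample (strictest reading; a max-failing-fraction knob relaxes it), or when
it is on a sex chromosome or SNP-flagged. The removal log lists a probe
under every reason it fails while the retained-set arithmetic counts it
once.

**ComBat.** Parametric empirical-Bayes location/scale adjustment:
standardise per probe against the batch-size-weighted grand mean and pooled
variance, estimate per-batch location γ and scale δ², shrink via a normal
prior on γ and an inverse-gamma prior on δ² (moment-matched), iterate the
conditional posteriors, remove and back-transform. Singleton batches are
an error; constant probes pass through with a warning. The implementation
reproduces `sva::ComBat` (parametric) to ~1e-15 on a fixed test matrix; the
frozen reference values live in the test suite. The pipeline adjusts for
experimental batches first, then for dataset, mirroring the two sources of
unwanted variation.

**NTB mixture.** The per-probe normal-brain summary is the *median* M
across NTB samples — robust at n = 5, where a mean would chase single
outliers. EM on a univariate 3-component mixture, best of 5 k-means-seeded
starts, tolerance 1e−8 on the log-likelihood (whose trace is checked to be
non-decreasing); runs with component collapse (sd < 1e−4 or empty
responsibilities) are discarded and restarted, and every restart failing is
an error. Components are reported in ascending-mean order (lowest = U) and
probes take their maximum-posterior state. Poorly separated or near-empty
components trigger a warning rather than an error, since one-mode inputs
are legitimate degenerate cases.

**Functional selection.** Within each dataset, Pearson correlation between
probe M and gene expression over shared samples, two-sided t test of zero
correlation, BH-FDR computed *per dataset* over the testable candidates
only (candidates whose gene is missing from an expression set are excluded
from that denominator). Thresholds r ≤ −0.3 and q ≤ 0.1 are boundary
inclusive. Correlations are computed on per-dataset matrices without
cross-dataset batch adjustment: a within-dataset correlation does not need
it.

**CIMP clustering.** Ward linkage on Euclidean distances, k = 2 by
default, the higher-methylation cluster labeled CIMP+.

**CBS.** For a position-ordered log2 ratio vector, the best circular arc
(i, j] maximises a pooled-variance two-sample t statistic between inside
and outside (computed from prefix sums, O(n²) per segment); the split is
accepted when its within-segment permutation p ≤ 0.01 (with early
termination once the count rules out significance) and recursion continues
in the pieces. The original algorithm's pruning/undo heuristics are
omitted — a deliberate simplification acceptable at desk scale.
Segment means always reconstruct the global mean exactly. Arm calls use
the probe-length-weighted mean segment ratio against a −0.2 log2 threshold
(no published threshold exists; this was fixed once against generator
defaults), and codeletion requires both 1p and 19q lost.

**MGMT score.** `prob = expit(intercept + c₁·M₁ + c₂·M₂)`,
`score = logit(prob)`, status *methylated* iff prob > 0.358 (strict: the
published cutoff's tie direction is unstated, so the boundary probability
stays unmethylated). The published coefficients are not hardcoded — they
appear only in the classifier's original reports — so the model ships as a
YAML slot and `fit_mgmt_model` calibrates one by maximum likelihood, with
an L2-penalised fallback under separation.

**Sparse PLS purity.** Response `y = arcsin(√purity)` (variance
stabilising for proportions). PLS1-NIPALS: each component's weight vector
is the unit-norm covariance direction Xᵀy of the deflated predictors,
soft-thresholded at fraction η of its largest absolute weight and
re-normalised; η = 0 reproduces dense PLS1 (checked against scikit-learn to
1e−8). Defaults K = 3, η = 0.4; `cv_spls` offers 5-fold MSE selection over
K ∈ {1..5}, η ∈ {0, 0.2, …, 0.8}. Predictions are back-transformed by sin²
after clipping the linear prediction to [0, π/2], so the HMP index always
lies in [0, 1]. The exact sparse-PLS variant in the literature is
ambiguous; the soft-thresholding (lasso-penalised direction) formulation
was chosen and is stated here. Predictors are intergenic probes with
across-sample median β strictly below 0.2.

**Moderated t.** Two-group linear model per feature; hyperparameters
(d₀, s₀²) by the method of moments on log sample variances (digamma/
trigamma relations, trigamma inverted by Newton); posterior variance
`(d₀s₀² + d·s²)/(d₀ + d)`; t with d + d₀ degrees of freedom (normal when
d₀ = ∞). `prior_df=0` disables moderation exactly. Zero-variance features
with equal means get p = 1 by convention. DMP gates are boundary inclusive
(|Δβ| ≥ 0.1, q ≤ 0.1, with Δβ the difference of group-mean *betas* while
the test runs on M). The four-dataset intersection requires a consistent
effect sign by default — an intersection without it could join opposite
effects — and can be switched off.

**STATIS.** Tables share columns (probes), not rows, so the analysis runs
on column-configuration operators W = XᵀX after column-centering, each
normalised to unit Hilbert–Schmidt norm (standard inertia normalisation;
each table contributes equally). RV coefficients are cosines between
operators; the first eigenvector of the RV matrix (nonnegative by
Perron–Frobenius) gives table weights; the weighted operator average is
eigendecomposed into the compromise, with tiny negative eigenvalues clipped.
The permutation null permutes each table's column order independently,
breaking cross-table correspondence while preserving within-table
structure; on the operators this is a simultaneous row/column permutation,
so operators are built once. p = (1 + #{λ₁* ≥ λ₁})/(1 + B), bounded below
by 1/(B+1). The scheme's calibration is verified under an iid-noise null
(Kolmogorov–Smirnov uniformity over 200 runs).

**Survival.** Cox fits are delegated to lifelines (Efron ties — the better
default when ties exist; the generator's continuous times have none) with
Newton precision tightened to 1e−9 so toy fits agree with brute-force
partial-likelihood maximisation to ~1e−9. LRT = 2(ll_full − ll_null) with
the parameter-count difference as df. The interaction screen fits
`time ~ cpg + arm + cpg:arm (+ codel)` per CpG, reports Wald and LRT
statistics and applies BH-FDR across CpGs to the LRT p values (raw-p
selection remains available via the returned table). The expected-survival
surface uses the Breslow baseline as a right-continuous step function
(S = 1 before the first event), powered by each grid point's partial
hazard; time grids beyond follow-up are clamped with a warning. Events are
modeled from surgery without delayed entry — left truncation is out of
scope.

## Pipeline

`run_pipeline` executes simulate → preprocess → select → mgmt → purity →
STATIS → differential → CNV → survival, in canonical order with explicit
dependency checking, writing TSV/JSON per stage plus a manifest of
thresholds, per-stage counts and SHA-256 hashes of every file. All
randomness flows from the single pipeline seed through stage-specific child
seeds, making reruns byte-identical. Default thresholds: promoter window
±1500 nt, r ≤ −0.3, FDR 0.1, |Δβ| ≥ 0.1, |log2FC| ≥ log2 1.2, MGMT cutoff
0.358, purity predictor median β < 0.2, 999 STATIS permutations, CBS
α = 0.01 with 200 permutations, arm-loss threshold −0.2.

Problem sizes in the acceptance checks (3000-probe mixtures, 5000-probe
null matrices, n = 2000 survival cohorts with 100 replicates, 20
functional-selection replicates at n = 100 per dataset) are the package's
chosen desk-scale study conditions: large enough for the statistical
properties to be sharp, small enough that the whole validation runs in
about a minute.

## Known limitations

* No raw-intensity normalisation (NOOb/dye/funnorm/RUV-2); inputs are
  assumed normalised betas.
* CBS without pruning/undo; long chromosomes with many change points will
  over-segment relative to the reference implementation.
* The NTB reference is small (n = 5 by design); mixture states inherit its
  sampling noise, mitigated by the median summary.
* Expression modeling is homoskedastic log-scale; count-based
  precision-weighting (voom-style) is out of scope.
* Cox models assume proportional hazards; no diagnostics beyond the
  residual hooks lifelines provides.
* The moderated-t intersection treats datasets as independent; shared
  samples between tables would invalidate the four-way intersection logic.
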