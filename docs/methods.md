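# Methods

`methwas` implements a tissue-specific methylome-wide association (MWAS)
workflow: cis-genetic prediction models for CpG methylation are trained in
a reference panel, applied to cancer GWAS summary statistics, and the
resulting CpG–cancer associations are colocalized, conditioned on known
GWAS signals, linked to target genes by eQTM scans, and assembled into
direction-consistent CpG–gene–cancer trios. A synthetic-data generator
provides inputs with the statistical structure the analysis assumes,
together with the ground truth needed to validate every stage.

## The association statistic

For CpG *m* with prediction-model weights *W*<sub>S−m</sub> over its cis
variants, the association with a trait summarised by per-variant effects
β̂<sub>S</sub> and standard errors se(β̂<sub>S</sub>) is

Z_m = Σ_{S ∈ Model_m} W_{S−m} · (σ̂_S / σ̂_m) · β̂_S / se(β̂_S)

where σ̂<sub>S</sub> is the reference-panel dosage standard deviation of
variant *S* and σ̂<sub>m</sub> the standard deviation of the
model-predicted methylation over reference samples. σ̂<sub>m</sub> is
computed from the predicted values *X·W* directly, so correlation between
model variants (LD) is captured; the alternative Σ W²σ̂² ignores LD and is
miscalibrated whenever a model holds more than one variant per LD block.
The weighted-sum construction assumes the GWAS per-variant errors are
themselves LD-correlated (they are, when estimated in one cohort); the
synthetic GWAS generator reproduces this by drawing its noise with the
panel's LD correlation, and the null distribution of Z_m then has unit
variance (measured 1.08 over 90 null CpGs).

Effects are reported as odds ratios per standard deviation of genetically
predicted methylation, `exp(γ̂·σ̂_m)` with
γ̂ = Σ W·(σ̂_S²/σ̂_m²)·β̂_S, and the CI uses se(lnOR) = |lnOR/Z| so the
interval is exactly consistent with the association Z. This reproduces
published CI bounds from (OR, Z) pairs to the printed 2-decimal rounding.

Significance is gated per cancer at Bonferroni-corrected two-sided
P < 0.05 (threshold 0.05 / number of models, strict inequality).

## Prediction models

Methylation beta values are inverse-normalized per CpG (Blom offset 3/8,
average ranks for ties) and residualized on covariates (genetic PCs,
PCA-based hidden factors standing in for PEER, sex, platform and library
indicators). Three model families share deterministic, seed-derived folds
so comparisons are paired:

* **Single-tissue elastic net** (α = 0.50, mixing L1/L2 on the
  mean-squared loss) over a 100-point λ path from λ_max down by 10⁻³,
  fit with scikit-learn's coordinate descent.
* **Cross-tissue sparse-group fit**: minimize
  Σ_t (1/2n_t)‖y_t − X_t β_t‖² + λ₁ Σ_j ‖β_j·‖₂ + λ₂ Σ_{j,t} |β_{jt}|,
  grouping each variant across tissues, solved by block coordinate
  descent (numba-compiled) with the penalty pair tuned on a 5×5 grid.
  The objective is validated by its own KKT subgradient oracle, not by
  equivalence to any external tool.
* **Best single cis-mQTL** baseline: per training fold, the variant with
  the smallest marginal p, with its fold-fitted slope.

Dosages are never standardized, so stored weights are on the dosage scale
that the association statistic's σ̂<sub>S</sub>/σ̂<sub>m</sub> scaling
expects. The cis window is ±500 kb around the CpG, 1-based inclusive.

### Cross-validated performance and the reliability gate

A model is *reliable* when cv_R > 0.10 and cv_P < 0.05. Both numbers
come from one *prequential* (forward-validation) measurement: fold
*f* ≥ 1 is predicted by a model trained — its λ path built and tuned by
internal CV — only on folds before *f*; cv_R is the Fisher-weighted
average of the per-fold correlations and cv_P their combined Fisher-z
test. Because no fold's responses ever enter the training or tuning of
the model later tested on them, the fold z-scores are exactly
uncorrelated under the null and the combined statistic is standard
normal; and because both gates apply to the same measurement, their
conjunction behaves coherently. The stored weights still come from the
conventional full 5-fold choice of λ (minimum pooled out-of-fold MSE)
refit on all data.

The naive alternative (a correlation test on the pooled out-of-fold
predictions at the CV-chosen λ) is badly anti-conservative: selection of
λ on the same predictions, fold-mean leakage from near-constant fold
models, and the sharing of training responses across folds inflate the
null rejection rate at the 0.05 level to ≈0.16–0.47 in our measurements.
Two subtler leaks matter as well and are avoided: the λ grid must be
anchored at the training prefix's λ_max (a full-data grid conditions on
the held-out responses and biases out-of-sample correlations), and
prediction/response vectors must be compared within folds. With the
prequential design the measured null cv_P < 0.05 rate is 0.05; the null
reliable-model rate is necessarily at most half of that (the gate also
demands positive R under a two-sided test), ≈0.02. At h² = 0.4, k = 3
causal variants and n = 400, mean cv_R is ≈0.61 against the √h² = 0.632
ceiling.

Model selection keeps, per CpG and tissue, the reliable elastic-net or
cross-tissue model with the higher cv_R; the best-mQTL model is used only
for method comparison (two-sided paired t-test on cv_R).

## Colocalization

Per-variant Wakefield log approximate Bayes factors,
log ABF = ½[log(1−r) + r·z²] with r = W/(V+W), feed a single-causal-
variant colocalization over the cis region: hypothesis weights for H0–H4
are log-sum-exp accumulations over single variants (H1, H2, H4) and
off-diagonal variant pairs (H3), with priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵
and prior effect variances 0.15² (quantitative trait) and 0.2²
(case-control) — the customary defaults, as none are stated for the
original analysis; all are exposed as CLI flags. PP.H4 > 0.80 is a high
and > 0.50 a moderate probability of colocalization (strict). The
CpG-side inputs are marginal cis-mQTL statistics recomputed from the
reference panel; model weights are deliberately not reused. Posterior
ratios among trait-associated hypotheses are invariant to rescaling one
trait's Bayes factors; the full posterior vector is not (H0/H2 do not
scale), which the tests assert in that corrected form.

## Conditional analysis

Independent GWAS signals at a locus are selected by forward stepwise
search at P < 5×10⁻⁸ on the z-score/LD scale (candidates with r² > 0.9
to a selected variant are skipped), and target variants are re-tested
conditionally via

z_t|S = (z_t − R_tS R_SS⁻¹ z_S) / √(1 − R_tS R_SS⁻¹ R_St)

with β reconstructed through the marginal standard errors and a 10⁻⁶
ridge on the selected-set LD. Variants whose sample size differs by more
than 20% from the locus median are dropped first. With LD measured in the
same cohort the conditional z equals the z of an individual-level
regression that includes the selected genotypes as covariates
(correlation >0.999, slope ≈0.99 in the oracle runs); with a small
external reference panel, LD sampling noise alone degrades that
agreement — a known practical limitation of all summary-statistic
conditional analysis, not of the decomposition. The association is then
re-evaluated with conditional β/se in place of marginal ones, against the
unchanged Bonferroni threshold. CpGs more than 1 Mb (strict) from every
known GWAS hit on their chromosome are classed putative novel.

## eQTM scan and trio assembly

Genes are retained when reads ≥ 6 *and* TPM > 0.10 in at least 20% of
samples (the "how many samples" rule is unstated upstream; 20% is the
adopted convention, exposed as a flag). Expression and methylation are
quantile-normalized between samples and inverse-normalized per feature;
each cis pair (gene TSS within ±500 kb of the CpG) is an OLS of
expression on methylation adjusting for methylation and expression hidden
factors (defaults 5 + 5, clipped to n_features/10 on small matrices,
where factors approaching the feature count would absorb the signal
itself), with BH-FDR per tissue at q < 0.05.

Gene-cancer evidence combines a predicted-expression association channel
and an external differential-expression table; the direction is the
significant channel's sign, 0 with a conflict flag when both are
significant and discordant. Essential genes have median CERES < −0.50
(strict); expression models qualify at R² > 0.01 and P < 0.05, keeping
the larger-R² model per gene. A trio (CpG, gene, cancer) is *consistent*
when all three edges are individually significant and
sign(CpG–cancer) = sign(CpG–gene) × sign(gene–cancer). Differential
methylation between tumor and normal samples uses a fixed-effect status
term with covariates — the literal "status as a random effect" is not
estimable for a two-level factor of interest, so the fixed-effect form is
normative here — and validates a CpG when its P < 0.05 and the effect
sign matches the association Z.

## Synthetic data

Genotypes: latent Gaussian AR(1) blocks (corr ρ^|i−j|, default ρ = 0.9)
thresholded at Hardy-Weinberg genotype frequencies for effect-allele
frequencies drawn from (0.05, 0.5]; positions 1-based, strictly
increasing, blocks 2 Mb apart so a ±500 kb cis window never spans blocks;
10% of allele pairs palindromic so harmonization paths are exercised.
Methylation: per tissue, latent = causal dosage effects + covariates +
noise with the cis fraction of variance fixed at h² (default 0.4, k = 3
causal variants, half the effects shared across tissues); beta values are
the inverse-logit around a per-CpG baseline. GWAS: marginal log-odds
effects are the LD-propagated projections of the scenario's direct
liability effects, se = 1/√(2Np(1−p)) at N = 50,000 by default, with
LD-correlated noise. Expression: linked genes follow γ·(standardized CpG
latent) with γ = 0.75 (correlation 0.6) plus three shared nuisance
factors that the hidden-factor correction is meant to absorb; linked
genes always pass the expression filter so ground truth stays testable.
Scenarios: `shared_causal` (one variant drives methylation and disease),
`ld_distinct` (distinct variants at |r| ≥ 0.7), `null` (no disease
effects; the truth ledger's mediation entries are exactly 0), and
`mediated_trio` (variant → CpG → gene → disease). One scenario seed
expands into fixed per-component child streams, so outputs are
byte-identical across runs. An individual-level cohort drawn from the
same genotype model (with per-variant OLS summary statistics and, for
trio evidence, cohort expression) is the oracle surface for the
summary-statistic methods.

What the generator does *not* emulate: realistic genome annotation,
allele-frequency spectra below 5%, population structure and relatedness,
binary case-control sampling (the liability is continuous; the analytic
GWAS is labeled log-odds by convention), probe-level measurement error,
and trans effects. Passing tests therefore show correctness of the
statistical machinery under the stated generative model, not robustness
to those real-data complications.

## Problem sizes and numerical choices

The evaluation routines run at desk scale: 100 CpGs × 20,000 individuals
for the association oracle, 500 null CpGs for calibration, 50 replicates
for coloc scenarios, eQTM power and trio recovery — sizes chosen so the
whole evaluation completes in minutes while keeping Monte-Carlo error
well inside the asserted margins. Missing dosages are mean-imputed after
QC. Degenerate inputs are handled explicitly: constant vectors return
zeros from the inverse-normal transform (with a warning), constant
out-of-fold predictions give (R, P) = (0, 1), Z = 0 flags an undefined
CI, and a monomorphic HWE table returns p = 1. Ties: average ranks in
rank transforms; expression-model R² ties break by a declared method
order; best-mQTL fold-selection ties break by smallest full-data p.
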