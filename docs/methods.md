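# Methods

## Setting and assumptions

The package implements two-sample summary-statistic Mendelian
randomization: per-SNP effects on a continuous exposure (SD units per
allele) and on a binary outcome (log-odds per allele) are estimated in
two non-overlapping cohorts of the same superpopulation, and the causal
effect of the exposure on the outcome is identified under the usual
instrumental-variable assumptions (relevance, exchangeability, exclusion
restriction). All pooled estimates are reported on the
log-odds-per-1-SD-exposure scale and as odds ratios exp(β) with
exp-transformed 95% CIs; odds-ratio CIs are exact transforms of the beta
CIs by construction.

## Harmonization

Outcome records are aligned to the exposure effect alleles: swapped
allele pairs flip the outcome beta sign and replace EAF by 1−EAF; strand
complements are resolved the same way. Palindromic SNPs (A/T, C/G)
cannot be oriented from alleles; those with EAF within a window of 0.5
(default 0.08) in either study are dropped, the remainder are oriented by
which side of 0.5 the EAF falls on. Any other allele configuration is
dropped with a warning. Harmonization is idempotent and invariant to the
outcome file's allele reference. LD matrices carry *signed* r referenced
to the exposure effect alleles; squaring happens only inside clumping.
Indefinite LD estimates (possible from small reference panels) are
repaired by the minimal ridge (|λ_min|+1e-8)·I followed by rescaling to
unit diagonal, with a logged warning.

## Instrument selection and strength

Selection is a P-value filter (defaults: 5e-8 for a primary cis set,
5e-5 for a liberal secondary set) followed by greedy clumping: candidates
sorted by ascending P (ties broken lexicographically by rsID, so the
result is invariant to row order), the best kept, and all remaining
candidates with r² ≥ threshold against it removed, repeated to
exhaustion. No genomic-window constraint is applied — the LD matrix
alone decides. Strength is the first-stage F = (β/SE)² and the variance
explained 2p(1−p)β² per SNP; the set-level total is reported both as a
plain sum and as the LD-adjusted quadratic form βᵀD R⁻ D β
(D = diag(√(2p(1−p))), R⁻ a pseudo-inverse), because plain summation
over correlated SNPs double-counts.

## Estimators

* **Wald ratio** β̂_Y/β̂_X with first-order delta SE σ_Y/|β̂_X| by
  default; the second-order form √(σ_Y²/β_X² + β_Y²σ_X²/β_X⁴) is
  available by flag. First order is the default because it makes
  single-SNP IVW and the GLS pooling coincide exactly.
* **Correlated-instrument IVW**: GLS of β̂_Y on β̂_X through the origin
  with covariance Ω_ij = σ_Yi σ_Yj ρ_ij, solved by Cholesky
  factorization; a singular Ω raises an error carrying the condition
  number. Computed on the beta scale (equivalent to pooling Wald ratios
  with their correlation, but numerically stabler). With identity LD it
  equals classic fixed-effect IVW to floating-point accuracy.
* **Independent IVW** with weights 1/σ_Y²; the multiplicative
  random-effects variant inflates the SE by max(1, √(Q/(K−1))).
* **MR-Egger**: weighted regression of β̂_Y on β̂_X with intercept,
  weights 1/σ_Y², after orienting every instrument to β̂_X > 0 (the fit
  is invariant to joint sign flips). Inference uses the estimated
  multiplicative residual scale with a t(K−2) reference — the convention
  of the standard implementations — rather than a fixed-scale normal
  test, because with balanced pleiotropy present the fixed-scale test is
  anticonservative; the estimated-scale t test keeps the intercept's
  type-I error at its nominal level (verified by simulation in the
  acceptance suite). All other estimators use two-sided normal
  (chi-square for Q) P-values.
* **Cochran's Q / I²**: Q = Σ(β̂_Yi − β̂ β̂_Xi)²/σ_Yi² with K−1 df,
  I² = max(0, (Q−df)/Q). Under the null with exactly known σ_Y and no
  exposure-side noise, Q is exactly chi-square(K−1), which the test
  suite checks distributionally.
* **Leave-one-out** re-runs the matching IVW (correlated when the LD
  submatrix is not the identity) with each SNP omitted.
* **RAPS**: β̂ maximizes the profile log-likelihood
  −½ Σ (β̂_Yi − β β̂_Xi)²/(σ_Yi² + β²σ_Xi² + τ²) with τ² = 0 by default;
  with overdispersion, (β, τ²) are estimated jointly and the Gaussian
  log-variance term is included (without it τ² is unidentified — the
  objective is maximized as τ² → ∞). LD is ignored and the simple
  quadratic loss is used; robust (Tukey/Huber) losses are out of scope.
  The SE comes from the observed information at the optimum (central
  second differences); the optimizer is a bounded scalar (or Nelder-Mead
  joint) search started at the IVW estimate, and the acceptance suite
  checks it against a dense grid.

## Power

For a two-sided α-level Wald test against log-OR b, with SE(β̂)
approximated from the outcome GWAS size N and instrument r² as
SE = 1/√(N·r²) (default "standardized" model) or
1/√(N·r²·φ(1−φ)) ("binomial" model, φ the case fraction):

power = Φ(|b|/SE − z_{1−α/2}) + Φ(−|b|/SE − z_{1−α/2}),

exactly symmetric in OR ↔ 1/OR, with the binomial model always the more
conservative (φ(1−φ) ≤ 1/4). The standardized model is the default
because it reproduces the published detectable-OR claims of the
motivating design (OR 1.30 at r² = 0.005 and OR 1.19 at r² = 0.016 both
clear 80% power at N = 45,563); the exact variance decomposition of the
cited method is not restated in the source, so both variants are exposed.
The minimum detectable OR is found by bisection (Brent) to 1e-6 and is
inverse-consistent with the power function. Exposure-GWAS uncertainty is
accepted in the spec object but ignored by this first-order formula.

## Synthetic data generator

Haplotypes are thresholded correlated Gaussians (AR(1) correlation
ρ_block within blocks, independence across blocks), alleles 1 with
probability equal to the per-SNP MAF, dosage = sum of two independent
haplotypes; both cohorts are drawn independently from the same
structure. The dosage-scale LD implied by the latent correlation is
computed exactly from bivariate-normal orthant probabilities and is the
"true LD" the correlated estimators consume. The exposure is
X = Gγ + cU + e with the environmental variance set so Var(X) = 1
exactly; the outcome cohort's liability is L = βX* + Gα + cU + e′ with
X* regenerated by the same rule (per-SNP direct effects α model
horizontal pleiotropy; U is the shared confounder), and case status is L
above the (1−prevalence) quantile of the analytic liability
distribution. Per-SNP GWAS fits are vectorized closed-form OLS
(continuous) and vectorized Newton-scoring logistic ML (binary;
separation is detected and the SNP dropped with a warning); the logistic
solver is cross-checked against statsmodels in the test suite. All
randomness flows from one seed through three spawned streams
(parameters, exposure cohort, outcome cohort), so outcome-side changes
cannot perturb exposure-side summaries and identical seeds give
byte-identical output files.

**What the estimators converge to.** Because the GWAS fit is logistic
while the causal effect acts on the probit (liability) scale, the
per-SNP log-odds is an attenuated/rescaled transform of the liability
coefficient, not the coefficient itself. The truth object therefore
carries the *pseudo-true* per-SNP logistic slopes — computed by
approximating the liability given a single dosage as normal (near-exact
here: the conditional noise is dominated by exactly Gaussian terms) and
solving the three-point logistic pseudo-MLE exactly — plus their IVW
pooling under the true LD. Recovery and coverage tests target this
pseudo-true pooled slope, which is what a consistent summary-statistic
estimator can converge to; the semi-analytic slopes are validated
against a 200,000-individual Monte Carlo fit in the unit tests.

**Default conditions.** Three instruments in one AR(1) block
(ρ = 0.35), MAF drawn from (0.20, 0.45), per-allele effect 0.10 SD,
exposure cohort 12,597 (the size of the motivating exposure GWAS),
outcome cohort 20,000 with case fraction 0.381 (the case fraction of the
motivating outcome GWAS), causal effect 0.25 per SD, confounder loading
0.3, no pleiotropy. These give expected first-stage F well above 30 —
the strong-instrument regime of the motivating study. The generator
emulates two-sample structure, LD, confounding and pleiotropy, but not
realistic human LD maps, imputation uncertainty, or sample overlap
between the two GWAS; passing tests therefore certify the estimators'
behaviour under the stated generating model, not robustness to those
additional real-data complications.

## Problem sizes and numerical choices

The simulation-based checks use 1,000 replicates for IVW coverage/bias
and for Egger-intercept calibration (cohorts of 12,597-20,000
individuals, 3-10 SNPs), 400-500 replicates for null-recovery checks,
and dense 1-D/2-D grids (steps 5e-4 / 2e-3) as optimizer oracles; these
sizes put Monte-Carlo error well inside the asserted bounds while
keeping the default test run to a few minutes. Ties in clumping break
lexicographically; LD validation tolerances are 1e-10 (symmetry, unit
diagonal) and −1e-8 (eigenvalue floor before ridge repair); P-values are
floored at the smallest positive double to honour the (0,1] contract;
degenerate inputs (zero exposure beta in a ratio, perfect Egger fits,
singular Ω) raise typed errors rather than returning NaNs, and the
pipeline logs and skips a failed sensitivity method instead of aborting.

## Limitations

GSMR, CAUSE, weighted-median/mode estimators and Steiger filtering are
out of scope, as are reference-panel downloads, proxy-SNP search and
VCF/PLINK parsing (LD comes from a user-supplied matrix or dosage
table). RAPS here is the simple-loss, independence-assuming variant,
intended as a sensitivity replicate on clumped instrument sets. The
power formula is first-order in the outcome GWAS only. The
cis-instrument fixture ships with exposure-side statistics only; outcome
GWAS associations must be supplied by the user, so published
outcome-side results are not re-derivable from the bundle alone.
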