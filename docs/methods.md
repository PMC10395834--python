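# Methods

This note records the statistical models implemented in `micromr`, the
conventions and defaults chosen where the methodology literature leaves
options open, what the synthetic-data generator does and does not emulate,
and the numerical decisions a maintainer would want to know.

## Two-sample summary-data model

All estimators consume per-variant pairs (β_Xj, σ_Xj, β_Yj, σ_Yj) after
harmonization. The working model is the standard linear instrumental-variable
approximation on the summary scale: β_Yj = θ·β_Xj + α_j + ε_j, where θ is the
causal effect of exposure on outcome (log-odds units for binary outcomes),
α_j is a direct (pleiotropic) effect of variant j, and ε_j has variance
σ²_Yj. Instrument validity assumes α_j = 0 (exclusion restriction); the
sensitivity battery probes departures.

### Harmonization conventions

* Allele alignment tries, in order: identical pair; swapped pair (flip β_Y
  sign, complement EAF); strand complement then the same two rules.
* Palindromic (A/T, C/G) variants carry no strand information in their
  letters. At intermediate frequency — min(EAF, 1−EAF) > 0.3 — the two
  strand readings are indistinguishable and the variant is dropped
  (`palindrome_ambiguous`); below that, alignment follows the side of 0.5 on
  which the two EAFs fall. A variant with no EAF cannot be
  frequency-aligned and is dropped when palindromic.
* Instrument strength is the squared z-score F = (β_X/σ_X)², the one-SNP
  identity; the threshold (default 10) is applied inside harmonization so the
  exclusion log accounts for every input variant exactly once.
* LD clumping is greedy on ascending p with squared correlation r² ≥ 0.01
  within a 10,000 kb window; the literature sometimes writes this rule as a
  bound on r — both readings are supported via `r2_threshold` (set it to
  0.01 for r², or 0.0001 for |r| > 0.01). Ties in p are broken by
  (chromosome, position, variant id) for determinism. Positions are 1-based;
  the window is |pos_i − pos_j| ≤ window_kb·1000.

### Estimators

* **Wald ratio** θ̂_j = β_Yj/β_Xj with first-order delta SE σ_Yj/|β_Xj|.
  The second-order term is available via configuration but is not the
  default, matching common practice.
* **IVW** is the zero-intercept weighted regression with weights 1/σ²_Yj.
  The multiplicative random-effects (MRE) variant scales the fixed-effect SE
  by max(1, √(Q/(J−1))): over-dispersion widens intervals, under-dispersion
  never narrows them. A single instrument reduces identically to the Wald
  ratio.
* **MR-Egger** adds a free intercept, fitted after orienting every
  instrument to a positive exposure effect — the estimator's usual
  convention, and what makes the slope and intercept invariant to arbitrary
  allele re-coding. Slope and intercept SEs carry the max(1, √(Q_e/(J−2)))
  inflation. With all β_X equal the design is singular and a collinearity
  error is raised.
* P-values use the normal reference by default (two-sample MR convention);
  a t reference with J−2 df is available (`use_t`).
* **Steiger**: per-variant r² = t²/(t²+n−2) summed per trait; the aggregate
  correlations (square roots of the sums) are Fisher-transformed and
  compared with a z-test using variances 1/(n−3). The forward direction is
  declared when the instruments explain more variance in the exposure.
* **Cochran's Q** = Σ(β_Yj − θ̂β_Xj)²/σ²_Yj against χ²(J−1) (J−2 after
  Egger).
* **BH-FDR** goes through `statsmodels`; the screen tiers rows at
  adjusted p < 0.2 (significant) and raw p < 0.05 (suggestive).

### MR-PRESSO

The observed residual sum of squares uses leave-one-out IVW predictions so
no instrument influences its own reference. Parametric replicates draw
β*_X ~ N(β_X, σ_X) and β*_Y ~ N(θ̂₋j β_Xj, σ_Yj) and recompute the RSS the
same way; empirical p-values use the plus-one correction and are therefore
never 0. Per-variant outlier tests compare each observed squared
standardized residual to its simulated distribution, Bonferroni-corrected
at α = 0.05 across instruments (the published tool's convention). Note the
granularity constraint: with J instruments, a variant can only be flagged
when n_simulations > J/α; the default 1000 satisfies this for J ≤ 50. The
distortion test compares the raw-vs-corrected estimate difference against
removals of random same-size instrument subsets (two-sided empirical p) —
the procedure's distortion step is not fully specified in the application
literature, and this subset-resampling null is this package's documented
reading.

### Colocalization

Per-variant Wakefield log-ABFs, log ABF = ½[log(1−r) + r·z²] with
r = W/(V+W), feed the standard single-causal-variant hypothesis sums; H3
(distinct causal variants) is the all-ordered-pairs sum minus the shared
diagonal, computed by log-sum-exp and log-diff-exp throughout. Priors
default to p1 = p2 = 1e-4, p12 = 1e-5; the prior effect SD defaults to 0.15
(binary-trait scale). Only PP.H4 > 0.8 is a decision rule; the priors and W
are configuration. The region definition is the caller's responsibility.

### MR-BMA

In inverse-variance-whitened coordinates (each row divided by σ_Yj) the
outcome vector is modeled as y ~ N(X_S θ_S, I) with θ_S ~ N(0, σ² I),
σ = 0.5, giving the closed-form log evidence −½(log det M + yᵀM⁻¹y),
M = σ²X_SX_Sᵀ + I, evaluated through the K-dimensional form for speed. The
model prior is binomial with inclusion probability 0.1. The −J/2·log 2π
constant is dropped (it cancels in posteriors). MIP_j sums posteriors of
models containing j; MACE_j sums posterior × conditional ridge estimate —
equivalently the posterior mean of a coefficient that is exactly zero in
models excluding j, hence deliberately conservative.

The space is enumerated exhaustively for K ≤ 15. Beyond that a shotgun
stochastic search walks add/delete/swap neighborhoods, moving with
probability proportional to posterior, caching evaluations, and stopping at
the evaluation budget (default 10,000) or after 50 consecutive moves that
discover no new model; posteriors are then normalized over the evaluated
space — an approximation that is exact whenever the budget covers 2^K.

Influence diagnostics compute, for each top-posterior model, per-variant
Cook's distances from the whitened least-squares fit and squared residual
(q) contributions; the flag threshold defaults to the 4/J convention. On
clean Gaussian data that convention flags a few percent of variants by
construction — the flags are a ranking device feeding the re-run hook
(`exclude_variants`), not a test with a controlled error rate. Empirical
MIP p-values by outcome permutation are provided as an optional, seeded
utility.

### Two-step mediation

b₁ (total, exposure→outcome), b₂ (exposure→mediator) and b₃
(mediator→outcome) are each univariable MR estimates with
exposure-appropriate selection thresholds (5×10⁻⁸ dietary, 1×10⁻⁵
microbial). Instruments selected for the exposure are excluded from the
mediator→outcome step: if the exposure has any direct effect on the
outcome, its instruments violate the exclusion restriction for the mediator
and would leak that effect into b₃. The indirect effect is b = b₂b₃ with
delta-method SE √(b₂²σ₃² + b₃²σ₂²); the mediated proportion 100·b/b₁ is
passed through unclipped (published tables legitimately contain negative
proportions and values above 100% when direct and indirect paths oppose).
The reported mediation probability is the one-sided upper-tail normal
probability P(indirect ≤ 0) — small when b is reliably positive — the only
convention consistent with the sign pattern of the worked-example table the
package ships; a two-sided option exists. Report rounding is half-away-from-
zero at two decimals; internal values are never rounded.

### Consensus

Four streams vote per exposure–outcome pair: univariable p < 0.05; ranking
MIP > 0.1; membership in the identification stage's top-10 MIPs; external
network-shift score ≥ 1. Scores are an input column — the network method is
published elsewhere and outside this package's scope. Streams without data
do not count toward either numerator or denominator; robustness requires
agreement of ≥ 3 streams. Specificity is the absence of nominal signal
against every supplied non-target outcome.

## Synthetic-data generator

The generator emulates two-sample summary data, not individual-level
genotypes. Latent effects are drawn, observed effects add Gaussian noise at
the reported SE, and SEs follow 1/√(2n·EAF(1−EAF)) for a standardized
continuous trait. Disease outcomes are binary at a few percent prevalence,
so their log-odds SEs include the case-fraction variance factor
1/√(cf(1−cf)), cf = 0.03 by default; omitting it (the naive constant-
variance form) overstates outcome precision roughly six-fold and makes
exposure-side noise dominate the Wald ratios, which is not how
biobank-scale binary GWAS behave.

Default conditions, chosen once as the study scale this pipeline targets:

| parameter | default | rationale |
|---|---|---|
| exposure GWAS n | 7,738 | microbiome-GWAS scale |
| outcome GWAS n | 220,000 (cf 0.03) | biobank disease GWAS |
| dietary GWAS n | 350,000 | biobank continuous/ordinal trait |
| SNP–exposure effect SD | 0.3 | instrument F in the hundreds, the strength reported for lead microbial-QTL variants |
| instruments per microbial trait | 50 (30 in outlier scenarios) | post-clumping counts |
| dietary instruments | 100 | biobank dietary traits yield many loci |
| causal effect θ | 0.2 | moderate log-odds effect |
| balanced pleiotropy SD | 0.05 | comparable to θ·γ spread |
| directional pleiotropy | U(0, 0.1), exposure-increasing orientation | the standard one-signed simulation design; mean 0.05 |
| outlier displacement | 5 × √(σ²_Y + θ²σ²_X) | a true 5-sigma Wald-residual outlier |
| EAF | U(0.05, 0.95), 20% palindromic | exercises harmonization |
| coloc LD | AR(1), r = 0.9 between neighbors; causal z = 8 | a well-powered locus |

Directional pleiotropy and one-signed outliers are defined relative to the
exposure-increasing allele: a symmetric draw in the arbitrary coded
orientation is sign-scrambled by allele re-coding and behaves as balanced
pleiotropy, which is not the phenomenon those scenarios test.

What the generator does **not** emulate — and hence what green tests do not
establish about real data: LD between instruments (the emitted LD matrix is
identity unless configured, so clumping is exercised separately), winner's
curse from discovery-and-use in one cohort, sample overlap between exposure
and outcome GWAS, population stratification, compositionality of microbiome
abundances, and assortative-mating or dynastic effects. Calibration results
(coverage, type-I error) hold under the generator's Gaussian summary-data
model; real-data departures from that model degrade them.

All streams derive from a single root seed via named `SeedSequence` spawn
keys, so stages are independently reproducible and equal seeds give
byte-identical outputs.

## Numerical choices and degenerate inputs

* Empirical p-values (PRESSO, distortion, permutation MIPs) use the
  (1 + #extreme)/(1 + B) correction.
* Two-sided normal p-values are floored at the smallest positive double so
  FDR adjustment never sees 0.
* Coloc accumulation is log-sum-exp / log-diff-exp; posteriors are
  renormalized and checked to sum to 1 within 1e-9.
* Degenerate designs raise typed errors rather than returning numbers:
  empty instrument sets (IVW), J < 3 (Egger), J < 4 (PRESSO), equal β_X
  (Egger collinearity), rank-deficient BMA subsets, fewer than two exposures
  after pruning (directing the caller to univariable analysis), b₁ = 0
  (undefined mediated proportion).
* The screen driver records per-exposure failures in their result rows and
  never aborts the panel.

## Analysis problem sizes

The shipped analysis scripts and test suite run at desk scale, chosen so the
full battery completes in minutes on one core: 200 replicates for recovery
and power suites (500 for Egger type-I error), 1000 PRESSO simulations per
fit (500 in the null-uniformity sweep), panels of 6–12 exposures over
120–150 union instruments, and 200-variant coloc regions. These sizes are
the package's own defaults; all are parameters.

## Known limitations

* Only the independent-normal effect prior is implemented for MR-BMA (no
  g-priors or correlated priors), and evaluated-space normalization under
  stochastic search slightly overweights high-posterior regions when the
  budget does not cover the space.
* Colocalization assumes at most one causal variant per trait per region.
* The mediation module estimates one pathway at a time; simultaneous
  multi-mediator adjustment and exposure–mediator interaction are out of
  scope.
* The weighted-median and mode estimators are deliberately absent; the
  univariable battery is IVW/Wald/Egger plus the sensitivity suite.
* NetMoss-style network scores are consumed, never computed.
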