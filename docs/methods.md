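# Methods

This note records the statistical models the package implements, the
conventions and defaults it adopts where the literature leaves room, and
what the synthetic validation studies do and do not demonstrate.

## Two-sample summary-data MR model

For instrument j, the exposure GWAS reports β̂_Xj ~ N(β_Xj, σ_Xj²) and the
outcome GWAS (a case-control study, so effects are log odds ratios) reports
β̂_Yj ~ N(β_Yj, σ_Yj²), with errors independent across the two studies
because the cohorts do not overlap. Under the instrumental-variable
assumptions β_Yj = θ·β_Xj + α_j, where θ is the causal log-OR per exposure
unit and α_j is the horizontal-pleiotropy (direct) effect, zero for a valid
instrument.

### Estimators

- **Wald ratio** (J = 1): θ̂_j = β̂_Yj/β̂_Xj, SE σ_Yj/|β̂_Xj| (first-order,
  ignoring exposure-side noise; with the F > 10 screen in place the
  neglected term is below ~10%, and in the simulated conditions F ≈ 100).
- **IVW**: θ̂ = Σ w_j θ̂_j / Σ w_j with w_j = (σ_Yj/|β̂_Xj|)⁻², which is
  algebraically weighted least squares of β̂_Y on β̂_X through the origin
  with weights σ_Yj⁻². Fixed-effect SE (Σ w_j)^(−1/2). The random-effects
  variant inflates the SE multiplicatively by max(1, √(Q/(J−1))) — never
  deflating it — rather than adding an additive between-SNP variance; this
  is the convention usual for summary-data MR. "Auto" mode uses random
  effects exactly when the Q test is significant (default q_alpha = 0.05).
  P-values are two-sided normal.
- **Cochran's Q / I²**: Q = Σ w_j (θ̂_j − θ̂)², df = J − 1, upper-tail
  chi-square p, I² = max(0, (Q − df)/Q)·100.
- **MR-Egger**: instruments are first oriented so every β̂_Xj > 0 (a
  simultaneous sign flip of both betas, which leaves every estimator
  invariant, fixes the intercept's meaning), then β̂_Y is regressed on β̂_X
  with intercept and weights σ_Yj⁻². Analytic SEs use the WLS residual
  dispersion RSS/(J−2) with t(J−2) reference distributions for both slope
  and intercept — the exact small-sample test when ratio variances are
  proportional to the weights. A dispersion floor is deliberately not
  applied to inference (flooring makes the intercept test conservative);
  an exact-fit dataset is kept representable by flooring the dispersion at
  the smallest positive double only. The bootstrap SE option redraws
  β̂*_X ~ N(β̂_X, σ_X), β̂*_Y ~ N(β̂_Y, σ_Y) and takes the SD of refit
  slopes (B = 1000 by default, seed required).
- **Weighted median**: ratios sorted ascending, each placed at the midpoint
  of its cumulative standardized weight, linear interpolation at one half;
  outside [p₁, p_J] the extreme ratio is returned. SE by the same
  parametric bootstrap.
- **Likelihood-based MR**: maximize Π_j N(β̂_Xj; ξ_j, σ_Xj²)·N(β̂_Yj;
  θξ_j, σ_Yj²). Given θ the maximizing ξ_j has the closed form
  (β̂_Xj/σ_Xj² + θβ̂_Yj/σ_Yj²)/(σ_Xj⁻² + θ²σ_Yj⁻²); θ is then found by
  bounded 1-D minimization (xatol 1e-10) on an interval of ±(10|θ_IVW|+10)
  around the IVW start, and the SE comes from the central-difference
  curvature of the profile log-likelihood (step 1e-4·(1+|θ̂|)). A
  non-concave curvature raises an estimation error rather than returning a
  bogus SE.

### MR-PRESSO

Observed statistic: RSS = Σ_j w_j (β̂_Yj − θ̂^(−j)β̂_Xj)² with θ̂^(−j) the
leave-one-out IVW slope and w_j = σ_Yj⁻². Null replicates draw
β̂*_X ~ N(β̂_X, σ_X) and β̂*_Y ~ N(m_j, σ_Y) and recompute the statistic
identically (leave-one-out slopes refit per replicate; n_sim = 1000).

Two conventions for the replicate mean m_j are in circulation. Centering on
the leave-one-out slopes (m_j = θ̂^(−j)β̂_Xj) injects the sampling spread of
J different fitted slopes into the null data and makes the global test
conservative — we measure rejection ≈ 0.01 at nominal 0.05 in the validation
conditions. The package therefore centers the **global** test's replicates
on the single-slope null (m_j = θ̂_full·β̂_Xj), which restores near-nominal
size, while the **per-SNP outlier** test keeps leave-one-out means so that a
gross outlier cannot contaminate its own null distribution. Empirical
p-values use the add-one correction (never exactly zero); outlier p-values
are Bonferroni-adjusted across J and flagged below 0.05. With outliers
flagged, IVW is recomputed without them; the distortion percentage
100·(θ̂_all − θ̂_reduced)/|θ̂_reduced| is compared against removals of 1000
random same-size subsets. Datasets with J ≤ 3 return an explicit
"not evaluable" status, as do the intercept test (J < 3) and the weighted
median (J < 3); these statuses propagate into the report tables instead of
silently missing rows.

### Decision tree and study orchestration

Per (exposure, outcome, database): J = 1 → Wald; J ≥ 3 with a significant
Egger intercept (default 0.05) → Egger with bootstrap SEs; otherwise IVW
with the Q test choosing fixed vs random. Sensitivity analyses are gated by
instrument count (likelihood > 1, weighted median > 2, MR-PRESSO > 3,
leave-one-out ≥ 2). The intercept gate runs before the Q gate; the Q test
only arbitrates within the IVW branch. Per-database primary estimates are
pooled with fixed-effect inverse-variance meta-analysis, switching to
DerSimonian–Laird random effects when the between-database Q is significant;
tau² = max(0, (Q − (k−1))/(Σw − Σw²/Σw)). A database that produces no
estimate (for example, all instruments missing from its outcome GWAS)
degrades the pooling to the remaining databases with an explicit warning.
Evidence labels partition (0, 1]: significant below α/m, suggestive in
[α/m, 0.05), null at and above 0.05; m defaults to
n_exposures × n_outcomes. Stochastic steps derive their seeds
deterministically from the master seed and the triple's labels (CRC-32 into
a SeedSequence), so re-running a study bundle is byte-identical.

### Instrument building

Significance filter (strict p < 5e-8 by default), greedy LD clumping
(r² > 0.001 within 10,000 kb discarded against the best remaining p-value;
ties broken by lexicographic rsID; without positions the r² lookup is
authoritative), confounder screen (drop variants with a reported confounder
association below 5e-8), proxy substitution for variants absent from the
outcome GWAS (highest r² ≥ 0.8, ties lexicographic, allele map applied),
allele harmonization, and the weak-instrument filter (strict F > 10 with
F = β̂²_X/σ̂²_X). Harmonization resolves swapped alleles by negating the
outcome beta (complementing its frequency) and opposite-strand reports by
base complement; palindromic A/T and C/G variants are oriented by allele-
frequency proximity, and dropped when either study's frequency falls in
[0.42, 0.58] or is missing (policy "drop" discards all palindromes). Every
input variant receives exactly one final audit disposition: kept, proxied,
or dropped with a reason.

### Power and multiplicity

Binary-outcome power uses the non-centrality approximation
λ = |ln OR|·√(n·r²·K(1−K)), power = Φ(λ − z_{1−α/2}) + Φ(−λ − z_{1−α/2});
it is exactly α at OR = 1 and symmetric in OR ↔ 1/OR. The Bonferroni
threshold α/m is reported alongside a one-significant-figure display value
(0.05/48 → 0.001).

## Synthetic data generator

The generator emulates the data structure the pipeline consumes: an
exposure cohort with a continuous trait and an independent outcome cohort
with a logistic binary disorder, genotyped at J Hardy–Weinberg SNPs
(MAF ~ U(0.1, 0.5)). Per-SNP effects γ_j have lognormal magnitude spread
(sd 0.5 on the log scale — GWAS hits span a wide effect range) and are
jointly scaled so the instruments explain a target r² of the unit-variance
exposure, mirroring the "explained variance" reported for real instrument
sets. Disease liability is expit(α₀ + θX + Σ α_j G_j) with α₀ solved by
root-finding on the realized linear predictor to hit the target prevalence.
Cohorts are summarized SNP-by-SNP the way a GWAS would release them: OLS
for the exposure; maximum-likelihood logistic regression for the outcome,
fit by a Newton solver vectorized across SNPs (each marginal model has two
parameters, so the update is closed-form; agreement with a generic logistic
fitter is covered by tests). Monomorphic or non-converged SNPs are excluded
with a warning. Variants receive non-palindromic allele pairs so the
harmonization step is exercised losslessly; palindromic handling is tested
directly on constructed records.

Named presets define the validation conditions (all with J = 10, 50k/50k
cohorts, prevalence 0.1, r² = 0.02 unless noted): `valid` (θ = 0.2, no
pleiotropy), `null` (θ = 0), `balanced` (α_j ~ N(0, 0.01²), comparable to
half a typical outcome-GWAS SE at these sizes), `directional`
(α_j ~ N(0.01, 0.005²), InSIDE satisfied; biases IVW by roughly
mean(α)/mean(γ) ≈ 0.12 here), `outlier` (one SNP with a direct effect 10×
its approximate outcome SE), and `contaminated` (4/10 instruments shifted
by +0.5 on the ratio scale). The contaminated preset uses stronger
(r² = 0.10, within the range real micronutrient instrument sets explain)
and more homogeneous (log-sd 0.2) instruments: the weighted median's
guarantee concerns an invalid minority of the *weight*, and with J = 10
strongly dispersed weights a 4-SNP minority frequently exceeds half the
weight; with weak instruments the per-ratio noise (SE ≈ 0.35 at r² = 0.02)
also swamps the 0.5 contamination separation, eroding the median's
robustness for reasons unrelated to the estimator. An optional block-LD
mode (each SNP copies its left neighbour per individual with probability
ld_rho inside blocks, giving geometrically decaying correlation) exists to
exercise clumping; the default is linkage equilibrium.

What the generator does **not** emulate: realistic LD panels, imputation
error, sample overlap, population stratification, winner's-curse selection
of instruments, or between-cohort assay heterogeneity in the exposure.
Passing the validation suite therefore demonstrates the statistical
machinery under the model's own assumptions, not robustness to those
real-data complications.

## Validation studies and problem sizes

The end-to-end checks (tests/test_acceptance.py, recomputed by
scripts/acceptance.py) use 500 replicates for test size, recovery and
coverage (IVW size within [0.03, 0.07]; mean estimate within ±0.02 of
θ = 0.2; coverage in [0.92, 0.97]; Egger intercept size under balanced
pleiotropy within [0.03, 0.07]) and 200 replicates for the robustness
orderings (|bias| of weighted median < IVW under contamination; Egger < IVW
under directional pleiotropy) and for MR-PRESSO (outlier detection ≥ 90%;
global size within [0.02, 0.08]). Oracle-equivalence checks (IVW ≡
origin-constrained WLS, Egger ≡ intercept WLS, both to 1e-10; clumping ≡
brute-force greedy) run on 200 random instances with J ≤ 12. The power
formula is checked against a 100k-draw Monte-Carlo Wald simulation at the
strongest real-world-style parameterization (n = 50k, K = 0.1, r² = 0.017,
OR = 1.2) within 0.01.

## Known limitations

- The Wald-ratio SE is first-order; very weak instruments (F near the
  screening threshold) would make it optimistic.
- The likelihood-based SE comes from profile curvature, which assumes a
  locally quadratic profile; heavy pleiotropy can make the profile
  irregular (an error is raised on non-concavity rather than a repair
  attempted).
- The weighted-median bootstrap treats weights as re-estimated per
  replicate but ignores correlation between numerator and denominator
  within a replicate beyond the parametric model.
- Proxy substitution trusts the supplied allele map; it does not verify it
  against an LD panel.
- No Steiger directionality filtering, multivariable MR, or non-linear MR.
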