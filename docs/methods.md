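# Methods

## Model and estimands

The toolkit works on two-sample summary statistics for m independent SNP
instruments: exposure associations αⱼ (assumed estimated in a large
external cohort), outcome associations β̂_YGⱼ with standard errors σ_Yⱼ,
all harmonized to a common effect allele upstream.  The structural model
behind the estimators is

    β̂_YGⱼ = β₁ αⱼ + β₂ⱼ + εⱼ,   εⱼ ~ N(0, σ_Yⱼ²),

where β₁ is the causal effect of interest and β₂ⱼ the direct
(pleiotropic) effect of SNP j on the outcome.  Pleiotropy is *balanced*
when the β₂ⱼ have sample mean zero and *directional* otherwise; all
Egger-based adjustment additionally assumes InSIDE (β₂ⱼ independent of
αⱼ).  By default the αⱼ are treated as known without error (NOME); an
optional per-SNP `alpha_se` records measurement error but is deliberately
*not* absorbed into the weights — the point of the weak-instrument mode
is to show what goes wrong when it is ignored.

## Statistics

- IVW: β̂_IVW = Σ wⱼ β̂ⱼ / Σ wⱼ with β̂ⱼ = β̂_YGⱼ/αⱼ, wⱼ = αⱼ²/σ_Yⱼ²;
  fixed-effect SE (Σ wⱼ)^{-1/2}.
- Cochran's Q = Σ wⱼ(β̂ⱼ − β̂_IVW)², referred to χ²(m−1); per-SNP
  contributions Qⱼ to χ²(1).
- MR-Egger: weighted least squares of β̂_YGⱼ on αⱼ with weights σ_Yⱼ^{-2}
  and a free intercept.  These weights are algebraically identical to the
  ratio-scale wⱼ and make Rucker's Q′ exactly the Egger weighted residual
  sum of squares, which guarantees the nesting Q′ ≤ Q (the IVW fit is the
  same weighted regression with the intercept pinned at zero).  The
  per-SNP form wⱼ(β̂ⱼ − β₀/αⱼ − β₁)² is the same quantity on the ratio
  scale.
- Per-SNP outlier tests compare Qⱼ (or Q′ⱼ) with the χ²(1) quantile at
  1−FWER and, for familywise control, 1−FWER/m (Bonferroni).  Only the
  upper tail is used: contributions are non-negative by construction.

## Design choices

**Sign orientation.**  Before the Egger fit, any SNP with αⱼ < 0 has
(αⱼ, β̂_YGⱼ) jointly negated.  This is a pure effect-allele relabelling —
ratios, weights, IVW and Q are invariant — but without it the Egger
intercept is not identified under allele recoding.  Whether orientation
was applied is recorded on the result.

**Egger intercept inference.**  Default: z-test with fixed-effect SEs
taken from the known-variance WLS covariance (X′WX)⁻¹.  Two opt-in
variants: multiplicative random-effects scaling of both SEs by
max(1, √(Q′/(m−2))), and a t(m−2) reference distribution.  The variant in
force is recorded in every experiment manifest so a power curve states
its exact test.

**Outlier removal.**  Single-pass removal of Bonferroni-flagged SNPs is
the default; iterative removal is behind a flag and logs a warning,
because repeated testing on filtered data no longer controls the nominal
FWER.  Removal refuses to leave fewer than 2 SNPs, and iteration stops
before the set becomes too small for the Egger refit (m < 3).

**Model hint.**  The report exposes Q − Q′ and a qualitative hint
("egger-better" when Bonferroni outliers exist on Q but none on Q′).  It
is advisory only; no automatic model selection is performed.

## Synthetic data generator

Summary-level defaults (all overridable in `SimulationConfig`):

| parameter | default | rationale |
|---|---|---|
| m | 25 | a typical moderately sized instrument set |
| αⱼ | Uniform(0.05, 0.5) | spans weak-to-strong instruments; nonzero spread is required for Egger identifiability and drives Egger-intercept power |
| σ_Yⱼ | Uniform(0.05, 0.15) | ratios individually noisy, yet the 25-SNP Q test has visible power across the pleiotropy grid |
| β₁ | 0.05 | a small causal effect; the pleiotropy tests do not depend on its value (the weak-instrument study is the exception, below) |
| balanced β₂ⱼ | Uniform(−c, c), c ≤ 0.2 | zero mean with controlled maximum magnitude |
| directional β₂ⱼ | Uniform(0, 2·mean), mean = 0.1 | simultaneously fixes the mean at 0.1 and the maximum at 0.2 |
| alpha_se | 0 | NOME holds unless the weak-instrument mode is opted into |

β₂ⱼ is always drawn independently of αⱼ, so InSIDE holds by construction.
`include_noise=False` suppresses εⱼ for exact-recovery diagnostics (σ_Yⱼ
stays positive so the weights remain defined).  Reproducibility: every
driver takes one base seed and derives per-replicate substreams with
`numpy.random.SeedSequence` spawning, so identical configs give bitwise
identical outputs.

The individual-level generator draws two disjoint cohorts from one
population: genotypes Binomial(2, maf) with maf ~ Uniform(0.1, 0.5), a
shared standard-normal confounder entering exposure and outcome with
coefficient 0.5, and unit-variance noise on each trait.  Exposure
associations come from per-SNP marginal regressions in cohort 2, outcome
associations from cohort 1.

What the generator does *not* emulate: linkage disequilibrium between
instruments, binary outcomes and case-control ascertainment, allele
frequency/effect-size coupling, winner's-curse selection of instruments,
and sample overlap between the two cohorts.  Passing tests therefore
demonstrate the statistical machinery under idealised two-sample
conditions, not robustness to those real-data complications.

## Experiments and problem sizes

- Power study: 1000 replicates per pleiotropy magnitude c ∈ {0, 0.05,
  0.1, 0.15, 0.2} by default; each replicate applies the Q, Q′ and
  Egger-intercept tests at the 5% level.  Monte-Carlo SE is
  √(p(1−p)/n_sim).
- Null calibration and null-distribution checks use 5000 replicates —
  enough for a Monte-Carlo SE of 0.3 percentage points on a 5% rate and a
  sensitive Kolmogorov–Smirnov comparison, while completing in seconds.
- Weak-instrument study: pleiotropy off, alpha_se ∈ {0, 0.05, 0.1, 0.15},
  1000 replicates each.  The demonstration config sets β₁ = 0.5: the
  variance term the standard weights ignore is β₁²·alpha_se², so with a
  near-zero causal effect Q stays calibrated even under gross measurement
  error, and a sizeable β₁ is what exposes the inflation.
- The contribution-profile experiment is a single seeded draw by design;
  the distributional claim (more Bonferroni outliers on Q than on Q′
  under directional pleiotropy) is tested over repeated seeds instead.

## Numerical notes

- Heterogeneity statistics are plain weighted sums; decompositions
  ΣQⱼ = Q and ΣQ′ⱼ = Q′ hold to floating-point round-off and are asserted
  at 1e−10 relative tolerance in the tests.
- The Egger fit delegates to `statsmodels` WLS; the test suite checks it
  against an independent normal-equations solve at 1e−8.
- Degenerate inputs fail loudly: fewer than 2 SNPs (any analysis), fewer
  than 3 (Egger), all instrument strengths identical after orientation
  (singular Egger design), zero-strength instruments (dropped with a
  warning at validation, or rejected in strict mode).
- p-values are reported at full double precision, never truncated.
- Interchange I/O formats floats with `%.17g` and parses with
  round-trip-exact float conversion, so write→read reproduces every field
  bit-exactly.

## Limitations

Beyond the generator gaps above: no weak-instrument-corrected Q weights,
no robust/median/mode estimators, no multivariable extension, no SIMEX
correction for Egger attenuation, and the χ²(1) reference for individual
contributions is an approximation that weakens for small m (the report
carries m so users can judge; no internal cutoff is imposed).
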