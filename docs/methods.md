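# Methods

## Model and assumptions

Let β_Xj ± σ_Xj and β_Yj ± σ_Yj be the estimated associations of SNP j with
the exposure (SD units) and the outcome (log-odds), from two GWAS of
non-identical samples.  Under the instrumental-variable assumptions
(relevance, exchangeability, exclusion restriction) each SNP identifies the
same causal effect θ through its Wald ratio θ̂ⱼ = β̂_Yj / β̂_Xj.  The working
generative model behind every estimator and the synthetic generator is

    β̂_Xj ~ N(β_Xj, σ_Xj²),   β̂_Yj ~ N(θ·β_Xj + αⱼ, σ_Yj²),

with αⱼ a possible horizontal-pleiotropy (direct) effect.  All estimation
is done on the log-odds scale; odds ratios appear only at the reporting
layer.

## Estimators

**IVW.** θ̂ = Σwⱼθ̂ⱼ / Σwⱼ with first-order weights wⱼ = β̂_Xj²/σ_Yj² —
algebraically the weighted regression of β̂_Y on β̂_X through the origin.
The fixed-effect SE is (Σwⱼ)^{-1/2}; the multiplicative random-effects
model (the default reported estimate) inflates it by √φ̂,
φ̂ = max(1, Q/(J−1)), leaving the point estimate unchanged.  Unbiased when
pleiotropy is balanced (E[α]=0, independent of weights); any directional
component biases it by roughly Σwⱼαⱼ/β̂_Xj / Σwⱼ.

**Weighted median.** Order statistics of θ̂ⱼ placed at standardized
cumulative weights (Sⱼ − wⱼ/2)/Σw, linearly interpolated at 0.5 (with equal
weights this is the interpolated sample median; ties broken by input order
for determinism).  Consistent while valid instruments carry >50% of weight.
The SE is a parametric bootstrap: resample (β̂_Xj, β̂_Yj) from their normal
sampling distributions, recompute the median, take the SD over `n_boot`
(default 1000) replicates.

**MR-Egger.** Weighted least squares of β̂_Y on β̂_X with a free intercept,
weights 1/σ_Y².  Under InSIDE (pleiotropy independent of instrument
strength) the intercept estimates the mean direct effect and the slope is a
pleiotropy-corrected causal estimate.  Both SEs carry the multiplicative
overdispersion √max(1, Q′/(J−2)), where Q′ (Rucker's Q′) is the weighted
residual sum of squares; when Q′/(J−2) > 1 these coincide with classical
WLS standard errors, and an `overdispersion=False` flag gives unscaled
(X′WX)^{-1/2} errors.  Inference uses normal quantiles throughout (a
t-option exists behind `use_t`): at J in the hundreds the difference is
negligible and published CI widths in this design are consistent with
normal inference.

**Heterogeneity.** Cochran's Q about the fixed-effect IVW estimate, df
J−1, chi-square p, I² = max(0, (Q−df)/Q).  The I² confidence interval uses
the closed-form test-based method (standard error of ln H, H=√(Q/df)),
which needs no resampling.  I²_GX applies the same construction to the
exposure betas with weights 1/σ_X²; it measures how much of their spread is
signal rather than sampling noise, i.e. the degree to which the Egger
no-measurement-error (NOME) assumption holds.  I²_GX < 0.9 triggers the
SIMEX stage in the pipeline (override with `simex_mode`).

**SIMEX.** For each λ in (0, 0.5, 1, 1.5, 2) and `n_sim` (default 1000)
replicates, β̂_X is perturbed with N(0, λσ_Xj²) noise and the Egger model
refitted; mean coefficients are modelled as a quadratic in λ and
extrapolated to λ = −1, the error-free case.  Variances follow the
simulation-based difference method: mean model-based variance minus
between-replicate variance, extrapolated the same way (floored at 1e-12
before the square root).  Per-λ child RNG streams derive from the master
seed, so results do not depend on evaluation order.  The λ=0 entry is the
naive fit by construction.

**MR-PRESSO.** dⱼ = wⱼ(β̂_Yj − θ̂₍₋ⱼ₎β̂_Xj)² with leave-one-out fixed-effect
IVW slopes.  The global statistic Σdⱼ is compared against `n_sim` simulated
null datasets (both beta vectors redrawn from the model above with αⱼ=0);
its p-value carries a +1/(n_sim+1) continuity correction and is reported as
a bound when saturated.  Per-SNP p-values are plain exceedance proportions
— deliberately without the continuity floor, matching the original
MR-PRESSO implementation, because a floored p-value could never pass a
Bonferroni threshold of α/J at practical `n_sim` when J is in the hundreds.
Outlier-corrected estimation reruns multiplicative-random IVW without the
flagged SNPs; the distortion test compares the induced shift against
removal of random same-size subsets (without replacement), two-sided.  Note
the per-SNP test's family-wise false-flag rate is α (default 0.05) by
design: occasional single false flags in long simulation batteries are
expected behaviour, not defects.

## Harmonization

Records are matched by exact rsid.  The exposure record is first oriented
so β̂_X ≥ 0 (alleles swapped, beta negated, EAF complemented), making the
effect allele the exposure-increasing allele; this is applied defensively
even to sources that claim pre-orientation.  The outcome is then aligned by
label, by label reversal (beta negated, EAF complemented), or — only when
both direct and reversed matching fail — by A↔T/C↔G strand complementation,
since same-strand reporting is the common case.  Palindromic SNPs carry no
strand information in their labels; the default policy
(`retain_same_strand`, MAF threshold 0.45) trusts the labels as same-strand
reads, mirroring consortium pairs known to share a strand, while
`infer_by_frequency` aligns by EAF concordance and drops SNPs as ambiguous
when the MAF exceeds the threshold or the EAF is missing (fail-safe), and
`drop_above_threshold` simply excludes high-MAF palindromes.  Every record
keeps an action flag (kept/flipped/complemented/dropped-with-reason), so
kept + dropped counts always reconcile with the input.

## Synthetic cohort and its calibration

The generator emits exactly the table structure the reader consumes,
including palindromic and strand-flipped allele labels, so the whole
pipeline — file I/O, harmonization, estimation — is exercisable without any
external data.  Binary-outcome effects are generated directly on the
log-odds scale (no individual-level logistic simulation), keeping the
ground truth analytic; `sampling_noise=False` gives the infinite-sample
limit in which every Wald ratio equals θ exactly.

Defaults emulate a 377-instrument study of a standardized behavioural
exposure against a biobank-scale binary outcome:

- true β_X ~ |N(0.019, 0.0028²)|, σ_X = 0.0022 → mean F ≈ 77 and
  I²_GX ≈ 1 − 1/(1 + (0.0028/0.0022)²) ≈ 0.62 (instruments tightly
  clustered just above the significance threshold);
- σ_Y = 0.007, the precision implied by an IVW standard error of ~0.035
  over 377 such instruments;
- balanced pleiotropy αⱼ ~ N(0, 0.0107²), giving E[Q/(J−1)] ≈
  1 + (0.0107/0.007)² ≈ 3.3, i.e. I² ≈ 0.70;
- θ = 0.25 (OR ≈ 1.28 per SD); ~2.7% palindromic SNPs forced to MAF > 0.45;
  EAF ~ U(0.05, 0.95) with small between-study noise.

What the generator does **not** model: linkage disequilibrium between
instruments (rows are independent, as conditionally independent SNPs should
be), sample overlap between the two GWAS, selection effects (winner's
curse) on the exposure betas, non-normal/heavy-tailed pleiotropy, and
allele-frequency differences between ancestries.  Passing tests therefore
demonstrate correctness of the statistical machinery under its stated
model, not robustness to those real-data pathologies; notably, real studies
can show more PRESSO outliers than the Gaussian-pleiotropy default
produces, because outliers in real data come from a heavier-tailed direct
effect distribution.

## Test-condition choices

Replicate-based checks of Egger intercept recovery and test calibration use
instruments bounded away from zero (β_X ~ |N(0.02, 0.004²)|, σ_X = 5e-4)
rather than the pipeline defaults.  Two reasons: (i) genome-wide
significance bounds true effects away from zero, so mass near zero is
unrealistic for selected instruments, and (ii) near-null instruments get
sign-oriented on noise, which negates their pleiotropy term and introduces
a small artificial downward bias in the mean intercept.  The IVW recovery
check compares the replicate mean against θ·λ with the analytic
weak-instrument attenuation λ = E[β_X²]/(E[β_X²]+σ_X²) (0.987 at the
default calibration — the familiar O(1/F) dilution), alongside a practical
|bias| < 0.01 bound.

## Numerical and design notes

- Weighted regressions use closed-form normal equations (vectorised for the
  batched refits SIMEX and PRESSO need); statsmodels WLS serves as an
  independent oracle in the test suite rather than as the implementation.
- φ̂ truncation at 1 (IVW-MRE and Egger) follows the standard
  multiplicative-overdispersion convention; `truncate_phi=False` disables it.
- Wald-ratio SEs are first-order delta method by default — this is what the
  origin-regression weighting reproduces — with the second-order expansion
  available per instrument.
- Empirical p-values: global/distortion tests are continuity-corrected
  (never 0), per-SNP outlier p-values are not (see above).
- Degenerate inputs raise typed errors: zero exposure beta (undefined
  ratio), all-equal exposure betas (singular Egger design), fewer
  instruments than a method's minimum (1 IVW-fixed / 2 IVW-MRE / 3
  Egger-median-SIMEX / 4 PRESSO), all instruments flagged as outliers.
- The pipeline derives one child seed per stochastic stage from the master
  seed, so stages can be reordered or skipped without disturbing each
  other's streams; reports serialize deterministically via
  `canonical_json()` (the provenance timestamp is excluded there).
- Default problem sizes (377 SNPs; 1000 bootstrap/SIMEX replicates; 5000
  PRESSO draws in the acceptance run, 1000 otherwise) keep a full analysis
  in the low seconds on one core while leaving simulation error well inside
  the reported precision.

## Known limitations

- No LD-aware instrument selection or clumping: instruments are assumed
  conditionally independent on input, and no proxy lookup is attempted for
  SNPs missing from the outcome table.
- The SIMEX quadratic extrapolant undercorrects under very heavy dilution
  (attenuation factors well below ~0.5); the per-λ trace and extrapolation
  R² are reported so this is auditable.
- Mode-based, multivariable and contamination-mixture estimators are out of
  scope.
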