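# Methods

This note records the statistical model, the conventions each estimator
follows, the generative model behind the synthetic data, and the numerical
and design choices that were genuinely open.

## Setting

Two-sample Mendelian randomization treats SNPs as instrumental variables:
for SNP *j*, the exposure GWAS reports (β̂_X,j, σ_X,j) and the outcome GWAS
(β̂_Y,j, σ_Y,j), estimated in non-overlapping samples. Under the
instrumental-variable assumptions (relevance; exclusion — the SNP affects
the outcome only through the exposure; exchangeability), β_Y,j = θ β_X,j
and each Wald ratio β̂_Y,j/β̂_X,j estimates the causal effect θ. Estimates
are in exposure units; when the outcome GWAS is a case-control study
reporting log odds ratios, θ is a log odds ratio per exposure unit and is
only exponentiated on request (`beta_to_or`) — units are user-declared
metadata and never guessed.

## Harmonisation

Outcome records are re-expressed relative to the exposure's effect allele:

* identical labels → unchanged; swapped labels → β_Y ← −β_Y, EAF ← 1−EAF;
* labels matching after base complement → strand flip, handled as the
  corresponding same/swapped case (attempted under actions 2 and 3; action
  1 assumes everything is already forward-strand);
* palindromic SNPs (A/T, G/C): labels carry no strand information, so under
  action 2 orientation is inferred from effect-allele frequencies. With MAF
  threshold t (default 0.3): both frequencies < t or both > 1−t → aligned;
  opposite sides → flipped; otherwise (either frequency inside [t, 1−t],
  using strict inequalities, or missing) the SNP is flagged ambiguous and
  excluded. Action 3 drops every palindrome.

The boundary case (frequency exactly at the threshold) counts as ambiguous:
the conservative reading of "minor allele frequency close to 0.5".
Multi-base (indel) alleles are accepted but never classed palindromic.
Proxy substitution (user-supplied table, default minimum r² = 0.8) replaces
only the outcome record, translating the proxy's alleles through its phase
map; exposure statistics are never proxied. All LD information is injected
from files — no reference panel is bundled, which keeps the tool fully
offline and its tests self-contained.

Non-palindromic label matching tries exact labels first and complements
second; for palindromic SNPs the two orders give identical results (the
final orientation depends only on which side of 0.5 each frequency falls).

## Estimators

Weights are always w_j = σ_Y,j⁻² on the regression scale. With L kept SNPs:

* **IVW**: b = Σ w β̂_X β̂_Y / Σ w β̂_X², the zero-intercept weighted
  regression. se_FE = (Σ w β̂_X²)^(−1/2); residual dispersion
  σ = √(Q/(L−1)). Variants: fixed effects (se_FE), multiplicative random
  effects (se_FE·σ), and the default se_FE·max(1, σ), which falls back to
  fixed effects under under-dispersion. Normal p.
* **MR-Egger**: SNPs are first oriented so every β̂_X,j ≥ 0 (negating both
  betas where needed — the fit is invariant to per-SNP sign flips), then
  β̂_Y = a + b β̂_X by weighted least squares. Standard errors carry the
  same max(1, σ) floor; p two-sided t with df = L−2 for both slope and
  intercept. The bootstrap variant redraws both betas from their reported
  standard errors and replaces the SEs by the spread of the refits.
* **Median**: interpolated weighted median of the ratios (the value where
  the cumulative normalised weight crosses 0.5). Ratio weights are the
  first-order inverse variances (σ_Y/|β̂_X|)⁻². The penalised variant
  multiplies each weight by min(1, 20·p_j) where p_j is the χ²₁ upper-tail
  probability of that SNP's contribution to heterogeneity about the
  weighted-median fit. SE by seeded parametric bootstrap (default 1000
  reps); normal p. Consistent when >50% of weight is on valid instruments.
* **Mode**: weighted Gaussian-kernel density over the ratios, bandwidth
  φ × the Silverman reference bandwidth (φ default 1), estimate = argmax on
  a 1000-point grid spanning the ratios ±3 bandwidths. Weighted variants
  use the full delta-method ratio variance σ_Y²/β̂_X² + β̂_Y²σ_X²/β̂_X⁴;
  the NOME variants drop the exposure-error term (first-order form). SE by
  parametric bootstrap of the ratios, summarised by the normal-consistent
  scaled MAD (1.4826·MAD) — the KDE-argmax bootstrap distribution is
  heavy-tailed, and the MAD is the convention for mode estimators. p
  two-sided t with df = L−1. Valid under ZEMPA (the modal pleiotropic bias
  is zero).
* **Maximum likelihood**: β̂_X,j ~ N(ξ_j, σ_X,j²), β̂_Y,j ~ N(θξ_j,
  σ_Y,j²) independently. Given θ the ξ_j have a closed-form maximiser, so
  θ is found on the 1-D profile objective (bounded minimisation around the
  IVW start, objective tolerance 1e-10); the SE comes from the full
  observed information via the Schur complement of the ξ block. Normal p.

**P-value conventions.** Wald ratio, IVW, maximum likelihood and the median
methods use the standard normal; Egger slope and intercept use t with
df = L−2; mode methods use t with df = L−1. These families reproduce the
published worked-example p-values exactly (to printed precision) from the
printed (b, se, nsnp) triplets; a blanket "t-distribution for everything"
convention would not.

**Method applicability.** With exactly one kept SNP only the Wald ratio
runs, whatever was requested. In the batch runner, methods whose minimum
SNP count (2 for IVW/ML, 3 for Egger/median/mode) is not met are skipped
with a log note; called directly, they raise.

## Sensitivity battery

* Cochran's Q about the fixed-effect IVW line (df = L−1) or the Egger fit
  (df = L−2), χ² upper-tail p. The Egger Q never exceeds the IVW Q on the
  same data (the free intercept absorbs heterogeneity).
* Egger intercept = average directional pleiotropic effect, identical
  numbers to the Egger fit.
* Direction test: per-SNP variance explained r²_j = t_j²/(t_j² + n − 2)
  summed per study (the sum, not a weighted sum — documented choice); the
  test statistic compares Fisher transforms of √r² scaled by
  √(1/(n_X−3) + 1/(n_Y−3)). For binary traits the same t-statistic form is
  applied to the log-odds estimates — a pragmatic approximation, flagged
  here, since no exact binary-trait variance-explained formula exists for
  summary data. The result is a flag about orientation, never an effect
  estimate.
* Leave-one-out: default-IVW estimates omitting each SNP, plus an "All"
  row computed by the identical code path (bit-identical to the batch
  runner's IVW row).
* Single-SNP: per-SNP Wald ratios plus pooled IVW (L ≥ 2) and Egger
  (L ≥ 3) rows; funnel data are (ratio, |β̂_X|/σ_Y); scatter data are
  oriented to β̂_X ≥ 0 with one line per method (intercept 0 except
  Egger). No plots are produced for single-SNP instruments.

## Synthetic data generator

Per SNP: true exposure effect γ_j ~ N(0.15, 0.05²); pleiotropic effect
α_j per scenario (none; balanced N(0, α_sd²); directional N(α_mean, α_sd²)
on a configurable fraction of SNPs; correlated, where α tracks the
standardised γ with correlation ρ — the InSIDE-violation regime); total
outcome effect Γ_j = θγ_j + α_j. Observed effects add independent noise:
β̂_X ~ N(γ, se_x²), β̂_Y ~ N(Γ, se_y²), with independent draws on the two
sides (no sample overlap, matching the two-sample design; overlap is out of
scope). Reported p-values are the two-sided normal p of β̂/se, so the
tables are internally consistent.

Defaults and why:

* **L = 100, θ = 0.2, se_y = 0.05**: a well-powered study with a moderate
  effect — the scale of the recovery studies.
* **γ ~ N(0.15, 0.05²), se_x = 0.01**: instruments that survived
  genome-wide-significance selection are bounded away from zero and widely
  spread; this gives exposure t-statistics of 10–20 and I²_GX ≈ 0.96, so
  the no-measurement-error regime is honest and the Egger slope is
  identifiable. A narrow γ spread would manufacture regression-dilution
  bias in Egger that says nothing about the estimator.
* **EAF ~ U(0.05, 0.95)** with observation noise (sd 0.005) per side, 20%
  palindromic SNPs by default; strand flips and label swaps are applied to
  the outcome table only, with the truth recorded per SNP.
* n_exp = n_out = 100 000 nominal sample sizes (drives the direction test).

What the generator does **not** emulate: LD between instruments (clumping
is tested against explicit LD-matrix fixtures instead), winner's-curse
selection bias, sample overlap, allele-frequency differences between
ancestries, and infinitesimal polygenic background. Passing recovery tests
therefore demonstrate correctness of the estimators under their stated
assumptions, not robustness to everything real data can do.

The scenario suite fixes the canonical test grid: null effect (θ = 0) for
type-I error; the base config for bias/coverage; 40%-invalid directional
pleiotropy for median robustness; fully pleiotropic directional (mean
0.05) for Egger-intercept recovery; correlated pleiotropy for the InSIDE
violation; and a palindrome-rich config (50% palindromic, 30% strand
flips, 30% label swaps) for harmonisation recovery.

## Numerical choices and edge cases

* Bootstrap defaults: 1000 reps, explicit seeds everywhere; the recovery
  studies in the test suite and the acceptance script use 100 bootstrap
  reps per replicate, which changes estimated SEs by a few percent while
  keeping 500-replicate studies inside a minute.
* KDE grid: 1000 points; bandwidth floored at 1e-8; degenerate
  (all-identical) ratios return that value for any φ.
* Duplicate SNP ids in one table keep the smallest p-value (missing p
  sorts last, ties keep the earliest row) — the "strongest evidence"
  convention, mirroring clumping.
* Clumping ties (equal p-values) break lexicographically on SNP id for
  determinism; SNPs missing from the LD matrix are treated as independent
  with a logged warning; the position window applies only when positions
  are supplied.
* Floats are written with 12 significant digits so read∘write round-trips
  to better than 1e-9 relative error.
* β̂_X = 0 makes a Wald ratio undefined and is a hard error; collinear
  exposure effects after orientation make the Egger slope unidentifiable
  and raise.

## Known limitations

* The mode estimators' bootstrap SEs are conservative when the ratio
  spread is dominated by sampling noise: resampling around already-noisy
  ratios flattens the density, inflating the spread of the argmax by up to
  ~√2, so mode confidence intervals can over-cover (≈99% at nominal 95% in
  the no-pleiotropy recovery study). This is a property of the
  observation-centred parametric bootstrap the estimator convention
  prescribes; centring the bootstrap at the fitted mode would fix coverage
  under the null model but is anticonservative under pleiotropy, so the
  convention is kept.
* MR-Egger retains a small regression-dilution bias of order
  θ·(1 − I²_GX) (≈0.008 under the default generator); this is inherent to
  the estimator, not corrected (no SIMEX).
* The direction test's binary-trait variance-explained is approximate (see
  above).
* No multivariable MR, no outlier-removal estimators beyond the penalised
  median, no LD computation from genotypes, no remote data access.
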