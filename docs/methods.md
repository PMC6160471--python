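# Methods

## Model

Two-sample summary-statistic MR treats each genetic variant j as an
instrument for a lipid exposure.  With true per-SD exposure effects γ_j,
per-variant pleiotropic effects α_j on the outcome, and causal log-odds θ
per SD of exposure, the outcome association satisfies

    Γ_j = θ γ_j + α_j.

Observed effects are β_Xj ~ N(γ_j, σ_Xj²) and β_Yj ~ N(Γ_j, σ_Yj²), with
the two samples independent (exposure and outcome come from different
consortia).  Valid instruments have α_j = 0; every diagnostic in this
package exists to detect or tolerate departures from that assumption.
Estimates are reported on the log-odds-per-SD scale and exponentiated to
odds ratios only for presentation.

## Harmonization

Exposure effects are oriented to the lipid-increasing allele (negative
betas flip alleles, negate the effect and complement the frequency; the
operation is idempotent).  Outcome rows are matched to the exposure alleles
either directly or by swap (swap negates β_Y and complements its
frequency).  Exclusions, each recorded with a reason and reconciled so that
input = retained + excluded:

* `missing_in_outcome` — variant absent from the outcome table.  No proxy
  search is attempted; unavailable variants are excluded and logged.
* `multiallelic_conflict` — allele pair matches neither directly nor by
  swap.  Indel alleles are compared by exact string or swap only; no
  strand inference is attempted for them.
* `palindromic_ambiguous` — A/T or C/G pairs, where strand cannot be
  resolved from the alleles.  They are retained only when both study
  frequencies sit on the same side of 0.5 and each is at least
  0.5 − `maf_ambiguity_limit` away from it.  The default limit of 0.42 is
  the conventional cut in summary-statistic MR tooling: above that
  minor-allele frequency the frequency comparison itself becomes
  unreliable.
* `allele_mismatch` — |eaf_exposure − eaf_outcome| > `freq_tolerance`
  (default 0.20).  Cross-ancestry panels typically differ by far less;
  larger gaps usually mean a mis-keyed allele.  Both thresholds are
  configurable because no universally agreed values exist.

## Instrument selection

The comprehensive set takes every panel variant with target-lipid
P < 5×10⁻⁸; the restrictive set additionally drops variants with
P < 10⁻³ for either other lipid, trading instrument strength for
specificity.  Gene-region (cis) sets rank candidates by ascending
target-lipid p-value and greedily accept a candidate iff its squared
correlation with every previously accepted variant is below 0.4.  P-value
ties are broken by lexicographic rsid order so the selection is
deterministic.  The gene window (nominally gene ± 100 kb) is metadata
carried on the region specification: candidate lists are inputs, and the
window is never recomputed here.  The signed LD correlation matrix is kept
(not just r²) because the correlated-instrument estimators need the sign.

## Estimators

* **IVW** — zero-intercept weighted least squares with weights σ_Yj⁻².  The
  default standard error uses multiplicative random effects,
  φ = max(1, √(Q/(J−1))) with Q the first-order Cochran statistic at the
  estimate; this matches the convention of the standard MR software and
  reduces to the fixed-effect error when residual dispersion is at or
  below its expectation.  The fixed-effect model is selectable, and φ is
  always reported so either is recoverable.  A single instrument degrades
  to the Wald ratio with a warning.
* **MR-Egger** — the same regression with a free intercept; standard errors
  scale by φ = max(1, √(RSS_w/(J−2))).  The regression is only meaningful
  under the exposure-increasing orientation, so the operation refuses
  negative exposure betas rather than silently reorienting.
* **Weighted median** — per-variant ratios sorted ascending, weights equal
  to inverse first-order ratio variances (β_Xj/σ_Yj)², cumulative midpoint
  positions s_j = Σ_{i≤j} w_i − w_j/2, and linear interpolation at s = ½.
  Standard errors come from a parametric bootstrap (default 1000
  replicates) redrawing both β_X and β_Y from their sampling
  distributions; the bootstrap seed is mandatory, never implicit.
* **Correlated-instrument IVW/Egger** — generalized least squares with
  Ω_jk = σ_Yj σ_Yk ρ_jk.  A ridge of 10⁻¹⁰·mean(diag Ω) is added before
  factorization so that near-duplicate variants (ρ → 1) remain solvable
  without materially changing well-conditioned problems; the system is
  solved by Cholesky factorization, never an explicit inverse (the
  explicit-inverse solve is retained as an independent oracle in the test
  suite).  A covariance that is still not positive-definite raises an
  error advising stronger pruning.

Confidence intervals use the normal 0.975 quantile throughout, for
consistency across variant counts; p-values are two-sided normal.

## Heterogeneity and outliers

**Q′** minimizes Q(b) = Σ (β_Yj − b β_Xj)² / (σ_Yj² + b² σ_Xj²) exactly by
bounded scalar minimization (tolerance 10⁻¹⁰) on a bracket of ±10× the
fixed-effect IVW estimate, widened to a minimum half-width of 0.1 so a
near-zero IVW estimate still yields a proper bracket.  The second-order
denominator carries the exposure uncertainty, easing the no-measurement-
error assumption; as σ_X → 0 the statistic reduces to first-order Cochran
Q.  Reference distribution: χ² with J−1 degrees of freedom.

**MR-PRESSO** computes, per variant, the weighted squared residual about
the leave-one-out IVW slope; the global statistic is their sum.  Both
observed and simulated statistics use σ_Y⁻² weights — the weighting the
IVW regression framework implies (the original description leaves it
open).  Monte-Carlo replicates (default 1000, seeded) redraw β_X* from its
sampling distribution and β_Y* around the leave-one-out fitted value;
empirical p-values use the add-one correction and can never be exactly
zero.  The workflow runs the global test, and only if it is significant at
0.05 flags per-variant outliers at unadjusted p < 0.05 — the unadjusted
reading of the outlier threshold is the default, with a Bonferroni option
exposed — removes them, re-estimates IVW and retests heterogeneity with
Q′.  The distortion test of the broader MR-PRESSO framework is not
implemented.  Flagging every variant is an error (no stable regression
remains), as is running on fewer than four variants.

## Power

Binary-outcome power uses the normal approximation
se(θ̂) = 1/√(N·K·(1−K)·r²), with N the total outcome sample, K the case
fraction and r² the exposure variance explained by the instrument, giving
two-sided power Φ(|ln OR|/se − z_{1−α/2}) + Φ(−|ln OR|/se − z_{1−α/2}).
This is the standard parameterization of online MR power calculators; it
neglects exposure-side estimation error, which at the sample sizes modelled
here is a sub-percent effect (the acceptance suite measures the
analytic-versus-empirical gap directly).  The minimum detectable OR is
found by bisection on the log scale to 10⁻⁶; the protective counterpart is
its reciprocal.

## Synthetic data

The generator mimics the scale of the real inputs: exposure GWAS of
188,577 individuals, outcome GWAS of 122,977 cases and 105,974 controls.
Allele frequencies are uniform(0.05, 0.95); true exposure effects
γ_j ~ N(0.08, 0.03²) clipped positive (typical lead-variant per-SD effects
for lipids); standard errors follow the standard GWAS approximations
σ_X = 1/√(2p(1−p)N) and σ_Y = 1/√(2p(1−p)·N_eff) with
N_eff = N_cases·N_controls/(N_cases+N_controls).  Pleiotropy modes: none,
balanced N(0, s²), directional N(μ, s²), or a few spiked outliers sized in
units of the outcome standard error.  The multi-lipid panel plants
lipid-specific and explicitly shared variants (at consortium-scale
standard errors any true cross-lipid effect is detected at P < 10⁻³, so
sharing is planted through assignments rather than small loadings).  LD
blocks use an AR(1) correlation ρ_jk = decay^|j−k|, positive-definite by
construction, with observed effects drawn jointly under exactly that
covariance.

One integer seed drives everything through named Philox substreams, each
consuming a fixed number of draws per variant in variant order, so
enlarging a dataset extends streams without perturbing earlier draws, and
identical configuration gives byte-identical output files (readers use
round-trip float parsing for the same reason).

What the generator does **not** emulate: realistic allele-frequency
spectra, sample overlap between the two GWAS, winner's-curse selection of
instruments, fine-scale LD beyond AR(1), or assortative-mating and
population-structure artefacts.  Passing tests therefore certify the
estimators and diagnostics under their stated sampling model, not
robustness to those additional real-data pathologies.

## Problem sizes used by the tests and acceptance script

Calibration claims use 1000 Monte-Carlo replicates (IVW bias/coverage at
J = 44; Q′ and MR-PRESSO global type-I at J = 20 with 1000 resamples per
replicate); robustness claims use 200–300 replicates (Egger intercept
recovery, weighted-median corruption, outlier detection and false-positive
rates); power agreement uses 2000 replicates; the end-to-end study uses a
185-variant panel with five gene regions.  These sizes keep each Monte-
Carlo standard error several times smaller than the tolerance it certifies.

## Known limitations

* No multivariable MR, mode-based estimators, or individual-level methods.
* No proxy-variant substitution, liftover, VCF parsing or network LD
  lookup; LD matrices and candidate lists are file inputs.
* The decision flag ("agrees across methods, nominally significant IVW, no
  pleiotropy evidence") operationalizes agreement as identical sign across
  IVW/Egger/median plus overlap of the Egger and IVW confidence intervals;
  it marks rows and never filters them.
* The power module's r² must be supplied or computed by the caller; it is
  not estimated from summary statistics.
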