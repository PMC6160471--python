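# mrlipid

Two-sample Mendelian randomization (MR) of blood lipids — LDL-cholesterol,
HDL-cholesterol and triglycerides — and lipid-drug-target gene variants on
breast cancer risk, from GWAS summary statistics.

MR uses genetic variants as instrumental variables: because alleles are
randomized at conception, a variant robustly associated with a lipid trait
can probe whether the trait causally affects disease risk, free of the
confounding and reverse causation that plague observational lipid–cancer
studies.  `mrlipid` implements the complete summary-statistic workflow for
an analysis of this design — exposure effects from a lipid-consortium GWAS
(per-SD units, ~190k individuals), outcome effects from a breast-cancer
case-control GWAS (log-odds, ~229k women, with estrogen-receptor-positive
and -negative subtypes) — and a synthetic-data generator with known ground
truth so every stage is testable without the consortium data.

## What it does

Given per-variant association tables (rsid, alleles, frequency, beta, se, p):

1. **Harmonization** (`sumstats_io`) — orient exposure effects to the
   lipid-increasing allele, match outcome alleles directly or by swap,
   drop strand-ambiguous palindromic variants (A/T, C/G with minor-allele
   frequency above 0.42) and cross-study frequency inconsistencies, with a
   complete audit log.
2. **Instrument selection** (`instruments`) — *comprehensive* (all variants
   with target-lipid P < 5×10⁻⁸), *restrictive* (additionally requiring
   P ≥ 10⁻³ for both other lipids, a pleiotropy filter), and *cis
   gene-region* sets for drug-target genes (CETP, HMGCR, PCSK9, NPC1L1,
   LDLR) by greedy selection in order of increasing p-value subject to
   pairwise r² < 0.4.
3. **Causal estimation** (`mr_core`) — with exposure effects β_Xj (se σ_Xj)
   and outcome effects β_Yj (se σ_Yj) for J instruments:
   - **IVW**: θ̂ = Σ β_Xj β_Yj σ_Yj⁻² / Σ β_Xj² σ_Yj⁻², the zero-intercept
     weighted regression of β_Y on β_X; multiplicative random-effects
     standard errors scale by φ = max(1, √(Q/(J−1)));
   - **MR-Egger**: the same regression with a free intercept; the intercept
     estimates average directional pleiotropy and its test is the Egger
     intercept test;
   - **weighted median**: the 50% point of the inverse-variance-weighted
     distribution of per-variant ratios β_Yj/β_Xj, consistent while valid
     instruments carry ≥ 50% of weight; parametric-bootstrap CIs;
   - **correlated-instrument IVW/Egger**: generalized least squares with
     outcome covariance Ω_jk = σ_Yj σ_Yk ρ_jk for cis variants in LD ρ.
4. **Pleiotropy diagnostics** (`heterogeneity`) — the exact **Q′** statistic
   with modified second-order weights, Q(b) = Σ (β_Yj − b β_Xj)² / (σ_Yj² +
   b² σ_Xj²) minimized over b (relaxing the no-measurement-error
   assumption), and the **MR-PRESSO** resampling workflow: global residual-
   sum-of-squares test, per-variant outlier test, and remove-and-retest.
5. **Power** (`mr_power`) — binary-outcome MR power and minimum detectable
   OR from outcome sample size, case fraction and instrument r².
6. **Orchestration** (`pipeline`, CLI `mrlipid`) — the full study grid
   (3 lipids × 3 outcomes × selections × methods; 5 genes × 3 outcomes),
   with per-cell error isolation, TSV/JSON reports, and a decision flag for
   estimates that agree across methods, pass nominal IVW significance and
   show no pleiotropy evidence.

## Worked example

Estimate a causal effect from synthetic summary statistics generated with a
true odds ratio of 1.10 per SD (θ = ln 1.1) across 44 instruments at
consortium-scale sample sizes:

```python
import numpy as np
from mrlipid import (simulate_instruments, orient_to_increasing_allele, harmonize,
                     ivw, egger, weighted_median, q_prime, to_odds_ratio)

exposure, outcome, truth = simulate_instruments(J=44, theta=np.log(1.1), seed=7)
harmonized, log = harmonize(orient_to_increasing_allele(exposure), outcome)
print(f"retained {log.n_retained}/{log.n_input} instruments")
for est in (ivw(harmonized), egger(harmonized), weighted_median(harmonized, seed=7)):
    d = to_odds_ratio(est, decimals=2)
    print(f"{est.method:16s} OR {d['odds_ratio']:.2f} "
          f"(95% CI {d['ci_low']:.2f}-{d['ci_high']:.2f}), P = {est.pvalue:.3g}")
het = q_prime(harmonized)
print(f"Q' = {het.q_prime:.1f} on {het.df} df, P = {het.pvalue:.2f}")
```

```
retained 44/44 instruments
ivw              OR 1.09 (95% CI 1.06-1.11), P = 3.23e-11
egger            OR 1.06 (95% CI 0.99-1.14), P = 0.0972
weighted_median  OR 1.07 (95% CI 1.04-1.11), P = 9.25e-05
Q' = 32.5 on 43 df, P = 0.88
```

All three estimators recover the planted OR 1.10 within their confidence
intervals (Egger pays its usual precision penalty), and Q′ finds no excess
heterogeneity — as it should, since no pleiotropy was simulated.

A complete synthetic study (lipid panel, three outcomes, LD gene blocks,
ready-made config) and the power calculator are available from the shell:

```bash
mrlipid simulate --preset paper-scale --seed 1 --out study/
mrlipid run --config study/config.yaml
mrlipid power --n-outcome 228951 --case-fraction 0.537 --r2 0.03
# minimum detectable OR at 80% power: 1.0701 (protective: 0.9345)
```

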