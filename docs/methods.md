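# Methods

## The causal question and the estimators

The package estimates the causal effect of birth weight (BW) on type 2
diabetes (T2D) and glycemic traits using genetic variants as instrumental
variables. An instrument must (1) associate with BW, (2) be independent of
confounders of the BW–outcome relation, and (3) affect the outcome only
through BW. The package provides diagnostics for each: the instrument
F statistic and incremental R² for (1), a confounder screen regressing
each candidate confounder on the GRS for (2), and the MR-Egger intercept
test plus a pairwise-LD check (r² ≤ 0.05) for (3).

**Study-level arm.** Each cohort contributes three covariate-adjusted
regressions: linear GRS → BW (BW in SD units), logistic GRS → T2D, and an
observational logistic BW → T2D. Per-study coefficients are pooled by
inverse-variance meta-analysis; the DerSimonian–Laird moment estimator
supplies the between-study variance τ² for random effects (the default,
since heterogeneity with I² > 25 % is expected in multi-cohort data). The
causal estimate is the ratio of pooled coefficients,

    β_IV = β_ZY / β_ZX,   se(β_IV) = sqrt(se_ZY²/β_ZX² + β_ZY²·se_ZX²/β_ZX⁴),

refused outright when |β_ZX|/se_ZX < 1 (an uninformative denominator makes
the ratio meaningless). A second-order delta term is available behind a
flag; the first-order form is the conventional Wald-ratio SE.

**Summary-level arm.** With harmonized per-SNP statistics (β̂_Xj, σ_Xj,
β̂_Yj, σ_Yj):

* *Wald ratio*: β̂_Yj/β̂_Xj with SE σ_Yj/|β̂_Xj|.
* *IVW*: weighted regression of β̂_Y on β̂_X through the origin, weights
  1/σ_Yj². A single variant reduces exactly to its Wald ratio.
* *Simple / weighted median*: the 50th (weighted) percentile of the Wald
  ratios, interpolated on cumulative weights s_j = Σ_{i≤j} w′_i − w′_j/2;
  consistent when variants holding ≥ 50 % of the weight are valid. The SE
  is the SD of the estimator over parametric-bootstrap draws
  (β resampled from N(β̂, σ) on both sides, 10 000 draws by default, seed
  mandatory). The inverse-variance weight profile is computed once from
  the observed data and held fixed across bootstrap draws.
* *MR-Egger*: the same weighted regression with a free intercept, after
  re-orienting variants so β̂_Xj ≥ 0. The intercept estimates the average
  direct (pleiotropic) effect per exposure-raising allele; the slope is a
  pleiotropy-corrected causal estimate under the InSIDE assumption.
  Inference uses t with k−2 df.

IVW and Egger SEs use a **multiplicative random-effects** model by default:
the fixed-effect SE is scaled by max(1, √(RSS/df)). This is the
conservative standard in two-sample MR; the unscaled fixed-effect model is
kept as an option because the exact algebraic identities (single-variant
IVW ≡ Wald ratio; Egger through the origin ≡ IVW) hold at machine
precision only there.

**Reporting orientation.** Estimators are computed per 1-SD *increase* of
birth weight internally and negated on output so that results read per
1-SD *decrease*, the low-birth-weight convention; ORs are exponentiated
after negation. The Egger intercept is deliberately left on the
β̂_X ≥ 0 orientation regardless of the reporting flip.

**Units.** 1 SD of birth weight = 543 g everywhere; `bwmr.risk` holds the
gram↔SD conversions (and the trait-side constants such as 13.1 mg/dL per
SD of fasting glucose). The absolute risk increase per 1000
participant-years uses the rare-outcome form ARI = baseline × (OR − 1) by
default; because published eMethods formulas for ARI vary, the formula is
pluggable and every report echoes the formula and baseline used.

## The synthetic-data generator

`SimConfig` describes one study system; `simulate_cohort` and
`simulate_two_sample_summary` draw from it.

* Genotypes: independent Binomial(2, eaf) per SNP — no LD, matching the
  instrument-screening rule (all pairwise r² ≤ 0.05) rather than
  simplifying away anything testable.
* Birth weight: BW = Σ_j β_j g_j + b_C·C + ε, C ~ N(0,1),
  with the per-allele effects rescaled by one common factor so the
  instrument explains exactly `target_r2` of variance and ε chosen so the
  total variance is sd_bw² (543 g)². Infeasible combinations (genetic +
  confounder variance exceeding sd_bw²) raise an error naming the bound.
* T2D: logit P(D=1) = α + θ·(−BW/sd) + Σ_j γ_j g_j + c_C·C, with the
  intercept α solved numerically so the marginal prevalence matches
  `baseline_prevalence`. Direct effects γ are zero (`none`), N(0, σ_p²)
  (`balanced`) or N(μ_p, σ_p²) on a configurable fraction of SNPs
  (`directional`); γ is drawn once per study system and shared between
  cohorts, as befits a property of the SNPs.
* Two-sample structure: an exposure cohort (single-SNP linear regressions
  of BW in SD units) and an independent outcome cohort in which cases are
  oversampled from a large population draw to the configured case/control
  counts — retention sampling, which leaves the log-OR estimand intact —
  followed by single-SNP logistic regressions (vectorized Newton–Raphson
  across SNPs). Monomorphic or non-converged SNPs are flagged, never
  silently dropped.
* A quantitative "glycemic trait" shares the causal structure on a linear
  scale for the quantitative-outcome code path.

Key defaults, chosen once as realistic study conditions: baseline T2D
prevalence 0.08 (typical adult cohort prevalence); confounder effects
80 g and 0.10 log-OR per confounder SD (a modest shared antenatal/
lifestyle factor); birth-weight mean 3500 g; effect alleles oriented to
raise birth weight (the usual GWAS convention); allele frequencies swept
over 0.15–0.85 with a ranked-hit-list effect-size profile. The 7-SNP
panel targets R² = 1.52 % (upper end of the published 0.32–1.52 % range)
and the 43-SNP panel 2.0 %.

What the generator does **not** emulate: LD structure and proxy lookup,
imputation dosages, population stratification, maternal-genotype effects,
non-linear BW–T2D relations, and between-cohort covariate heterogeneity.
Passing tests therefore demonstrate correctness of the estimators under
the design's own assumptions, not robustness to those real-data
complications.

## Replicated experiments and their problem sizes

`bwmr.experiments` runs the built-in simulation studies; per-replicate
seeds derive from one base seed via `SeedSequence`. Sizes used by the test
suite, chosen as the design's stated conditions (recovery) or for
replicate throughput (calibration banks):

* Recovery: 200 replicates, 43 SNPs, exposure n = 50 000, outcome
  10 000/10 000, θ = 0.7.
* Null calibration: 500 replicates at θ = 0 with the design exposure size
  (50 000) and a 4 000/4 000 outcome arm; bootstrap 600 draws per median.
* Directional pleiotropy: 200 replicates, mean direct effect 0.02 log-OR;
  partial-validity ordering: 200 replicates with 40 % invalid instruments.
* Instrument strength: 100 cohorts of n = 5 000 at R² = 1.52 %.

## Numerical choices

* Meta-analysis: Q, I² = max(0, (Q−df)/Q)·100 and DL τ² computed from
  fixed-effect weights; k = 1 returns the single estimate flagged; flagged
  (non-converged) studies are excluded with counts reported.
* Logistic fits: per-study models via statsmodels with non-convergence
  and separation turned into flagged records (SE > 50 or non-converged);
  single-SNP fits via a clipped vectorized Newton solver (step clip ±5,
  tolerance 1e-10, 50 iterations).
* Weighted median ties: `np.interp` on the cumulative-weight positions
  averages across exact ties and clamps when one variant holds a majority
  of the weight.
* Palindromic SNPs (A/T, C/G) are resolved by allele frequency only when
  both sides are ≥ 0.08 from 0.5 (same side ⇒ aligned, opposite ⇒
  flipped), otherwise dropped with a report. Strand complements are tried
  before declaring an allele mismatch.
* Intercept solving for prevalence uses Brent's method on the sampled
  linear predictor (exact for the realized sample).

## Known limitations and honest calibration findings

Two deliberate "red" findings are kept visible in the statistical test
suite rather than hidden, because they are true properties of the
procedures as implemented:

1. **IVW recovery bias at the design size.** With a conditional logistic
   disease model at prevalence 0.08 and a 43-SNP instrument explaining
   2.0 % of variance at exposure n = 50 000 (per-SNP F ≈ 23), the mean IVW
   estimate of θ = 0.7 is ≈ 0.64: non-collapsibility of the odds ratio
   (marginal/conditional factor ≈ 0.96, verified by quadrature) times
   weak-instrument regression dilution (≈ F̄/(F̄+1) ≈ 0.96). The recovery
   test asserts the nominal ±0.05 band and fails by this structural
   ≈0.06 bias; CI coverage of the true θ remains ≈ 0.92–0.95.
2. **Simple-median CI over-coverage.** The parametric bootstrap spreads
   the ratio centers by the exposure-side noise, flattening the density at
   the median; the resulting SEs over-cover the null (≈ 0.99 at 500 null
   replicates against a 0.92–0.98 band). The weighted median, which
   downweights imprecise ratios, calibrates within the band, as do IVW
   and MR-Egger (intercept-test size ≈ 0.044–0.055).

Other limitations: the ratio estimator refuses weak denominators rather
than attempting weak-instrument-robust inference (no Fieller/AR
intervals); MR-PRESSO-style outlier removal, mode-based estimators,
multivariable and non-linear MR are out of scope; the ARI translation
assumes a rare outcome when equating OR with RR.
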