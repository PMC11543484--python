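# Methods

## The estimating equation and its companions

The package's core quantity is the estimated triglyceride content of
LDL,

    eLDL-TG = TG/38.5 + nonHDL-C/5.75 + 9.75·TG/nonHDL-C + 244/HDL-C − 2.95   (mg/dl),

a four-term closed form in the standard lipid panel. The functional
form encodes the physiology: LDL-TG rises with total TG and with the
atherogenic particle pool (nonHDL-C), the TG/nonHDL-C ratio captures
TG enrichment of apoB particles, and the reciprocal HDL-C term captures
the inverse relation between HDL and TG-rich lipoprotein remnants. The
published applicability domain is TG < 1,000 mg/dl and nonHDL-C <
400 mg/dl (strict inequalities: a value exactly at the bound is out of
range). Within the ratio/reciprocal terms, HDL-C ≤ 0 or nonHDL-C ≤ 0
makes the expression undefined; only then is no value returned.
Everywhere else the policy is *flag, don't censor*: out-of-domain rows
keep their computed value plus a machine-readable flag so cohort row
counts are preserved.

Companion markers computed alongside:

* **nonHDL-C** = TC − HDL-C.
* **LDL-C** by the Sampson/NIH equation
  `TC/0.948 − HDL-C/0.971 − (TG/8.56 + TG·nonHDL-C/2140 − TG²/16100) − 9.44`,
  flagged beyond its published TG < 800 mg/dl domain.
* **sdLDL-C** = LDL-C − lbLDL-C with
  `lbLDL-C = 1.43·LDL-C − 0.14·ln(TG)·LDL-C − 8.99`.
* **Rem-C** = nonHDL-C − LDL-C. Negative values are reported with an
  `IMPLAUSIBLE` flag, never clipped, so the identity
  Rem-C + LDL-C = nonHDL-C holds to machine precision.

### Units

All computation is in mg/dl because the equation coefficients are
stated on that scale; SI values are converted only at I/O edges, with
38.67 mg/dl per mmol/L for cholesterol-type analytes and 88.57 for
triglyceride-type. Display rounding is 2 decimals in mmol/L. These
standard molar factors reproduce the printed dual-unit pairs
160 → 4.14, 44.6 → 0.50 and 1000 → 11.3 (3 s.f.); two other printed
pairs in the source material (175 → 1.97, 400 → 10.36) are not exactly
consistent with any single factor (the standard factors give 1.98 and
10.34) and are treated as display rounding artifacts of the original.

## Classification rules

**Discordance quadrants.** Subjects are cross-classified by LDL-C and
eLDL-TG at cutpoints that default to the cohort's own medians (141 and
41 mg/dl in the motivating population). "High" means strictly greater
than the cut, so boundary values fall low; with continuous markers the
choice is immaterial, with rounded data it is stated and configurable.

**Risk-enhancer groups.** Positivity is `≥ cut` at LDL-C 160, TG 175
and eLDL-TG 44.6 mg/dl (the last configurable; it is an 80th-percentile
anchor, not a biological constant). Groups: A none positive, B LDL-C
only, C TG only, D eLDL-TG only, E eLDL-TG plus at least one other.
The eighth positivity pattern — LDL-C and TG positive with eLDL-TG
negative — belongs to no named group in the original five-group scheme;
it is labelled `BC_RESIDUAL` so the classification is total and the
original groups remain reconstructable. (With these cutpoints that cell
is sparsely populated, which is presumably why it went unnamed.)

**Quantile strata.** k-quantile strata use linearly interpolated
empirical quantiles (numpy's default, "type 7"); membership is by
half-open intervals (lo, hi], lowest closed. Ties share a stratum, so
stratum sizes can be unequal — documented behavior, not an error.

**PCE risk.** The pooled-cohort-equations 10-year ASCVD risk uses the
published race/sex-specific coefficients, kept in a versioned YAML file
rather than code so the transcription is auditable. Races other than
White/Black fall back to the White coefficients (the published
convention) and are flagged; ages outside 40–79 are scored but flagged.
The guideline's worked reference profile (55-year-old, TC 213, HDL-C 50,
SBP 120 untreated, nonsmoker, nondiabetic) computes to 5.38 / 6.07 /
2.05 / 3.03 % for White-male / Black-male / White-female / Black-female,
matching the published 5.3 / 6.1 / 2.1 / 3.0 % to printed rounding. A
`fixed_demographics` mode scores every subject as a 55-year-old White
male, isolating the lipid/BP contribution to the score.

## Equation development (refitting)

`fit_equation` mirrors the original development: a seeded random 50/50
train/validation split, OLS (unweighted, no robust loss — none was used
originally) on the design `[TG, nonHDL-C, TG/nonHDL-C, 1/HDL-C, 1]`,
R² on both halves. Rows with missing inputs or nonpositive denominators
are excluded and counted; the default TG fitting bound is 11,950 mg/dl,
the development data's stated maximum, and is configurable. Higher-order
terms are deliberately not offered. Rank deficiency raises an error
naming the collinear columns; a saturated fit (n = p) warns. Residual
diagnostics report banded residual SDs against TG or nonHDL-C, the
evidence from which applicability bounds are justified.

### Identifiability note

The design is intrinsically ill-conditioned: TG and TG/nonHDL-C are
strongly correlated, and 1/HDL-C varies little around its mean so its
coefficient trades off against the intercept. With noise at the
realistic level (population R² ≈ 0.61) and n = 20,000, the analytic OLS
standard errors under this package's default cohort are ≈ 10% of the TG
coefficient and ≈ 18% of the intercept. Individual-coefficient recovery
to a few percent is therefore not achievable at that sample size — only
the *fitted surface* (and R²) is stable. Tests assert coefficient
recovery within 3 standard errors, exact recovery (1e-8) in the
noiseless limit, and train/validation R² agreement within 0.02.

## Survival evaluation

* **Kaplan-Meier** product-limit curves (lifelines), starting at 1,
  right censoring handled; a sample with no events yields a flat curve
  and a warning.
* **Generalized Wilcoxon (Gehan-Breslow)** k-sample chi-square with
  weights equal to the number at risk, emphasizing early events — the
  "Wilcoxon chi-square" of the classic statistical packages. df = k − 1.
* **Cox proportional hazards** via partial likelihood with Efron tie
  handling (more accurate than Breslow with many ties); Wald 95% CIs on
  the log-HR scale. `standardize` z-scores chosen covariates so HRs
  read per 1-SD; threshold designs enter as indicator covariates.
  Two adjustment presets mirror common practice: the guideline nonlipid
  set (age, sex, race, SBP, BP treatment, diabetes, smoking) and the
  same plus BMI.
* **ROC AUC** for a single marker equals the Mann-Whitney concordance
  (ties count half); a single-marker logistic fit is a monotone
  transform and cannot change it — both equivalences are asserted in
  tests rather than assumed.
* **`marker_battery`** runs the ranking design: each marker cut into
  quintiles, survival across strata scored by the Wilcoxon chi-square,
  plus the marker's AUC; markers are ranked by chi-square and
  per-marker failures are reported in-table rather than aborting.
* No multiplicity correction is applied to battery rankings (the design
  reports raw orderings); no competing risks or time-varying covariates.

## Synthetic cohorts

The generator exists so every analysis above is exercisable without
restricted cohort data. It emulates:

1. **Lipid marginals and dependence.** A Gaussian copula over
   (log TG, TC, HDL-C) with correlations (logTG–TC 0.30,
   logTG–HDL −0.45, TC–HDL 0.15); TG is log-normal (median 130 mg/dl,
   log-SD 0.55), TC ≈ N(227.6, 41.0), HDL-C ≈ N(57.0, 14.7). The
   location/scale defaults were obtained once by pooling published
   quadrant-level summary statistics of a large primary-prevention
   cohort (size-weighted means and variances); the correlations are
   field-plausible choices reproducing the negative TG–HDL-C dependence
   visible across those quadrants. Rows with HDL-C or nonHDL-C below
   5 mg/dl are rejected and resampled so all derived terms are defined.
2. **A reference-method LDL-TG** equal to the equation's prediction
   plus Gaussian noise whose SD is set from the generated cohort's own
   signal variance so the population R² equals a target (default 0.609,
   the equation's published fit; 1.0 gives the noiseless loop-closure
   case).
3. **Outcomes.** Exponential event times with log-hazard linear in the
   standardized marker (default HR 1.24 per 1-SD) or in a threshold
   indicator (default HR 1.32), administrative censoring at a 14-year
   horizon, and optional additional uniform censoring solved by
   bisection on the realized sample to land within 2% of a requested
   censoring fraction (unattainable requests raise). The default
   baseline hazard of 0.016/year gives ≈ 20% cumulative events over the
   horizon — chosen to make recovery designs well-powered at desk
   scale; real primary-prevention incidence is lower.
4. **Demographics** (age, sex, race, SBP, treatment/diabetes/smoking,
   BMI) are drawn independently of the lipids and the hazard. That
   independence is a deliberate simplification: adjustment can then
   never explain away a generated marker effect, which makes recovery
   tests clean but means the generator does not reproduce confounding
   structure present in real cohorts.

One integer seed drives everything through numpy `SeedSequence`
spawning, one child stream per stage, so cohorts are byte-reproducible.

### What passing tests do and do not show

The generator's lipids are unimodal and its hazards exactly
proportional; real cohorts have assay rounding, mixed dyslipidemias,
medication effects, non-proportional hazards and confounded
demographics. Green tests therefore demonstrate that the estimators and
procedures are implemented correctly and recover known truth under the
stated model — not that any particular cohort-level effect size will
replicate in real data.

## Problem sizes and tolerances

Test and report sizes are chosen as desk-scale analogues of the
original designs: refits at n = 20,000 (the original training-half
size), hazard-recovery replicates at n = 4,000 × 100 with ≈ 20% events,
null calibration at 1,000 replicates. Numerical tolerances: equation
arithmetic 1e-3 mg/dl against hand oracles; noiseless refit 1e-8;
AUC/concordance equivalence 1e-12; unit round-trips 1e-12 relative;
Monte-Carlo assertions use 3-SE bands or the explicit coverage /
calibration bounds stated in the tests.
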