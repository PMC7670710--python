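# Methods

## Scope and model

`harmdw` implements an indirect-elicitation framework for the health
impact of gambling problems. The object of estimation is a disability
weight (DW) for each at-risk PGSI category — low-risk (LR), moderate-risk
(MR) and problem gambler (PG) — net of the psychiatric comorbidity that
travels with gambling problems, plus the machinery around it: DW algebra,
a condition registry with relative risks, a generative model for
synthetic study populations, propensity-score adjustment, and YLD
aggregation.

Comorbidity is handled multiplicatively throughout: health-state
valuations (HSV = 1 − DW) of co-occurring conditions multiply, so
`DW_[1,n] = 1 − ∏(1 − DW_j)`. The combined weight always lies between
the largest component and the capped sum of components. The package does
not implement super-additive ("exacerbating") combinations: no functional
form for them is established, so only the multiplicative model is
offered. The Mathers-style adjustment (`adjust_milder_weight`) derives
composite-consistent individual weights by leaving the more severe weight
unchanged and assigning the milder condition the composite minus the
severe weight, i.e. `m(1 − s)`.

## Condition registry

`data/comorbidity_registry.csv` encodes 40 psychiatric conditions with
(a) pooled prevalence among treatment-seeking problem/pathological
gamblers with a 95% CI, (b) an optional second prevalence from community
samples of problem gamblers, (c) the general-population prevalence with
an SE or 95% CI, (d) published DW severity levels (scalar or range), and
(e) the published relative risk and SE for cross-checking. Percentages
are stored verbatim and converted to proportions once, at load time.

Relative risk is `f = A/B` (prevalence among problem gamblers over
community prevalence) with a first-order delta-method standard error

    σ_f ≈ |f| √((σ_A/A)² + (σ_B/B)² − 2σ_AB/(AB)),  σ_AB = 0.

Where only a 95% CI is published, the SE is recovered assuming a
symmetric normal interval (half-width / 1.959964). This convention
reproduces the published SEs (0.60, 0.81, 0.65, 3.31, 3.54, 14.83,
2.12, …) to 2 decimal places for every row whose published RR equals the
prevalence ratio. Ten rows (e.g. nicotine dependence, major depressive
disorder, GAD, antisocial personality disorder) publish RRs that cannot
be derived from the tabulated prevalences — evidently pooled across
sources in an undocumented way — and are flagged `rr_unverified` rather
than guessed at; they are excluded from exact-reproduction tests. Ranged
DWs (e.g. 0.12–0.60 for OCD) are stored as ranges; when a scalar is
required the midpoint is used and the choice is visible in
`ConditionRecord.scalar_dw`.

## Synthetic populations

The generator defines the study conditions for all estimator validation.
Defaults:

- **Size / categories.** n = 20,000; marginal PGSI prevalences
  NP 90%, LR 6%, MR 3%, PG 1%. Category DWs LR 0.14, MR 0.29, PG 0.46 —
  the published Australian direct-elicitation values.
- **Risk factors.** Age (truncated normal, mean 46, SD 17, ≥ 18), gender,
  employment (62/5/33), income quintile, education (4 levels), marital
  status, standard-normal trait impulsivity, childhood gambling exposure
  (15%), venue distance (exponential, mean 8 km), urbanicity (70/20/10),
  minority home language (20%). Factors are drawn independently — a known
  simplification; real risk factors are correlated, which makes matching
  *easier* here than in field data.
- **Category assignment.** Ordered logit on an encoded covariate vector.
  The literature reports directions but not effect sizes, so the default
  coefficients (impulsivity +0.6, male +0.5, unemployment +0.6, younger
  age, lower income/education, single/divorced, childhood exposure,
  venue proximity, metro residence, minority language — see
  `DEFAULT_PROPENSITY_COEFFICIENTS`) are package choices with the
  documented signs. Cutpoints are solved numerically so the *average*
  category probabilities equal the configured marginals regardless of
  coefficient scale.
- **Comorbidity.** Eight conditions are modelled by default: the seven
  registry rows with verifiable RRs (alcohol abuse, alcohol dependence,
  dysthymic, panic, psychotic, adjustment disorder, paranoid personality
  disorder) plus cannabis use disorder. For condition c with community
  prevalence p and PG relative risk R, P(c | PG) = min(1, R·p); LR and MR
  receive interpolated relative risks 1 + 0.25(R − 1) and 1 + 0.5(R − 1)
  (configurable fractions, not empirical claims); the non-problem
  prevalence is solved so the population marginal equals p. On top of the
  category-conditional mean, individual log-odds are tilted by
  `confounding_strength × impulsivity` (default 0.5 per SD) and recentred
  per category by root-finding so conditional means are preserved — this
  creates genuine confounding for the estimator to defeat without
  breaking calibration. Adjustment disorder (R = 30.7) is infeasible
  under these marginals (the implied non-gambler prevalence is negative);
  it is clipped at zero with a logged warning and excluded from
  realized-RR checks.
- **Simulation condition DWs.** Mean of published severity midpoints
  where the registry prints levels (alcohol-use-disorder levels stand in
  for abuse 0.235 and dependence 0.373); package defaults where nothing
  is printed: adjustment disorder 0.15 (beside somatoform 0.144 and mild
  depression 0.145), paranoid personality disorder 0.193 (the borderline
  PD value, the only published PD weight).
- **HSV.** Latent HSV is the product of complements over the category
  weight and present-condition weights — the multiplicative model applied
  uniformly, including to the gambling condition itself. Non-problem and
  low-risk gamblers can receive a recreational uplift (1 + benefit);
  the magnitude of positive wellbeing contributions is unquantified, so
  `benefit_uplift` defaults to 0. Observed HSV multiplies the latent
  value by mean-one lognormal noise exp(ε), ε ~ N(−σ²/2, σ), σ = 0.2,
  then clips to [10⁻⁶, 1]. An additive truncated-normal noise option
  exists for robustness experiments. All randomness flows from one seeded
  generator; identical config + seed gives byte-identical outputs.

What the generator does *not* emulate: correlated risk factors,
measurement error in condition diagnoses, informative non-response,
condition–condition dependence beyond the shared category/impulsivity
pathways, and any longitudinal dynamics. Passing recovery tests therefore
show the estimator is correct under its assumed data-generating process,
not that field estimates would be unbiased.

## Propensity adjustment

`PropensityMatcher` fits a logistic model of case membership (each
at-risk category versus NP controls, estimated separately per category)
on the same encoded covariates the generator uses. Greedy 1:1
nearest-neighbour matching runs on the logit score, without replacement,
cases in descending score order, within a caliper of 0.2 SD of the logit
score; ties break toward the earlier record; unmatched cases are counted
in the result, never silently dropped. ATT weighting gives controls
score/(1 − score), truncated at the 99th percentile (logged; on default
simulations truncation removes < 5% of control weight mass). Balance is
reported as absolute standardized mean differences using the pooled SD of
the *unadjusted* groups; `max SMD < 0.1` is the package's reporting
convention for adequacy, not a hard threshold. A degenerate caliper
returns an all-unmatched report from `match_nearest`; a fit that yields
zero usable pairs raises.

## Estimators and the ceiling

The default log-linear estimator regresses log HSV (floored at 10⁻⁶) on a
case indicator plus condition indicators, weighted by the matching or ATT
weights, and reads DW = 1 − exp(β). Self-rated valuations cannot exceed
full health, and with mean-one multiplicative noise nearly half of
fully-healthy controls sit exactly at HSV = 1; treating the ceiling as
ordinary data drags the control group's mean log HSV downward and
attenuates every weight by ~0.04. Observations at HSV = 1 are therefore
treated as right-censored and the model is fitted by weighted
censored-normal (Tobit) maximum likelihood (L-BFGS-B on an analytic
gradient, WLS start). Plain weighted least squares remains available
(`censor_ceiling=False`); on noiseless data nothing is stochastically
censored and WLS reproduces the coefficients to machine precision, which
is what the exact oracle tests use. If the WLS residual scale is below
10⁻¹⁰ the censored fit short-circuits to WLS (degenerate noiseless
likelihood).

The additive estimator fits HSV itself on category, condition and
category × condition interaction terms (the multiplicative discount
appears as a positive interaction a·b), with the analogous censoring at
HSV = 1. Its normal error model is misspecified under multiplicative
noise and sits ~0.03 low at the default σ; it is shipped as the verbal
"interaction" formulation and as a robustness check, not the default.
Interaction columns that are exactly collinear with main effects (a
condition occurring in only one arm) are dropped with a warning and
recorded in `dropped_terms_`; collinear main effects raise. Condition
main effects are re-estimated by default; `fixed_condition_dws` moves
known weights into an offset instead.

Uncertainty: nonparametric case-resampling bootstrap (cases and NP
controls resampled independently), re-running propensity fit, matching
and the causal model in every replicate so matching uncertainty is
propagated; percentile 95% intervals, b = 500 by default (minimum 100),
seeded; more than 5% failed replicates aborts with diagnostics.
`counterfactual_hsv` reports the mean predicted HSV for cases with the
category indicator switched off, conditions held fixed, beside the
observed case mean.

Bias in validation experiments is measured on the signed (unclipped)
estimate; reported `dw` values are clipped to [0, 1] with the clip
recorded, since clipping at zero would otherwise inflate apparent bias in
null scenarios.

## Burden

YLD = prevalence × DW × population. Category weights from the pipeline
are already net of comorbidity, so no further scaling is applied. The
report flags whether LR + MR aggregate YLD exceeds PG YLD. Category
prevalences for a jurisdiction are user inputs. YLL and DALY fields are
reserved and left empty — no mortality inputs are modelled.

## Validation sizes and numerical choices

- Parameter recovery: 200 seeded populations of n = 20,000 at default
  noise and confounding; observed mean bias per category ≲ 0.001–0.002,
  RMSE ≈ 0.005–0.015 (PG is the noisiest: ~200 cases per population).
- Null recovery: 50 seeds with all category DWs 0; confounding-reduction
  check: 30 seeds comparing the unadjusted log-scale group difference
  (upward-biased by ~0.13) against the full pipeline.
- The acceptance script uses 50 seeds at n = 20,000 — enough for a
  Monte-Carlo SE of ~0.002 on the PG mean.
- Tolerances: exact algebraic identities at 10⁻¹⁰–10⁻¹²; stochastic
  checks at 3–5 σ of their Monte-Carlo noise; root-finding (category
  cutpoints, confounding recentring) via Brent's method at xtol 10⁻¹².
- Degenerate inputs: empty condition lists are full health; zero noise is
  allowed (exact simulations); category prevalences of 0 or 1 map to
  infinite cutpoints; zero-variance covariates are flagged with SMD 0.

## Known limitations

- The recovered weights inherit the multiplicative model; if real
  comorbidity interactions are super-additive the framework
  under-corrects by construction.
- Matching assumes the propensity covariates capture confounding; the
  simulation satisfies this by design (same encoding on both sides), so
  tests cannot detect omitted-confounder bias.
- The additive estimator's ceiling correction is approximate under
  multiplicative noise.
- Registry rows with unverifiable published RRs are flagged and excluded
  from calibration rather than reconciled.
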