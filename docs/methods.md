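# Methods

This note records the statistical model the package implements, the
conventions and numerical choices that were genuinely open, the design of the
synthetic-data generator, and what the test suite does and does not
demonstrate.

## The oxidative balance score

The OBS is a composite of 20 exposures, each scored 0–2 and summed. The
packaged scheme has 16 dietary components (fiber, carotene, riboflavin,
niacin, vitamin B6, total folate, vitamin B12, vitamin C, vitamin E, calcium,
magnesium, zinc, copper, selenium as antioxidants; total fat and iron as
prooxidants) and 4 lifestyle components (physical activity as antioxidant;
alcohol, BMI and serum cotinine as prooxidants) — 15 antioxidants and 5
prooxidants in total. Intakes are per-day amounts from a 24-hour recall and
exclude supplements; cotinine proxies both active and passive smoking.

Scoring rules:

* **Tertile components.** Within each sex a component has boundaries
  (t₁, t₂). Groups are half-open: value < t₁ → low, t₁ ≤ value < t₂ →
  middle, value ≥ t₂ → high, so a value exactly at a boundary belongs to the
  upper adjacent group. Antioxidants score (0, 1, 2) across the groups,
  prooxidants (2, 1, 0). Boundaries are always stored ascending; polarity
  alone decides the direction of points. (Published boundary tables for
  prooxidant rows sometimes print the inequality signs in score order rather
  than value order; storing ascending values and deriving direction from
  polarity resolves this unambiguously.)
* **Alcohol.** Fixed thresholds instead of tertiles: exactly 0 g/d scores 2;
  below the heavy-drinking threshold (30 g/d men, 15 g/d women) scores 1; at
  or above it scores 0.

The dietary sub-score (0–32) excludes exactly the four lifestyle variables;
the lifestyle sub-score (0–8) contains only them; their sum is the total by
construction.

### Quantile convention

All empirical quantiles in the package — tertile boundaries, OBS quartile
cuts, weighted medians in descriptive tables — use one definition: **the cut
at probability p is the smallest observed value whose cumulative normalized
weight strictly exceeds p** (equal weights when none are given). Combined
with the half-open grouping this splits evenly divisible unweighted data into
exactly equal groups (values 1…9 give tertile boundaries (4, 7); OBS values
1…8 give quartiles of size two) and sends boundary ties to the upper group.
The strict inequality is deliberate: with "≥" a cumulative share landing
exactly on p (e.g. 3 of 9 values at p = ⅓) would close the lower group one
value early and produce systematically unbalanced groups. A relative
tolerance of 1e−12 on the comparison keeps exact rational ties (⅓, ⅔) stable
in floating point.

Degenerate distributions (fewer than 3 distinct values for tertiles, 4 for
quartiles, or ties so heavy that cuts coincide) raise an error rather than
silently produce collapsed groups.

### Packaged boundaries

The default `CutpointSet` ships inside the package as YAML
(`data/obs_schema.yaml`) so scoring requires no downloads; it is tagged
`packaged_table1` provenance and round-trips exactly through the config
reader/writer. Whether such published boundaries were derived weighted or
unweighted is generally not reported; the packaged values are treated as
given constants. For any other cohort (including all synthetic ones)
`compute_cutpoints` recomputes sex-specific boundaries from the data —
unweighted by default, optionally survey-weighted.

## Cohort exclusions

Five steps in a fixed order: (1) missing any schema component or model
covariate; (2) age outside 20–84 (ages ≥85 are top-coded in the emulated
surveys, and the analytic population is adults); (3) pregnancy; (4) dietary
recall below minimum quality; (5) implausible energy intake, men <800 or
>4200 kcal/d, women <500 or >3500 kcal/d — **exclusive** bounds, a value
exactly at a bound is retained. A row violating several criteria is charged
to the first violated step, matching sequential flowchart semantics; whether
the source surveys applied the criteria jointly or sequentially is not
knowable from published flowcharts, so the sequential reading is adopted and
the step order is part of the documented contract. The pipeline is
idempotent, and the missingness column list is configurable.

## Telomere replicate QC

Inputs are already T/S ratios (telomere repeat copies relative to a
single-copy gene); no PCR-efficiency modelling is done. Per sample
(nominally six wells over three days, ≥3 required): the largest and smallest
values are *potential* outliers; the mean m of the interior values is taken;
a potential outlier v is excluded iff |log(m/v)| > 0.4. Two open readings
are made explicit and configurable:

* **Log base.** The threshold's base is unstated in assay descriptions;
  symmetric ratio criteria conventionally use the natural log, so that is
  the default (`log_base=None`), with any base available.
* **Restoration.** Whether a potential outlier that passes the test
  re-enters the final mean is implied but not explicit; the default restores
  it (`restore_passing=True`); the stricter interior-only mean is available.

At most two values can ever be excluded per sample, the returned mean is
scale-equivariant and lies within the retained range, and all-equal
replicates short-circuit (no candidates). Run-level rules: a run is dropped
when it has ≥8 invalid control wells or when **more than** 4 control DNA
values fall outside the across-run mean ± 2.5 SD (exactly 4 is retained;
values exactly on the band edge are inside).

## Design-based estimation

Point estimates are weighted least squares with the analysis weights (the
4-year examination-center weights in the emulated design). The covariance is
Taylor linearization over between-PSU variation of weighted score totals
z_hj = Σ_{i∈PSU hj} w_i x_i e_i:

    G = Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)(z_hj − z̄_h)'
    V(β̂) = (X'WX)⁻¹ G (X'WX)⁻¹

with design degrees of freedom df = #PSUs − #strata; intervals and p-values
use the t distribution on df. With one stratum and each observation its own
PSU this reduces to the classic HC0 sandwich times n/(n−1) (score totals sum
to zero when an intercept is present), which the tests verify against an
independently coded loop oracle. Numerical choices: X'WX with condition
number above 1e12 raises a collinearity error; strata with a single PSU
raise an error by default (`lonely_psu="error"`), with an optional
conservative fallback that centres the lonely PSU's score total at the grand
mean across all PSUs — masked-variance public-use designs guarantee ≥2 PSUs
per stratum, so the error default protects against malformed inputs rather
than a real analysis case.

Weighted descriptives report the weighted mean with the population-form
weighted SD (denominator Σw), weighted median/quartiles under the package
quantile convention, and unweighted counts with weighted percentages for
categories. No Rao–Scott or Kruskal–Wallis tests are computed for baseline
tables: those are descriptive displays here.

## The study models

Outcome: natural log of the T/S ratio (ln, not log10 — the scale of
published log-LTL summaries, mean ≈ 0.03–0.05 with SD ≈ 0.24, is consistent
only with the natural log). Four strictly nested covariate models:
1 crude; 2 + age, ethnicity, education, PIR; 3 + dietary energy; 4 + CRP.
Encodings: age, energy and CRP continuous (age continuous is an assumption —
category treatment is not stated in the emulated analyses; CRP enters
untransformed); ethnicity 5 categories referenced on non-Hispanic white;
education 5 ordered categories; PIR 3 categories (≤1.3 / 1.3–3.5 / >3.5).
All analyses are run separately by sex (separate fits, not interaction
terms). The OBS enters (a) continuously and (b) as sex-specific quartiles
with Q1 reference plus a trend term: the quartile's ordinal index 1–4
entered as a single continuous covariate (default), or per-quartile median
score coding as an option. Quartiles are sex-specific by default
(configurable), matching the sub-population descriptive tables the design
emulates.

Leave-one-component-out sensitivity removes each of the 20 components in
turn, recomputes the reduced score by summation (range 0–38, deliberately
not renormalized — the comparison is between continuous-score slopes), and
refits the full model per sex: 40 rows.

## The synthetic cohort generator

The generator exists to give every stage a testable input with known ground
truth; its defaults are the conditions under which the package's statistical
guarantees are stated.

* **Design.** H = 14 strata × 2 PSUs (defaults), n = 1600, participants
  allocated evenly across strata. Weights are inverse inclusion
  probabilities varying by stratum (0.5–0.9) and age band (×1.25 under 40,
  ×1.0 for 40–59, ×0.7 for 60+), so weighted and unweighted estimands differ
  and the design machinery is genuinely exercised.
* **Exposures.** Each tertile component is log-normal per sex with (μ, σ)
  chosen so its theoretical tertiles equal the packaged boundaries (μ the
  mean of the log boundaries, σ their log-distance over twice the standard
  normal ⅔-quantile 0.4307). Dietary intakes share a correlation of 0.45
  with energy on the latent normal scale; energy itself is truncated normal
  per sex (men 2477 ± 781, women 1818 ± 622 kcal/d, truncated inside the
  plausibility bounds so clean rows never trip the energy filter). Alcohol
  is zero-inflated (40% male / 55% female nondrinkers, log-normal amounts
  among drinkers); cotinine has a 10% point mass at zero over a heavy-tailed
  log-normal. Demographic covariates are categorical draws with frequencies
  typical of a US adult examination sample; CRP is log-normal around
  0.17 mg/dL.
* **Outcome.** ln(T/S) = α_sex + β_sex·OBS + γ_age·age + N(0, σ) with
  defaults β_female = 0.004, β_male = 0, γ_age = −0.002/year, σ = 0.24
  (matching the observed dispersion of log T/S in adult samples), and
  intercepts (0.13 men, 0.05 women) placing mean ln(T/S) near 0.03. The OBS
  in the outcome model is computed by the package's own scorer with tertiles
  recomputed from the generated sample — exactly what the analysis pipeline
  will recompute, so recovery tests measure estimation error, not scorer
  mismatch.
* **Planted violations.** Extra rows cloned from clean participants, each
  carrying exactly one exclusion violation, appended with fresh ids and
  recorded in the ground truth; the clean cohort passes the filter
  untouched, so planted counts are recovered exactly.
* **Replicate sets.** Per sample: a log-normal base T/S times multiplicative
  well noise with CV 6.5% (the typical interassay CV of the emulated assay);
  a planted outlier multiplies one well by a factor (default 2.0, whose log
  0.693 clears the 0.4 threshold with margin; factor 1.1, log 0.095, is the
  designed negative control).

What the generator does **not** emulate: joint intake correlations beyond
the shared energy factor, the bimodal smoker/nonsmoker structure of
cotinine, item nonresponse patterns, clustering of outcomes within PSUs
(outcome errors are i.i.d., so design effects come from weighting alone),
or calibration/nonresponse adjustment of weights. Passing tests therefore
demonstrate the correctness of the scoring arithmetic, filter semantics, QC
rules and design-based variance machinery on a faithful survey *structure* —
not that real-survey estimates would be unbiased under misspecification.

## Verification sizes and guarantees

The simulation-backed checks run at sizes chosen to make their Monte-Carlo
error meaningful while staying desk-scale: planted-effect recovery uses 400
replicates of the default n = 1600 cohort (mean estimate within 10% of
β_female = 0.004; empirical 95% CI coverage within [0.93, 0.97], a band
whose MC standard error at 400 replicates is ≈1.1 points); the p-for-trend
type-I check uses 500 null replicates at n = 800, H = 8, asserting the
rejection rate within three binomial standard errors of 0.05. Both bands
were fixed before running. The linearization covariance is required to match
a loop-coded oracle to 1e−10 relative tolerance on a fixed n = 12 design.

## Known limitations

* The packaged boundary table applies to the population it was derived from;
  for any other cohort, recompute cutpoints.
* Quartile cuts on a discrete 0–40 score can be degenerate in small or
  homogeneous samples; the package raises rather than merging groups.
* The linearization assumes with-replacement first-stage sampling (no finite
  population correction), the standard public-use-survey convention.
* Sub-score models inherit the total-score component weights (every
  component counts equally); no reweighting or standardization of
  components is attempted.
* The CRP covariate enters untransformed despite skewness; this mirrors the
  emulated analysis but is worth revisiting for real applications.
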