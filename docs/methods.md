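# Methods

## Scope and data model

`metsev` analyses one baseline visit of an older cohort (men 55–75, women
60–75 years) with overweight/obesity (BMI in [27, 40)) and at least three
harmonized metabolic-syndrome criteria. A cohort is one wide subject table
(demographics, anthropometry, triplicate-averaged blood pressure, fasting
biochemistry, medication flags, sitting-time categories, sleep, chair-stand
repetitions) plus long-format companions keyed by `subject_id`: FFQ
responses, activity records, BDI-II items, and an optional supplement
table. All tables travel as delimited text; canonical internal units are
mg/dL for lipids and glucose, cm, kg, mmHg and MET·min/day, with declared
unit conversions (e.g. mmol/L × 38.67 for cholesterol fractions, × 88.57
for triglycerides) applied and logged at load.

## Severity score (MetSSS)

The published severity score's exact coefficients live in a separate
validation paper and are not reproduced here; `metsev` implements the
score's *contract*: per component the standardised exceedance above the
clinical threshold, truncated at zero,

h_i = max(0, d_i (x_i − t_i)/s_i),

summed by default (a Euclidean option exists). This satisfies the defining
properties — zero exactly when every component is at/below threshold in the
risk direction, monotone non-decreasing in each risk direction, HDL
contributing when *below* threshold — while thresholds, scales, aggregation
and a medication rule are configuration. Defaults: harmonized thresholds
(WC 102/88 cm men/women, TAG 150 mg/dL, HDL 40/50 mg/dL, BP 130/85 mmHg,
glucose 100 mg/dL) and scales equal to round population SDs (9 cm, 60, 11,
16, 9.5, 28 in component units). Medication does not enter the score by
default (it does enter the MetS component *flags*, where drug treatment
counts as meeting the criterion); a `medication_rule="threshold"` switch
treats treated components as at least at threshold. Because the scales are
package defaults, absolute score values and tertile cut-points are not
comparable to the published instrument's 2.7/4.0 — tertile *membership*, the
analysis's actual stratifier, is scale-invariant within any monotone
re-calibration of a single component set.

Tertiles are cut at the empirical 1/3 and 2/3 quantiles using the
inverted-CDF (type-1) convention, so cut-points are observed values and the
inclusive-left rule (T1 ≤ q1 < T2 ≤ q2 < T3) gives deterministic group
sizes under ties.

## Dietary layer

**Frequency conversion.** The nine FFQ categories map to servings/day via
interval midpoints: never = 0, 1–3/month = 2/30.4, 1/week = 1/7, 2–4/week =
3/7, 5–6/week = 5.5/7, 1/day = 1, 2–3/day = 2.5, 4–6/day = 5, ≥6/day = 6.
Full precision is used in every computation; the two-decimal *truncating*
formatter (`paper_format`, 5.5/7 → "0.78") exists only because printed FFQ
conventions truncate rather than round.

**Nutrient profiles.** intake_i = Σ_items servings/day × per-portion
content_i, plus declared supplement vectors. Percent-of-energy uses 4 kcal/g
for carbohydrate and protein, 9 for fat, 7 for alcohol. Glycaemic index is
the carbohydrate-weighted mean of per-item GI values.

**Energy filter.** Exclusion iff intake is strictly outside [500, 3500]
kcal/d (women) or [800, 4000] (men); boundaries are kept. The filter is
idempotent and order-independent of the other stages.

**MD-17.** The 17 Mediterranean-diet items are not enumerated in baseline
reports; the default criteria operationalise the published PREDIMED-Plus
style screener as 0/1 predicates over food-group intakes (olive oil as main
fat and ≥4 tbsp/d, ≥2 vegetable and ≥3 fruit servings/d, limits on
red/processed meat, butter/cream, sugary drinks, pastries, snacks and
spirits, minimum legumes/fish/nuts/sofrito frequencies, white-meat and
whole-grain preference, daily wine). They ship as an editable structure;
analyses of real questionnaire data should substitute the instrument's own
item definitions.

**DII.** For each of the 30 food parameters, z = (intake − mean)/SD against
a reference table, centred percentile c = 2Φ(z) − 1 ∈ (−1, 1), DII =
Σ c_j · effect_j. The standard-normal CDF is used as the percentile map (an
`empirical` within-sample mode exists); whole-food parameters (garlic, tea,
onion) read dedicated food-group intakes. The default table's reference
means/SDs are package choices plausible for an older Mediterranean
population — *not* the global reference database, which is licensed — with
effect-score signs and magnitudes following the conventional
pro-/anti-inflammatory classification. |DII| is therefore bounded by
Σ|effect_j| ≈ 8.3, and adding k·SD to a positively-scored parameter moves
its contribution by effect·(2Φ(z+k) − 2Φ(z)).

## Activity layer

MET·min/week = MET score × min/day × days/week; daily = weekly/7. Intensity
classes: light < 4.0 MET, vigorous ≥ 6.0; the printed convention (4–5.5 for
moderate) leaves (5.5, 6.0) unassigned, so moderate is implemented as
[4.0, 6.0) to make the classes a partition honouring both printed
boundaries. Total-PA outliers are flagged at |x − mean| ≥ 3 SD within
sex × 5-year age-band strata ({55–59, 60–64, 65–69, 70–75}), computed once
on pre-filter data; constant strata flag nobody. Sitting-time categories
1..12 map to hours via the default midpoints (0, 0.5, 1, 1.5, 2, 3, …, 8,
9), the open-ended top category mapped to its lower bound; the instrument's
exact interior boundaries are not published, so the mapping is declared
configuration. Sleep averages as (5 × weekday + 2 × weekend)/7. Chair-stand
repetitions are a pass-through measurement.

## Statistics

Categorical variables: Pearson chi-square on the K × 3 table, no continuity
correction, zero-margin levels dropped. Non-normal continuous variables
(age): tie-corrected Kruskal–Wallis with pairwise KW × 3 Bonferroni.
Continuous variables: OLS with the tertile as a 3-level factor; the family
test is the type-II 2-df F on that factor — with an empty covariate set this
*is* the one-way ANOVA, verified to machine precision against an
independent F computation. ANCOVA adds dummy-coded covariates (sex, age;
the full set adds education, smoking, marital and employment status, plus
the five drug-class flags for the biochemistry table). Pairwise letters
(a: T1 vs T2, b: T1 vs T3, c: T2 vs T3) come from the covariate-adjusted
contrasts of the same fitted model with p × 3 capped at 1, reported only
when the family test rejects. Rank-deficient designs are rejected naming
the collinear columns. Normality uses the estimated-parameter KS test
(Lilliefors correction, so null p-values stay calibrated); variance
homogeneity uses Levene on absolute deviations from group means.
Missingness is complete-case per variable, with per-group n reported.

## Synthetic cohort generator

One latent severity factor L ~ N(0,1) per subject drives the six MetS
components: component = mean(sex) + SD · (λ·L + √(1−λ²)·ε), with ε from a
residual correlation matrix (SBP–DBP 0.6, TAG–HDL −0.25, small WC terms),
triglycerides log-normal (the configured mean acting as the median, log-SD
0.42), HDL loading negative, and waist circumference additionally tied to
BMI. Default loadings are 0.45–0.55. Eligibility (age window, BMI window,
≥3 raw-value MetS criteria) is enforced by vectorised rejection sampling
capped at 1000 rounds, after which an informative error reports the
acceptance rate. Medication flags are Bernoulli with logit = b₀ + b₁·L;
default intercepts reproduce prevalences typical of such cohorts
(antihypertensives ≈ 78%, insulin ≈ 4%).

Lifestyle couplings are expressed as the mean shift, in SDs of the
variable, between extreme severity tertiles. The tertile index used for
the shift is that of the subject's *realized severity score* — the same
stratifier the analysis uses — so a configured extreme-tertile shift is
what the analysed contrast sees, up to sampling noise. Default couplings
encode the directions such cohorts show: moderate/vigorous LTPA −0.2,
sitting +0.15, TV +0.1, BDI +0.25, chair-stand −0.3, nuts −0.15,
red/processed meat +0.15, other oils and spirits +0.1, education −0.2.
`CohortSpec.null()` zeroes every coupling, medication slope and missingness
rate for calibration studies.

LTPA comes from one representative activity per intensity class (3.3, 4.5,
7.0 MET) with zero-inflated gamma weekly MET·min (shape 0.9); BDI items are
per-subject truncated Poisson with log-normal rates (population total
≈ 8 ± 7); FFQ categories arise from a latent normal per item (group-level
location solved numerically so expected group intakes sit at realistic
Mediterranean levels, e.g. ≈ 2,350 kcal/d mean energy with SD ≈ 540, olive
oil ≈ 39 g/d, nuts ≈ 15 g/d) plus a subject appetite factor (SD 0.15) and
severity shifts for the coupled food groups. Missing-data flags default to
the stage proportions seen in such trials (PA 3.4%, FFQ 0.6%,
biochemistry 8.1%).

What the generator does *not* emulate: the real cohort's full joint
distribution (only marginal locations/spreads and coupling signs), seasonal
or centre effects, item-level dietary correlations beyond the shared
appetite factor, and follow-up visits. A ceiling effect worth knowing: with
total sitting centred at 8 h/d and the instrument topping out at "≥9 h/d",
category binning compresses the configured sitting-severity gradient — as
it would with the real instrument. Passing tests therefore demonstrate the
*pipeline's* correctness and calibration, not distributional fidelity to
any particular trial.

## Numerical and design choices

* Quantiles: tertile cut-points inverted-CDF; IQR linear interpolation.
* Tertile ties: inclusive-left, deterministic.
* Friedewald LDL returns missing at TAG ≥ 400 mg/dL.
* VAI lipid inputs convert mg/dL → mmol/L with 88.57 (TAG) and 38.67
  (cholesterol); without this the score-1 reference calibration is
  unattainable.
* All randomness flows from one integer seed through independent
  `numpy` generator streams per table; identical spec ⇒ byte-identical
  output files.
* Problem sizes used by the calibration suite — 1000 replicates of n = 600
  for type-I error, 100 replicates of n = 3000 for effect recovery, 10⁵
  draws for tertile consistency, 200 seed replicates for p-value
  uniformity — were chosen to make binomial noise on a 5% rate small
  relative to the acceptance band while the whole suite stays interactive.

## Known limitations

* The severity score is a contract-faithful stand-in, not the published
  coefficient set; absolute scores are not comparable across configurations.
* Default DII reference means/SDs and the MD-17 item definitions are
  package configuration, not instrument reproductions.
* ANCOVA assumes homogeneous covariate effects across tertiles (no
  interaction terms) and complete-case covariates.
* The chi-square and Kruskal–Wallis pairwise corrections use a fixed
  Bonferroni factor 3 (the three tertile pairs) regardless of how many
  pairs are testable.
* No survey weights, imputation, or longitudinal structure.
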