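# Methods

`egsdisparity` quantifies black-white disparities in the delivery, timing
and outcomes of urgent abdominal surgery from weighted, stratified,
hospital-clustered discharge samples, and decomposes those disparities
into contributions of mediator groups.  Because the licensed discharge
databases this kind of study uses cannot ship with a package, every
estimator here is exercised against a synthetic generator whose structural
coefficients are known, so "does the pipeline recover the truth" is a
testable question rather than an article of faith.

## The sampling design and design-based estimation

Each discharge row carries a sampling weight (`discwt` for cross-sectional
estimates, `trendwt` for across-year trends), a design stratum, and a
hospital identifier that acts as the primary sampling unit (PSU).  Point
estimates of means and proportions are Hajek ratio means
`sum(w*y)/sum(w)`.  Variances come from Taylor linearization of the ratio:
per-record scores `z_i = w_i (y_i - mean) / sum(w)` are summed to cluster
totals, and the variance is the between-cluster dispersion of those totals
within strata, `sum_h n_h/(n_h-1) sum_c (z_hc - zbar_h)^2`.  Subgroup
(domain) estimates keep the full design: out-of-domain rows carry zero
scores but their clusters still anchor the variance, the standard
convention for design-based subgroup inference.  No finite-population
correction is applied.

Numerical choices:

* **Lonely PSU** (a stratum with a single sampled cluster): the singleton
  cluster total is centered at the grand mean of all cluster totals — a
  conservative convention; a warning is logged.
* **Confidence intervals** are normal-theory Wald intervals at 1.96 SE
  throughout; p-values are two-sided Wald z tests.  No multiple-testing
  correction is applied (raw p-values are reported).

## Age adjustment

Group comparisons are directly standardized over five age bands (<40,
40-54, 55-69, 70-89, >89): `sum_b s_b * mean(y | band b, group)`.  The
default standard population is the pooled (all groups) weighted age
distribution of the diagnosis cohort — symmetric between the groups being
compared, since no external standard is canonical for this design.  The SE
treats band-specific estimates as independent,
`sqrt(sum_b s_b^2 se_b^2)`.  Bands carrying standard weight but empty in a
subgroup are dropped from both the standard (renormalized) and the
estimate, with a log message.  Two exact identities are enforced by test:
standardizing a group to its own age distribution reproduces its crude
mean, and groups with identical band-specific means have exactly zero
adjusted disparity.

## Treatment standardization

To ask how much of a length-of-stay disparity is carried by differential
treatment, the comparison (black) group's outcome is reweighted to the
reference (white) group's joint distribution over (age band x treatment
strata), where treatment strata are formed from wait-to-surgery days
(capped, by default, at 10 to keep cells populated) and the nominal
surgery-type category.  The unadjusted disparity uses the same machinery
with age bands only, so the only thing changing between the two numbers is
the stratification.  Percent explained is
`(unadjusted - adjusted)/unadjusted * 100`.  Reference strata with no
comparison-group rows are collapsed: their reference weight is reallocated
proportionally across the comparison-present strata of the same age band
(logged).  This estimator is nonparametric in the treatment-outcome
relation; its Monte-Carlo noise at moderate samples is dominated by the
comparison group's cell counts, which is why validation checks average the
percent-explained over replicates.

## Trends and gap closure

One age-adjusted disparity per calendar year is estimated with the trend
weights; year 2015 is excluded unconditionally (the sample's methodology
changed mid-year, making it incomparable).  The trend is an unweighted
ordinary-least-squares fit of the yearly point estimates on calendar year
("simple regression"; a closed-form slope with a two-sided t test on n-2
degrees of freedom).  Inverse-variance weighting is deliberately not the
default, to keep the trend definition transparent; a perfectly linear
series gets p = 0 for a nonzero slope and p = 1 for a flat one.  When the
slope is significant (p < 0.05) and opposes the sign of the final-year
disparity, the years-until-closure extrapolation |final disparity / slope|
is reported, anchored at the observed (not fitted) final-year value.

## Empirically derived covariates

* **Diagnosis severity subgroups**: primary codes are ranked by weighted
  in-hospital mortality and partitioned into three groups by exhaustive
  search over the two cut points minimizing total within-group weighted
  variance (weights = code discharge totals).  This is deterministic,
  reproduces strongly unequal group sizes when the mortality spectrum is
  skewed, and is persisted so new data can be scored with frozen cut
  points.  Weighted mortality is the default; an unweighted switch exists.
* **Crude comorbidity score**: each comorbidity's excess risk is the
  weighted mortality difference (with minus without) within the diagnosis
  cohort; a record's score is the sum over its comorbidities, so it is
  exactly additive and zero for records without comorbidities.  Negative
  excess risks are retained; a comorbidity with no variation gets a
  missing excess risk and is excluded with a warning.  Risk differences
  (not ratios) are used because only differences sum into an additive
  score.
* **Hospital aggregates**: weighted per-hospital operative rate, mean LOS,
  percent black patients, and the white-black operative-rate difference
  (defined only for hospitals seeing both groups).  A configuration flag
  disables them for inputs whose hospital identifiers are uninformative.

## Mediation by difference of coefficients

The disparity in an outcome is the black-vs-white coefficient of a
weighted GLM.  With base covariates B (age bands, continuous age, calendar
year — adjusted in every model, hence excluded from the mediation) and
mediator groups g1..gk (medical, treatment, hospital, socioeconomic):

* total  = race coefficient given B;
* direct = race coefficient given B + all groups (the unexplained part);
* unique_g = coefficient(B + all groups except g) - direct;
* overlap = total - direct - sum_g unique_g.

The identity `total = direct + sum unique + overlap` is exact by
construction on the link scale, which is why the decomposition is carried
there; odds-ratio and rate-ratio transforms are derived for reporting
only, with the non-collapsibility caveat that ratio-scale components do
not combine exactly.  The overlap term is the portion attributable
non-uniquely to several groups at once.  No inferential testing is
attached to components; the SE recorded for a unique component is the
conservative `sqrt(se_loo^2 + se_direct^2)` that ignores the positive
correlation of the two race coefficients.

Model families: binomial logit for surgery delivery and mortality;
negative binomial with log link for length of stay and time to surgery.
The negative-binomial race coefficient is reported as a discharge-per-day
incidence rate ratio `exp(-beta)`: a longer stay is a lower daily
discharge probability, hence a ratio below 1.  The dispersion `alpha` is
estimated once per outcome by a Pearson-moment regression on an initial
Poisson fit of the most saturated model, then held fixed across the nested
models of a decomposition so coefficient differences are comparable
(maximum-likelihood dispersion estimation is unavailable for weighted
fits, and a common alpha is the right comparison anyway).  Survey weights
enter as frequency weights normalized to mean one; standard errors are
cluster-robust sandwich estimates grouped on the hospital PSU.  All five
race/ethnicity groups enter as dummies with white as reference; the black
coefficient is the reported disparity.

Design matrices are built with first-sorted-level reference coding, and
constant or linearly dependent columns are pruned left-to-right by a
Gram-matrix rank check (e.g. the surgery-category "none" dummy, which
duplicates the surgery indicator) — every component model is fitted on a
full-rank design, with dropped columns logged.  Outcomes that are
themselves treatment variables (surgery delivery, time to surgery) never
receive the treatment group as mediators; time-to-surgery models are
fitted on the operated subset.  The hospital group's statistical covariate
is outcome-specific: hospital mean LOS for stay-length models, hospital
operative rate for surgery-delivery and mortality models.

Three sensitivity analyses repeat the decomposition (a) excluding elective
admissions, (b) restricted to the most recent years, and (c) with
individual comorbidity flags replacing the crude score plus the
against-medical-advice flag added; an empty restricted subset skips that
variant with a warning.

## The synthetic generator

The generator emulates the schema and design of a national inpatient
sample: hospitals with size/ownership/region/teaching attributes, strata
formed by crossing region and hospital type (singleton strata are merged
so every stratum has at least two clusters when counts permit), lognormal
discharge weights with mean 5 (echoing a roughly 20% sampling fraction;
real design-weight construction is proprietary, so these are structural
stand-ins), and `trendwt = discwt` times a mild year factor.

The structural model is race -> mediators -> treatment -> outcomes on link
scales.  Default race-conditional distributions qualitatively mirror real
inpatient cohorts: black patients are younger (a 7-year mean age gap),
more often Medicaid/self-pay and lowest-income-quartile, less often
admitted electively, and preferentially seen at urban teaching hospitals.
Default direct effects encode the qualitative disparity pattern (less
surgery, longer waits, longer stays, higher mortality for black patients).
Six diagnosis cohorts are generated with per-diagnosis baseline rates
(surgery near-universal for appendicitis, below half for obstructions;
mortality from ~0.2% to ~14%) plus an "other" stream that exercises the
inclusion filter; gallstone-pancreatitis rows carry the secondary
gallstone code requirement.

Mechanics worth knowing when interpreting tests:

* Time to surgery is a truncated-geometric process — a per-day surgery
  probability on the logit scale (capped at 21 days); LOS is wait plus an
  independent negative-binomial postoperative stay, so an LOS rate model
  is a working approximation rather than the literal generating law.
* The LOS age profile is constant within the five analysis age bands, so
  band-level adjustment and standardization are exactly aligned with the
  generating process; mortality and surgery delivery keep logit-linear
  age effects.  Hospital effects on outcomes act through observed
  attributes only (no latent hospital random effect), so the
  independence assumptions of the Taylor variance hold by construction.
* For nonlinear links the recorded "true total" race effect is defined as
  the coefficient of an age- and year-adjusted marginal fit on a large
  simulated population (`true_total_effects`), not as a sum of path
  coefficients — logit and log-link effects are non-collapsible, and this
  definition makes recovery tests well-posed.
* Race groups beyond black/white are generated with realistic shares but
  carry no structural effects by default.

What the generator does not emulate: repeated admissions of one patient,
ICD coding realism beyond the packaged illustrative map, calibration to
real national totals, year-specific schema dialects, or informative
weighting (weights are independent of outcomes given design cells).
Passing recovery tests therefore demonstrates that the estimators are
correct under a faithful design-and-confounding structure, not that any
specific real-world estimate is reproduced.

## Validation scale and problem sizes

Recovery checks run at 50,000 generated discharges per replicate (100
replicates for the null and single-path mediation checks), 200 replicates
for confidence-interval coverage, and a 400,000-row population for the
brute-force total-effect oracle; these sizes make Monte-Carlo error small
relative to the tolerances while keeping the full suite comfortably
runnable on one CPU.  The wait-time standardization check averages
percent-explained over 10 replicates because the estimator's per-dataset
noise at realistic black-patient cell counts is several percentage
points.  The single-path recovery scenario sizes its delay disparity to
the largest wait-time gap reported in comparable cohorts (~1.8 days) and
uses the obstruction cohort for the mortality path (its higher baseline
mortality gives the oracle a usefully small Monte-Carlo error).

## Known limitations

* The decomposition is a statistical attribution, not a causal one: a
  nonzero "direct" effect is an unexplained association, and mediator
  groups are observational constructs.
* Ratio-scale components are reported for readability but are not
  additive; only link-scale components decompose exactly.
* Negative-binomial dispersion is held fixed within a decomposition; if
  the mean model is badly misspecified the pseudo-true coefficients of
  nested models can differ slightly from their fixed-dispersion ideals.
* Replicate-weight (BRR/jackknife) variance estimation and exact
  small-sample inference are out of scope.
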