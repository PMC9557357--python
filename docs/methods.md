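# Methods

`checause` estimates how catastrophic health expenditure (CHE) is
distributed across disease areas — non-communicable diseases (NCDs),
communicable diseases (CDs, including maternal and child health) and
injuries — from household-survey microdata in which visit-level detail is
only partially observed. This note documents the model, the estimation
procedure, the synthetic-data generator used for validation, and the
numerical and design choices a user should know about.

## The estimation problem

Surveys in the mould of the WHO aging/adult-health studies record, per
adult respondent, the annual number of inpatient and outpatient visits,
but the *reason* for a visit only for the three most recent visits per
care level and the out-of-pocket (OOP) cost only for the single most
recent. Estimating disease-specific annual OOP spending therefore
requires two imputation stages before any CHE accounting is possible.

**Stage 1 — cause imputation.** Raw visit reasons (18 codes) are mapped
to seven cause groups (NCD, CD, injury, pain, surgery, other,
unidentified) through an editable codebook CSV; the mapping is
survey-specific and deliberately not hard-coded. Visits beyond the third
get their cause from a random-forest classifier trained per country and
care level on visits with observed causes. Features: respondent
covariates (age, sex, urban residence, education, wealth quintile),
annual visit counts, care level, and leave-one-out counts of the
respondent's other observed causes. The last feature group carries most
of the signal when a respondent's care is concentrated in one disease
area. Cross-validation is grouped by respondent so visits of one person
never straddle a train/test split. Defaults: 500 trees, sqrt feature
subsampling, minimum leaf 5, fixed seed; all exposed in
`ImputationSettings`. Ties in the modal class break by the canonical
group order (NCD, CD, injury, pain, surgery, other, unidentified).
Hard-label imputation feeds the main pipeline; class probabilities are
retained for sensitivity analyses.

**Stage 2 — cost imputation.** OOP per visit follows a two-part model:
a logistic model for P(OOP > 0) and a log-link GLM for positive amounts,
fitted per country and care level on observed-cost visits with the cause
group as a covariate (reference CD, so the NCD coefficient is the log
NCD-vs-CD cost ratio). The positive part is gamma-with-log-link by
default; a log-normal OLS with Duan smearing retransformation is
available (`cost_family="lognormal"`). Predicted cost is the expected
value p̂ × conditional mean, never a stochastic draw: imputed visits
contribute mean spending, smoothing over visit-level noise. Observed
values always override predictions. Candidate covariate sets can be
compared by grouped-CV RMSE on the expected-cost scale including zeros
(`select_covariates`); ties resolve to the earliest listed set. Currency
conversion to 2017 international dollars is a linear PPP factor applied
identically to OOP and household expenditure, so CHE flags are invariant
to the unit choice (tested as scale equivariance).

## CHE accounting

Per-respondent annual OOP by cause group is the sum over all visits of
final (observed or predicted) costs; household OOP sums over surveyed
respondents. Capacity-to-pay follows the standard food-share approach:

* households are ranked by food spending per equivalized member
  (`size ** beta`; beta defaults to 1, the literal per-capita reading,
  with 0.56 — the Xu et al. equivalence scale — as a switch);
* the subsistence line is the weighted mean of that quantity over
  households whose cumulative-weight interval overlaps the open
  (45%, 55%) band of the weighted distribution;
* capacity-to-pay = expenditure − line × size^beta, except that
  households spending less on food than the line substitute their actual
  food spending (the WHO convention; prevents negative capacities);
* a nonpositive capacity is floored at 1e-6 with a warning counter;
  households with nonpositive expenditure are excluded and logged.

A household incurs CHE when OOP **strictly exceeds** 40% of
capacity-to-pay (both the fraction and strictness are config fields). A
CHE case is attributed to NCD, CD or injury when that category strictly
exceeds 75% of the household's *disease-specific* spending
(NCD+CD+injury only; pain/surgery/other/unidentified spending never
enters the denominator); otherwise, or when disease-specific spending is
zero, the case is unallocable.

Two share normalizations are reported: percent of all (valid) households
and percent of CHE cases; the latter sums to 100 over the four
categories by construction. The NCD share of CHE can be joined against
an externally supplied table of NCD shares of adult DALYs per country;
the DALY values are reference inputs and nothing is computed on them.

## Uncertainty

Uncertainty intervals come from a non-parametric bootstrap that respects
the survey design: primary sampling units (PSUs) are resampled within
strata, keeping each PSU's households together, with percentile 2.5/97.5
bounds (default B = 1000, fully seeded). The implementation uses the
Rao–Wu rescaling variant — k−1 of a stratum's k PSUs are drawn and their
weights multiplied by k/(k−1) — because the naive k-draw variant
deflates variance by (k−1)/k per stratum, which measurably depresses
interval coverage at realistic PSU counts; our calibration experiments
showed empirical coverage of ~0.89–0.92 for naive resampling versus
~0.94 with rescaling. The naive variant is available via
`rao_wu=False`. Strata containing a single PSU are merged into a
neighbouring stratum and logged. Imputation models are not refit per
replicate by default (refitting is a flag): intervals quantify sampling
uncertainty conditional on the fitted models.

## Drivers analysis

The **visits-to-CHE** count k is the minimal number of a household's
visits, taken from most to least expensive, whose cumulative OOP
strictly exceeds the threshold amount (0.40 × capacity-to-pay). Because
costs are sorted descending, the greedy prefix is a minimum-cardinality
crossing subset, so k is invariant to how equal costs are ordered (both
properties are tested exhaustively). The construction assumes visit
costs are independent within a household — it ignores insurance designs
that kick in above a spending level.

Comparative regressions are OLS with one-way cluster-robust standard
errors by PSU: per-visit OOP and private-facility attendance on the most
recent (non-modelled) visits, and linear probability models for "CHE
from one visit" and "CHE from five or more visits" restricted to CHE
cases, with the attributed disease category, age, urban residence,
education, sex and wealth-quintile indicators as covariates. Linear
probability (not logit) matches the probability-difference framing of
the outcomes; regressions are unweighted by default with a
survey-weighted option. Collinear terms are dropped left-to-right with a
warning; missing covariates are handled by listwise deletion with
counts logged.

## The synthetic generator

`synthetic_sage` emulates the survey structure the estimators assume,
with full ground truth retained in a sidecar (`TrueParameters`) that
estimation code never touches:

* stratified two-stage design (default 10 strata × 4 PSUs), household
  selection probabilities that oversample 50+ households (factor 2), and
  weights as inverse selection probabilities normalized to a nominal
  adult population of 1e6;
* 18–49 households contribute one respondent aged 18–49; 50+ households
  contribute all members aged 50+;
* household expenditure log-normal (median ≈ $4000/year, log-sd 0.7,
  urban and size shifts), food share Beta(9, 11) (mean 0.45); wealth
  quintiles are weighted quintiles of a simulated asset index
  correlated with, but distinct from, expenditure;
* visit counts negative binomial (outpatient mean 1.6/person-year,
  inpatient 0.10, dispersion 1; an optional cap exists, default none);
* each respondent has a dominant cause from a multinomial logit over the
  seven groups (age, education, urban, sex effects scaled by
  `cause_signal`); visits follow the dominant cause with probability
  1 − `cause_noise` (default 0.75);
* costs follow the two-part law per cause × care level: median
  outpatient CD visit ≈ $13, inpatient ≈ $100, log-sd ≈ 1, zero-cost
  probabilities 0.15/0.08, with the NCD log-mean exactly
  log(`ncd_cost_ratio`) above CD (default ratio 1.6) plus small
  covariate effects.

Censoring reproduces the survey exactly: causes retained for recency
ranks 1–3 per care level, cost for rank 1 only, counts always. These
defaults produce a weighted CHE rate of roughly 1–2% of households, in
the range typical of the surveyed settings.

What the generator does **not** emulate: country-specific marginals,
recall error, panel structure, seasonality, informal payments, or any
dependence of visit costs within a household beyond shared covariates.
Passing recovery tests therefore demonstrates internal consistency of
the estimation chain under its own assumptions, not robustness to those
real-data features.

## Validation scenarios and problem sizes

`checause.scenarios` fixes four named data-generating conditions used by
the test suite and the acceptance script:

* **cost recovery** — dense outpatient care (~22 000 positive-cost
  visits per replicate) with the planted 1.6 ratio; over 100 replicates
  the part-2 NCD coefficient shows < 5% bias and ≈95% CI coverage;
* **high signal** — `cause_signal=10`, `cause_noise=0.02`, so held-out
  classifier accuracy exceeds 0.95 in every country × care-level cell;
  at 20 000 households the pipeline's NCD/CD/injury shares of CHE cases
  match the truth-sidecar shares within 2 percentage points;
* **mechanism** — NCD care generates many cheap visits (rate multiplier
  5, cheap log-means) while CD care generates rare expensive inpatient
  stays, on a lower expenditure scale (median $1500) so accumulation can
  cross the threshold; the five-plus-visits NCD contrast is positive and
  the one-visit contrast negative in ≥ 90% of replicates, and a null
  variant (identical NCD/CD laws) centers both on zero;
* **calibration** — 2400 households across 20 strata × 5 PSUs per
  replicate, B = 200, 200 replicates, reference value from a single
  200 000-household run: empirical coverage of the 95% interval for the
  weighted CHE rate falls in [0.90, 0.99].

These sizes were chosen so each check runs in seconds to a couple of
minutes on one CPU while keeping Monte-Carlo error well below the
tolerance being asserted.

## Known limitations

* The attribution rule ignores non-disease spending entirely; a
  household whose spending is mostly "pain" or "unidentified" can be
  attributed to a disease category on a small disease-specific base.
  This mirrors the disease-specific-share definition but is worth
  remembering when unidentified shares are large.
* Expected-value cost imputation understates within-household OOP
  dispersion, so CHE flags for households whose crossing depends on
  imputed visits are smoother than reality; the truth-vs-pipeline share
  comparison quantifies the net effect under the generator.
* The bootstrap conditions on fitted imputation models unless refitting
  is enabled, understating total uncertainty somewhat.
* Single-country cells with too few observed-cause visits fall back to
  the country's other care-level model; with no trainable model at all
  the pipeline raises rather than guessing.
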