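# Methods

## Study design emulated

The package implements a prospective-cohort design over linked
record-level data: adults registered in primary care, first stroke
between 1 January 2020 and 31 December 2023, followed for 180 days
(home-time) and 1 year (dispensing).  Five sources are linked by a shared
person identifier: primary-care diagnoses (SNOMED CT), hospital
admitted-patient spells (ICD-10 primary diagnosis per spell), a
hospital stroke audit (stroke type, NIHSS, Rankin), death registrations
(ICD-10 underlying cause) and community dispensing (four drug classes).
Probabilistic linkage is out of scope: identifiers are assumed already
linked, as they are inside a national secure data environment.

## Ascertainment rules

* **Index event.** The earliest stroke-coded record across sources.
  Records dated within 30 days *after* the index date belong to the same
  event; the window is anchored at the index date, not chained
  transitively, and same-source records on the same date collapse to
  one.  Records beyond the window are discarded — recurrent strokes are
  deliberately not analysed, since separating follow-up consultations
  from true recurrence in coded data is unreliable.
* **Prevalent exclusion.** Any stroke record strictly before the study
  start excludes the person.  A first record *on* the study start date is
  eligible.
* **Death-only events.** A stroke-coded death with no in-life stroke
  record forms an index event dated at death with source {ONS}.
* **Fatality.** Death from any cause within 30 days of index, *inclusive*
  of day 30 (the conventional 30-day case-fatality window; the bound is
  fixed here so boundary behaviour is testable).

## Subtype harmonisation

Codes map to ischaemic / haemorrhagic / unknown: ICD-10 by longest
prefix (I63, I61, I64 and their 4-character children), SNOMED and the
audit's type field exactly.  One subtype per event is resolved by source
priority (audit > hospital > primary care > deaths).  Within the deciding
source, "unknown" records are ignored if a specific type is present;
both specific types present resolves to unknown.  An unknown-only record
in a higher-priority source *does* override a specific type below it —
the priority rule is applied literally.

## Outcome definitions

Home-time uses half-open day conventions: a spell occupies
[admission, discharge), so same-day admission and discharge contributes
zero hospital days; the day of death and all later days in the window are
dead days, and in-hospital death days count once, as dead.  With these
conventions home + hospital + dead = 180 exactly for every person, which
the tests exploit (a day-by-day labelling oracle must agree with the
interval arithmetic in 100% of randomised cases).  Open-ended spells
close at min(death, end of data).  Survivors whose window extends past
the data end have the remainder counted as home; the generator
guarantees complete 180-day follow-up, and a warning would apply
otherwise.

Incident dispensing starts 30 days ("1 month") after the anchor —
discharge of the index spell if hospitalised, otherwise onset — and ends
365 days ("1 year") after *onset*.  A discharge later than onset + 335
days therefore leaves an empty eligibility window, which is logged, not
an error.  Event times for the competing-risk analysis run from the end
of the washout; persons dying on or before that origin are excluded from
the at-risk set (the alternative — counting them as competing events at
time zero — is a documented switch of interpretation the package does
not take).

## Estimators

* **Direct standardisation.** Rate = Σ w_s (d_s/T_s) / Σ w_s per 100 000
  person-years, with ESP 2013 weights (shipped as data).  Only adult
  bands are used; the 18–19 sliver inherits the 15–19 band weight.  When
  strata are age × sex, the age weight is split equally between sexes.
  95% intervals use the gamma method of Fay & Feuer, which keeps coverage
  at small counts; a normal approximation would be a one-line swap.
  A stratum with positive weight and zero person-time is an error naming
  the stratum.
* **Aalen–Johansen.** Product-limit all-cause survival with
  cause-specific increments S(u−)·d_k(u)/n(u); censored subjects at a
  tied time stay in the risk set.  Additivity
  CIF_disp + CIF_death + S = 1 holds to 1e-10 at every event time and is
  asserted on arbitrary data.
* **Cause-specific Cox.** Other-cause events are censored; partial
  likelihood is maximised by lifelines with Breslow tie handling.
  A fit is *flagged* (no estimates) on exceptions, non-finite output, or
  the monotone-likelihood signature of separation (|β| ≥ 10 or SE ≥ 20),
  which lifelines can otherwise report as a spuriously "converged" huge
  coefficient.  Proportional-hazards diagnostics are deliberately not
  performed; the hazard ratios summarise time-averaged effects.
* **Adjusted CIF.** G-computation (marginal standardisation): per
  covariate pattern, Breslow baselines for both causes are combined in
  discrete product-limit form S(t|x) = Π(1 − Σ_k dH_k(u|x)) and the
  per-pattern CIFs are averaged over the observed covariate
  distribution.  The product-limit (rather than exponential) form is
  chosen so that zero coefficients reduce *exactly* to the
  Aalen–Johansen estimate; survival factors are clipped at zero for
  extreme covariate patterns.
* **Mean home-time.** Crude means with normal-approximation intervals;
  adjusted marginal means by averaging OLS predictions with every
  subject's stratum set to each level in turn (collapsible in balanced
  designs, which a test asserts).

## Covariate conventions

Condition flags use records from birth to index − 1 day (primary care
SNOMED exactly; hospital ICD-10 by prefix, primary diagnosis);
hypercholesterolaemia is defined from primary care alone.  The Charlson
score uses the Quan 2005 ICD-10 mapping with the original weights
(shipped as a replaceable CSV), hierarchy rules (severe liver over mild,
complicated diabetes over uncomplicated, metastases over primary
malignancy), binned 0 / 1–2 / 3–4 / 5+.  Measurements take the most
recent value in [index − 2 years, index − 1 day] inside configured valid
ranges (e.g. SBP 50–300 mm Hg, BMI 10–80; the ranges are declared
defaults in `data/measurement_ranges.yaml`, not claims about any
external protocol).  Age at index uses birth year with a mid-year
convention, since the generator emits years only.  COVID-19 exposure is
reduced to dated positivity flags: "recent" is any flag in
[index − 14, index − 1], "history" anything earlier.

## The synthetic generator

What it emulates: per-person exponential waiting time to first stroke at
the configured age-sex incidence; subtype mix ~70/13/17; 30-day case
fatality by subtype (ischaemic 0.12, haemorrhagic 0.35, unknown 0.18);
independent per-source capture given fatality status; zero-inflated
integer date jitter (35% of records jittered with SD 2 days; death dates
registry-exact), so the inter-source median date difference is ~0 with
tail disagreement; source-specific probability of coding the subtype as
unknown (primary care 0.19, hospital 0.012, audit 0, deaths 0.26);
log-normal length of stay (median 5 days); first post-stroke dispensing
per class at constant daily hazard competing with death, followed by
monthly-to-quarterly refills; prior-year dispensing per class
prevalence; comorbidity records, pre-stroke measurements and deprivation
lookup tables.  All numeric defaults are the package's own realism
choices for an English adult population; none is a measured external
value.

What it does not emulate — and therefore what passing tests do not show
about real data:

* **No late mortality.** Deaths occur only within 30 days of stroke, so
  among non-fatal strokes there is almost no competing death during
  dispensing follow-up and no home-time lost to death after day 30.
  Competing-risk estimator behaviour under heavy competing mortality is
  verified separately with direct competing-exponential simulations.
* **Captures are independent across sources** given fatality status;
  real sources are positively correlated (a configurable limitation).
* Toy code vocabularies (a handful of SNOMED concepts per condition);
  no geographic structure in LSOAs; no private prescriptions; no
  recurrent strokes; fixed age at study start (persons do not age across
  calendar years in the incidence denominators).

## Problem sizes and numerics

The analysis drivers use 300 000 persons (seed 20, ~3 600 strokes); the
acceptance script uses 1 000 000 persons (~12 000 strokes), sizes chosen
to give stable percentages at interactive runtimes.  Statistical
recovery tests use 3-standard-error bands around their closed-form or
binomial oracles; exact-arithmetic checks (home-time partition,
percentage rounding, subset counts) use equality.  Percentages round
half-up to one decimal; quantiles use linear interpolation; disclosure
rounding (off by default for synthetic data) rounds counts half-to-even
to multiples of 5.  Cox convergence tolerance is 1e-9 on the
Newton-Raphson precision with at most 100 steps.
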