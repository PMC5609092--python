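# Methods

This note records the model behind `rhtn`, the conventions and numerical
choices that fix its behaviour, what the synthetic generator does and
does not emulate, and the places where the design was genuinely open.

## Date conventions

All intervals are half-open `[start, end)` on whole days, computed on
proleptic-Gregorian ordinals. "Within six months" is a fixed 183 days
and "within a year" a fixed 365 days, so results are identical across
leap years; person-years use 365.25-day years. Repeat-prescription and
blood-pressure search windows are `(start, start + w]` — the initiating
day itself is excluded, the boundary day included (a repeat exactly 183
days after the nth drug's start confirms). Eligibility ends the day
*after* the earliest exit date; the 31 December prevalence snapshot uses
a closed upper bound so the study-end day itself counts (otherwise the
final study year would have a structurally empty denominator). Age in
whole years is `floor((date − birth)/365.25)`.

## Exposure model

Coverage is a stockpiling model: one day of supply is consumed per
covered day, and supply remaining when a new script arrives is appended
after the new supply. Carryover is uncapped — a deliberate choice, as
the definition being implemented states carryover without a ceiling.
Consequently total covered days per class never exceed total days'
supply (they are equal within a run). Two same-day scripts of a class
both contribute supply. Scripts without a days'-supply value receive a
configurable default of 28 days per script: deriving days' supply from
raw quantity/dosing text is not reproducible from class-level records,
so the imputation is a declared stand-in and an input column overrides
it.

A discontinuation is recorded when ≥ `discontinuation_gap` (default 90)
days separate a run's expected finishing date from the next script of
the class. In the adherence lookback the observation window is truncated
at the *first* such discontinuation date; a consequence worth noting is
that a patient whose only script sits early in the lookback is assessed
over the short window they were actually prescribed for — their class
PDC can be 1.0. This follows the definition literally ("until the
discontinuation date of that drug"); the concurrency requirement
upstream is what prevents long-discontinued patients from qualifying.

"Repeat prescription" means any later script of the same class, not the
same product — class-level exposure is what the definition tracks. The
adherence average runs over the regimen's classes only, not every
antihypertensive the patient ever used (an open reading of "across all
drugs"; the regimen-only reading keeps the measure attached to the
regimen being assessed). Classes with no script in the lookback are
skipped, not averaged as zero; if every class is skipped the candidate
is not assessable and cannot become a case.

## Candidate detection and arbitration

Candidates are emitted at coverage-run starts — exactly the days a class
begins a new episode. When more than n−1 other classes are active, one
candidate is emitted per n-subset containing the new class, and the
earliest achievable index date wins; the diuretic requirement and
confirmation prune the rest. Same-day starts of two classes treat both
as new. Candidate initiation dates are restricted to the patient's
eligibility window, and a case's index date must fall inside it.

Detection is *not* monotone in scripts in the strictest sense: adding a
script of an already-used class can merge two coverage runs and erase
the later run-start (and with it a candidate date). What does hold, and
is property-tested, is that day-level concurrency is monotone and that
scripts of a previously unseen class never remove existing candidates.

The three-drug arm takes the *first* at-or-above-threshold reading in
the 12-month window (earliest opportunity; single-measurement
ascertainment). Readings between the third drug's start and the
confirmation date are eligible — the full 12-month window is searched.
Thresholds are resolved per reading date and patient age, so the
sensitivity variants (≥ 160/90 mm Hg for an early period, ≥ 150/90 mm Hg
at age 80+) are ordered first-match override rules, not separate code
paths. A non-adherent or controlled-BP rejection does not remove the
patient from the cohort: later candidates are evaluated, and
controlled-BP rejections are flagged re-eligible (a future drug change
re-opens the question; the same regimen is not re-tested on later
readings alone).

## Rates

Incidence numerators are new cases per calendar year; denominators are
person-years of treated, diagnosed, eligible patients before their own
index date — patients excluded for poor adherence keep contributing in
full. Prevalence counts cases alive (and, by default, still eligible) at
year end over eligible treated-hypertension patients at year end; a
configuration switch relaxes the numerator to alive-only, and a patient
who transfers out and returns re-enters the numerator if eligible at the
snapshot.

Crude intervals are exact Poisson (Garwood) limits via the chi-square
quantile form. These are the natural small-count limits for rates; note
that published crude intervals for comparable tables are often much
wider than Poisson limits (their method typically unstated), so only
point estimates should be compared. Standardised rates use fixed weights
from the standard year's cohort (person-time for incidence, persons for
prevalence) with a weighted-Poisson variance,
`var = Σ (w_a/W)² e_a/d_a²`, and a normal interval floored at zero.
Strata empty in a given year contribute rate zero with a logged warning;
a band-set mismatch between rates and standard is a hard error.
Stratification assigns both numerator and denominator by the same
reference age (1 July for incidence, 31 December for prevalence), which
makes stratum sums conserve the annual totals exactly — an invariant the
tests enforce.

Default age bands are 18–39 then 5-year bands to 85+, nesting the usual
reporting categories (65–69 … 80+); configurable as any partition of
[18, ∞).

## Trend models

The count model is a Poisson GLM with log person-time offset fitted by
IRLS (statsmodels; convergence tolerance 1e-8, max 100 iterations),
Wald tests on each interaction block from the observed-information
covariance, and no overdispersion adjustment. Calendar year enters as a
categorical factor in the general operation; the pipeline's default
uses linear year and coarse age groups (<60, 60–69, 70–79, 80+) because
the fully categorical interaction model is not estimable on desk-scale
cohorts (sparse cells separate perfectly). Non-convergence raises with
diagnostics; the pipeline records the skip rather than failing the run.

The segmented fit is a simplified joinpoint re-implementation:
continuous piecewise-linear least squares on log rate vs year,
joinpoints restricted to observed years with ≥ 2 points per segment
(shared knots counting for both sides), exhaustive grid search over
placements. The number of joinpoints is chosen sequentially (k vs k+1):
the statistic (RSS_k − RSS_{k+1})/RSS_{k+1} is compared against its
permutation distribution under residual permutation of the k-joinpoint
fit, Bonferroni-adjusted over the sequence at α = 0.05, with a
Monte-Carlo p of (1 + exceedances)/(1 + permutations); a null RSS below
1e-12 short-circuits to "no further turns". Per-segment slopes are
linear contrasts of the fitted coefficients with t-based intervals, and
APC = 100·(e^β − 1). Errors are treated as uncorrelated and unweighted
— a documented simplification relative to the reference joinpoint
software, whose error-model options are not reproduced; sign and
ordering of segments, not exact APC values, are the supported
inferences. Determinism follows from the seed.

## Synthetic cohort

The generator emulates: 1995–2015 calendar coverage; adult entry ages
(uniform 40–75 at the pivotal drug change); registration/up-to-standard
bookkeeping placed so eligibility starts at diagnosis; stepped
intensification; heterogeneous refill behaviour (28-day adherent vs
56-day sparse cadence, mean PDC ≈ 0.55 for the latter); readings whose
level tracks regimen context; optional transfer-out hazards. Planted
cases are constructed *backwards from the case definition* on aligned
28-day grids, so confirmation and index dates are known in closed form
and sensitivity is exactly measurable; confound archetypes (switchers,
non-adherent pseudo-cases, controlled-on-three) are built to fail
exactly one rule each.

It does not emulate: realistic product/dose mixtures, seasonal
prescribing, measurement-error distributions of clinic readings,
mortality differentials, or any real database's demographics and
absolute rates. Blood-pressure values are clipped away from the
decision boundary (controlled ≤ 138/88, qualifying ≥ 141 systolic), so
passing recovery tests demonstrates the algorithm's correctness on
records that satisfy or violate the definition unambiguously — not its
behaviour under borderline readings, which real data contain. BP effect
sizes and the adherence mixture are free parameters of the artifact,
not estimates.

Preset scenarios: `clean` (2,000 patients, noise-free, 10% planted cases
split 6%/4% across arms), `switchers` (no true cases), `nonadherent`
(pseudo-resistance dominates; disabling the adherence rule inflates the
count), `trend` (onset years triangular with a 2004 mode, yielding a
rise-then-fall incidence series). Problem sizes throughout the tests and
the acceptance script (2,000-patient cohorts, 1,000-scenario oracle
sweeps, 199 permutations) were chosen as the smallest that make the
recovery and calibration properties sharp.

## Known limitations

Prescribing-based PDC overestimates true intake adherence; the
single-reading BP criterion admits white-coat effects; the generator's
guarantees are by construction, so recovery rates on it are ceilings,
not field estimates; and the joinpoint simplifications above mean
published APCs from the reference software will differ numerically.
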