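# Methods

This note documents the models, conventions and design choices behind the
pipeline, in the order the stages run.

## Time model

All timestamps are real hours from a fixed study origin (1 August 2010,
00:00); calendar months are recovered by attaching the origin. The study
calendar has a 12-month pre-program period (Aug 2010 – Jul 2011), the
excluded initiation month (Aug 2011, program start 19 Aug 2011), and a
12-month program period (Sep 2011 – Aug 2012). Generated times are snapped
to a dyadic 1/1024-hour grid (~3.5 s). The grid has two properties the
tests rely on: every grid value and every sum/difference of grid values is
exactly representable as an IEEE double, so intervals recomputed by the
pipeline equal generator-truth intervals bit for bit; and the grid is exact
in microseconds, so ISO-8601 file round trips are byte-identical.

## Episode definitions

A BSI episode is growth of a pathogen from ≥ 1 blood-culture set in a
patient with SIRS. Commensals (coagulase-negative staphylococci,
*Corynebacterium*) are pathogens only when ≥ 2 sets are positive within
48 h *and* a clinically related infection is recorded; otherwise the
organism is flagged a contaminant in that set. Positive cultures of the
same organism within two weeks (336 h, read as "a culture at exactly 336 h
starts a new episode") of onset belong to one episode; the
different-infection flag splits regardless of gap. Onset is the first
culture order of the episode; the reference time is the ID/AST report of
the index isolate (the first report drives therapy decisions when repeat
cultures exist). A set growing ≥ 2 pathogens forms a single polymicrobial
episode.

Exclusions are applied with a fixed precedence so accounting is
deterministic: age < 18 → not hospitalized/ED at culture → discharged
before the report → polymicrobial → death within 24 h of the report →
onset in the initiation month. Acquisition type uses the 48-h rule from
admission (or ED visit when admitted through the ED): < 48 h without
healthcare exposure = community, with exposure = healthcare-associated,
≥ 48 h = hospital-onset. Healthcare exposure is an input boolean; so are
all chart-review judgments (dose/site adequacy, clinical infection,
IV-to-oral clinical-course flags, mortality adjudication flags) — the
package classifies, it does not re-adjudicate.

## Therapy classification

Susceptibility "I" (intermediate) is treated as *not* active — the
conservative reading of "active antimicrobial". An agent is in use on
[start, stop), where the stop is the *imputed discontinuation*: the next
scheduled administration after the last given dose (inferred from the
record's dosing schedule; running orders never stop). At time *t* the
regimen is

* **effective** iff ≥ 1 in-use agent has S for the episode pathogen;
* **superfluous** iff any in-use agent is on the broad-spectrum list for
  the pathogen's gram category *and* the pathogen is susceptible to ≥ 1
  non-superfluous agent of that category in the knowledge base (the
  minimal operational reading of "the spectrum was excessive"). The lists
  are per gram category; anaerobes and yeasts have none. Combination
  therapy with one superfluous agent is superfluous overall;
* **optimal** iff effective, not superfluous, and ≥ 1 in-use *active*
  agent is adequate in site and dose (input flags) and route — IV always
  qualifies, oral only while all five IV-to-oral criteria hold.

Event times, measured from the reference time: time to effective therapy
is 0 when empirical therapy is effective, else the first start of an
active agent; time to optimal therapy is the first time the optimal
predicate holds (evaluated at every regimen-changing instant: starts,
imputed discontinuations, clinical-flag flips); de-escalation is
max(discontinuation of a broad agent in use at the reference, start of a
strictly lower-spectrum-rank active agent), requiring the narrower agent
to still be running when the switch completes and, by assumption, to be
active in vitro ("narrower" is rank-strict, not necessarily minimal);
the IV-to-oral switch is the first oral administration of an active agent
while all five criteria hold — an oral switch under a failed criterion is
recorded as an inappropriate switch, not an event.

Censoring: 240 h after the reference, or earlier at death or discharge;
ties resolve event > death > discharge. Infection-related death requires a
positive non-contaminant culture within 48 h before death (the paper-level
criterion "positive blood culture at the time of death" given an explicit
window), or a persistent focus with sepsis signs, or death within two
weeks of the report without an alternative explanation. Thirty-day
mortality uses episodes, not patients, as the denominator.

## Survival statistics

Kaplan-Meier is the plain product-limit estimator with the standard tie
convention (events before censorings) and Greenwood's variance. Landmark
proportions 1 − S(t) get a linear normal 95% interval clipped to [0, 1] —
matching the symmetric intervals a clinical reader expects — rather than a
log-log transform; the median CI inverts the sign test (first crossing of
S ∓ 1.96·se through 0.5). The log-rank test is the standard two-group
counting-process form with hypergeometric variance; with no events it
warns and returns p = 1. lifelines implements the same estimators and is
used as the independent cross-check in the test suite, never as the
implementation, because the module's contract pins the variance, CI and
tie conventions explicitly.

## Interrupted time series

Months are coded t = 1..24 with post_t = 1 for t ≥ 13 and the trend-change
regressor (t − 12)·post_t, the standard segmented-regression
parameterization; the initiation month is excluded, not renumbered.
Monthly proportions (episodes with the event by the landmark hour, over
eligible episodes — de-escalation is evaluated among episodes on effective
empirical therapy) are modelled untransformed by OLS, one point per month,
coefficient t-tests on n − 4 df, no autocorrelation correction; the
Durbin-Watson statistic is reported as the diagnostic, and is flagged
undefined when residuals are numerically zero (perfect piecewise-linear
input). statsmodels provides the OLS fit and the DW statistic.

## Contingency and baseline statistics

2×2 chi-square is uncorrected Pearson (algebraically the squared pooled
two-proportion z) — the uncorrected form reproduces the published
two-period p-values from the printed counts, the Yates-corrected form does
not. Fisher's exact test is two-sided by the point-probability method
(scipy). Rank-sum comparisons use Mann-Whitney with exact enumeration for
combined n ≤ 12 without ties, else the tie-corrected normal approximation
with continuity correction; mean differences use Welch's t with
Satterthwaite df. The chi-square-vs-Fisher rule (all expected counts ≥ 5)
is advisory: the report generator applies it, the functions only warn.

## Synthetic cohort generator

The generator draws ground truth first and then constructs records that
realize it: event times are drawn per outcome from period-specific
exponential models and snapped onto each administration record's own q8h
dosing grid; stored truth is recomputed from the realized record times
with the same float expressions the pipeline uses, so the end-to-end
identity is exact, not approximate. One `numpy.random.default_rng` stream,
consumed in a fixed order (pre months, post months, injections), makes the
whole record set a deterministic function of the seed.

Default study conditions (chosen once, from the published cohort):
648/678 included episodes over 12 + 12 months; empirical-therapy mix
allocated by largest-remainder quota so the per-period category counts are
exactly the published ones (317/181/21/129 and 337/170/20/151); pathogen
marginals from the published distribution, ESBL fractions 0.322/0.442
among *E. coli*, MRSA 0.522/0.516, ICU 0.071/0.117; report delays uniform
48–90 h pre and 39–81 h program (a 9-h mean shortening); event-time rates
calibrated to the published landmarks — P(effective ≤ 24 h) = 0.388/0.748
among ineffective-empirical episodes and P(de-escalation ≤ 24 h) =
0.282/0.571 among superfluous episodes, which compose with the category
mix to the published all-episode landmarks (≈ 87.8% vs ≈ 94.4% effective
at 24 h); 30-day mortality 68/648 and 67/678 with the published
infection-related fractions; 22% canceled consultations in the program
period. Where the source gives no value (dose-correction rate for the
small "effective but inadequately dosed" stratum, IV-to-oral switch
fraction and rate, length-of-stay dispersion), parameters were set once to
plausible clinical magnitudes — switch parameters were fitted to the
published day-2/day-8 switch proportions under a cure-fraction exponential
model — and are documented in `simulate.PeriodParams`.

Injected, truth-labeled extras exercise every selection rule: per-period
counts of each exclusion cause, contaminant-only and SIRS-absent sets,
repeat cultures inside an episode, late recurrences (≥ 2 weeks, same
admission) and flagged different-infection episodes (which ride on the
host's running therapy and are therefore empirically optimal, consuming
optimal quota slots).

What the generator does **not** emulate: the causal pathway of the alert
mechanism (event-time distributions are assigned, not produced by a
prescribing model), patient-level covariate confounding, correlation
between episodes of the same patient beyond shared admissions, seasonal or
secular trends within a period, and irregular real-world dosing schedules
(everything is q8h). Passing tests therefore demonstrate that the
*computation* is correct under the stated statistical structure, not that
the clinical effect sizes would replicate in new hospital data.

## Numerical choices and degenerate inputs

Empty samples, zero margins, collinear ITS designs, all-zero residuals and
empty susceptibility panels raise errors rather than returning defaults.
Landmark queries beyond the last observed duration carry the last value
forward and flag extrapolation. Greenwood variance at S = 0 is reported as
0. The KM brute-force oracle, Fisher enumeration oracle, log-rank
hand-tally oracle and OLS normal-equations oracle live in the test suite,
independent of the implementation paths they check.

## Known limitations

Episodes are treated as independent in all tests (patients can contribute
several episodes); the published analysis does the same, so the package
reproduces that simplification rather than correcting it. The
knowledge-base spectrum ranks are a total preorder per gram category
chosen for the default formulary; hospitals with different formularies
should edit the shipped table. Daptomycin and anti-MRSA cephalosporins are
absent from the default knowledge base (not available in the study
setting); whether they would be superfluous-listed is left to the user.
The analysis-script interface (`analysis/01..07`) plus the library
functions in `pipeline` are the intended entry points; no shell CLI is
provided because every consumer of this package is expected to work in
Python.
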