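# Methods

## The procedure

`asthmasteps` classifies asthma severity by proxy of BTS/SIGN treatment
steps from prescribing records alone. The working assumptions are:

* current pharmacotherapy intensity is a usable severity proxy, so the
  guideline's stepwise ladder can be read off prescriptions;
* a regimen is observable only on days a prescription is written, so steps
  are evaluated at *prescription events* and durations are measured between
  event dates;
* any medication prescribed in the 120 days before an event is part of the
  current regimen. 120 days balances capturing staggered refills of a
  multi-component regimen against resolution for detecting regimen change;
  because most ICS canisters are 30-day supplies at label dosing (a 120-dose
  canister at two puffs twice daily), a refill still falls inside the window
  at usage as low as 25%, so intermittent as-needed use is captured as
  continuation.

The stages, in pipeline order: identify medications → apply exclusions →
extract dose text → impute → validate strengths → band daily doses →
condense same-day rows → build windowed regimens → classify steps → discard
run-in → trajectory statistics. Every stage is a pure function of its
inputs; re-running on identical inputs and configuration is byte-identical.

## Rule details and numerical choices

**Name matching.** Fields are uppercased and single-spaced before matching.
An entry matches when its generic key or any brand token occurs as a
substring of the name. Two distinct entries matching is an error, never
silently resolved — the shipped catalogue therefore keys combination
products (Seretide, Symbicort, Flutiform) and extrafine beclometasone by
brand-safe tokens. A fully generic rendering of a combination product
("FLUTICASONE/SALMETEROL") would match two rows and raise; sites whose data
contain such names must add a dedicated catalogue row with a disambiguating
token. Exclusion precedence is fixed so attrition counts are well defined:
out-of-period → deleted → no-match → formulation (spray/drop, ICS-bearing
entries only) → indication keyword → non-asthma brand.

**Strength extraction.** The microgram list
[10000, 5000, 4000, 2000, 1000, 500, 400, 320, 250, 200, 184, 160, 125,
100, 92, 80, 65, 50] is scanned in descending order, then the milligram list
[0.5, 20, 10, 5, 4, 2, 1] (×1000), so no value is ever read as a proper
suffix of a longer one; a left digit/decimal-point guard makes this robust
even to prefixes the ordering alone would not protect. For combination
inhalers a `a/b` token yields the ICS component before the slash; the LABA
component after it is carried but never used for banding. Strength is
searched in the dose text first, then in the medication name (strengths are
routinely embedded in names, "SERETIDE 250").

**Quantity.** Numbers one-to-four (numerals or words) anchored by
"TAKE"/"INHALE" before, or "TO BE TAKEN"/"DAILY"/"AT"/"PUF"/"P " after. The
"P " shorthand is implemented as number-then-"P "-with-trailing-space; the
preceding-anchor rules are tried first. Numbers above four never match and
fall to imputation.

**Imputation.** Missing frequency/quantity/strength are filled with the
per-medication mode over observed values; ties break to the smallest value
(deterministic and never dose-inflating — the direction of this tie-break is
a design choice, not externally specified). A component with no observed
value anywhere for its medication stays absent, and the record then carries
no daily dose; for non-ICS classes this is harmless since only class
presence matters. Extracted strengths not among a product's licensed unit
strengths exclude the record (`STRENGTH_OUT_OF_RANGE`) after imputation.

**Banding.** Guideline low/medium/high daily-dose values per drug +
inhaler type widen into ranges: low (0, L]; medium [L+1, M] (or [M/2, M]
with no low value); high [M+1, 4M] (or [H/2, 2H] with no medium value).
Above the high upper limit the category is "unknown". Classification uses
the upper limits as cutpoints — the smallest defined band whose upper limit
covers the dose — which equals range containment wherever ranges are
contiguous and keeps the mapping total when a low or medium range is absent
(a dose below a gap takes the band above it, the conservative direction for
a severity proxy). Daily doses are compared at 1-mcg integer granularity
(half-up rounding) to match the "+1 microgram" boundary construction.
Paediatric "very low" doses fall inside the low range; no separate band
exists. No cross-molecule dose equivalence is applied: each product is
banded on its own thresholds.

**Regimens.** The window is the 120 days ending on (and including) the
index day — inclusive of the index so same-day combination prescribing
forms one regimen. Within a window, each distinct ICS-containing product
contributes its *most recent* prescription's daily dose, banded on its own
thresholds; the regimen's band is the maximum over products
(LOW < MEDIUM < HIGH < UNKNOWN — "unknown" means above-range, so it cannot
rank below high). The aggregation across concurrent ICS products is a
documented choice; maximum is monotone and auditable. An ICS product whose
daily dose is unrecoverable even after imputation is banded UNKNOWN to keep
the mapping total. SABA is a reliever: it never counts as an add-on and
only marks the SABA-only regimen. Corticosteroid solutions count as the
"other controller" add-on, never toward the inhaled band. Prescribed (not
dispensed) dates define exposure timing, as dispensing linkage is noted to
be imperfect in this class of data.

**Steps.** The decision tree is ordered configuration data over (band,
add-on count); the shipped adult tree is: no ICS → 0; low alone → 1; low +
one add-on → 2; low + ≥2 add-ons or medium with ≤1 add-on → 3; high or
unknown band, or medium + ≥2 add-ons → 4. Totality over the full band ×
add-on-subset space is validated at load; the step-1 configuration is
unique. A paediatric variant (one strength category down, saturating at 4)
ships as an alternative config, disabled by default; under-5 LTRA
substitution is out of scope.

**Trajectories.** Episodes merge consecutive events at one step; duration
runs from the episode's first event to the next episode's first event. The
final episode is censored and excluded from duration summaries (no survival
modelling is attempted; the censored percentage is disclosed per step).
Within-step regimen changes are label changes between consecutive
equal-step events and populate the transition matrix's diagonal.
Transitions touching step 0 are excluded by default (they commonly reflect
non-adherence). Person-years are rolling 365-day blocks anchored at each
patient's first retained event — anchored rather than calendar years to
avoid partial first years; the convention is a configurable choice since
either reading is defensible.

## The synthetic cohort generator

The generator emulates the *structure* of a Scottish primary-care
prescribing extract, not any real dataset's marginal distributions. Per
patient: a latent Markov walk over steps 0–4 (initial distribution 26/16/7/
21/30%, the shape typical of a general asthma population) with
exponentially distributed dwell times — mean 300 days before a step-down
versus 130 before a step-up, encoding that clinicians de-escalate more
slowly than they escalate; each step interval is realised as a concrete
regimen valid for that step under the adult tree; components refill every
30 ± 3 days; dose texts render from phrase templates with configurable
noise (the "PUFS" typo, missing strength or frequency, unit spacing, brand
versus generic names) plus a 2% admixture of non-asthma decoys and 1% nasal
sprays to exercise exclusions. All randomness flows from one seed;
identical configs give byte-identical output.

Ground truth records, per prescription, the true frequency/quantity/
strength and, per prescription day, both the *latent* step and the
*expected* step — the step implied by the true medications in that day's
lookback window. The two differ transiently after a latent change because
old refills legitimately remain in the window; the expected step is the
correct target for a window-based method, and the pipeline must (and does)
reproduce it exactly when text noise is off. What passing round-trip tests
show is therefore that identification, text extraction, imputation, banding,
windowing and classification are internally consistent; they cannot show
robustness to phrasings, products or data-quality failures absent from the
generator's templates — real EHR text is messier than any finite template
set.

## Test and verification sizes

The exhaustive episode oracle covers all 3,905 trajectories of ≤5 events
over steps 0–4 against a brute-force reference. Round-trip and
dwell-asymmetry checks use a 500-patient, five-year, zero-noise cohort
(~57,000 post-run-in events); band-range partition and monotonicity checks
use 1,000 random threshold triples. These sizes give stable medians and
full branch coverage while keeping the whole suite under a minute of
simulation time.

## Known limitations

* The shipped catalogue, keyword lists and band thresholds are
  reconstructions of 2019-era UK guidance; real deployments must align them
  with the local formulary and guideline vintage.
* Only the rule set described here is implemented — no general clinical
  NLP; untranslatable phrasings fall to mode imputation.
* Complex regimens cannot be distinguished from overlapping regimen
  switches inside one window.
* BNF item codes are carried through but not interpreted, and no
  asthma/COPD differential diagnosis is attempted: callers should restrict
  input to diagnosed asthma patients.
* Person-year and window conventions (anchored years; inclusive 120-day
  lookback; maximum-band aggregation) are reasonable documented choices,
  not externally fixed constants; all are overridable in configuration or
  call arguments.
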