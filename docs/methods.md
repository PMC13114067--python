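# Methods

## The instrument

The packaged instrument holds 134 descriptors: 128 scored items and 6
bonus items, organized into six categories and 29 subcategories, each
descriptor assigned to one of three forms (49 room, 51 site, 34
culture-of-care).  Descriptor IDs (`PHY-GC-01`, …) are assigned
deterministically in published order — category code, subcategory code,
ordinal — and are frozen: they are the join key between instrument,
responses, and scorecards, so they must never change across releases.

Weights are integers 1–5 for scored items.  Bonus items carry their
achievable bonus points directly as their weight, which for the
culture-of-care bonuses is 7, 7, and 10; the 1–5 range is therefore
enforced for non-bonus descriptors only.  The published table does not
mark which descriptors use yes/no scoring, so the packaged file marks
the six bonus items as binary and everything else as graded; the schema
carries `response_kind` per descriptor, so a site using a corrected
instrument file can override this without code changes.  `na_allowed`
defaults to true for every descriptor: the instrument is used across
breeding, discovery, and safety-testing facilities, and no exhaustive
list of never-NA items exists.

Structural invariants checked at load time and in tests: unique IDs,
known categories/forms/kinds, weights in range, and — in the test
suite — every subcategory maximum equal to its published value, the
non-bonus total of 884 points, and bonus totals of +5 (behavioral),
+5 (environmental), +5 (procedural), and +24 (culture of care).

## Scoring conventions

**Item points.**  A scored item earns `value x weight` (binary answers
are normalized to 0/2 on read, preserving the `2 x weight` item
maximum).  A bonus item earns its full signed weight when fully
satisfied (2/yes) and nothing otherwise; the schema supports negative
bonus signs (penalties) although the published instrument has none.

**NA renormalization.**  An NA answer removes the item from both the
achieved score and the applicable maximum.  Scoring an assessment with
an item NA is exactly equivalent to scoring against an instrument with
that item deleted (a property test asserts this).  A subcategory whose
applicable maximum is zero reports NA rather than a number.

**Pooling.**  Site items count once.  Room and survey items pool by
summed points across units: each unit's non-NA answer contributes
`value x weight` to the numerator and `2 x weight` to the denominator.
Summing, rather than averaging per-unit percentages, keeps the
denominator well defined when units have different NA patterns.  One
consequence is accepted openly: in a subcategory mixing site and room
items, adding rooms shifts weight toward the room items, so "duplicate
the same room k times" leaves per-descriptor ratios and room-only
subcategory percentages unchanged but can move a mixed subcategory's
percentage.  The property tests pin the invariant at the levels where
it holds exactly.

**Bonus pooling.**  Bonus accrual differs by form, matching how the
published scores behave: a room bonus is earned by each room that
satisfies it (three rooms with digging substrate earn +15), a site
bonus is earned once, and a survey bonus takes the rounded mean over
respondents — summing would inflate the numerator with respondent count
while the denominator stays pooled, and the published culture-of-care
bonuses never exceed the +24 instrument maximum despite 3–6 respondents
per facility.

**Aggregation and rounding.**  Category scores pool subcategory points;
the facility overall pools all six categories' points including
bonuses.  Percentages are never averaged upward.  All intermediate
arithmetic is exact integer arithmetic; the only rounding is
half-away-from-zero at the final percentage (92/96 → 96, 167/170 → 98).
Bonus points enter numerators only, so percentages above 100 are
possible; they are reported uncapped with a warning.

**Cross-facility aggregation.**  Benchmark averages are unweighted
means of facility percentages over facilities with non-NA values.
Facilities differ by orders of magnitude in animal counts, and pooling
raw points across facilities would let the largest sites dominate; the
per-descriptor within-facility pooling already accounts for room
counts.  Gap flags use strict inequality (pct < threshold, "above"
means pct > threshold) and sort ascending by percentage with
name-then-facility tie-breaks, so reports are deterministic.

## Response files and validation

The on-disk format is a long-form CSV (`facility, period, form, unit,
descriptor_id, value`) with a JSON mirror; room animal counts and
respondent demographics travel as `@`-prefixed metadata rows so the
header stays fixed.  Room and site forms are exhaustive checklists — a
missing descriptor is a located error, distinct from an explicit NA,
because the percentage denominator depends on that distinction.  A
survey question skipped by a culture-of-care respondent is read as NA
(survey non-response), and demographics default to `no_answer`.
Validation is total: every malformed record produces an error naming
the file line or facility/unit/descriptor; nothing is silently
dropped.  Round-trips through either format are lossless, NA included.

Sampling checks are advisory warnings, not errors, mirroring the
guidance under which the instrument is deployed: assess roughly 10 % of
rabbit rooms (at least 3, or all rooms if the facility has fewer; at
most 10 — the cap takes precedence over the 10 % rule at large sites)
and collect 3–6 survey responses.

## Synthetic submissions

The generator emulates complete facility submissions.  Quality is a
single parameter `q` per category in [0, 1]: each graded answer is the
sum of two independent Bernoulli(q) draws — `P(2) = q²`,
`P(1) = 2q(1−q)`, `P(0) = (1−q)²` — and each binary answer is
Bernoulli(q) scaled to {0, 2}, so every item's expected score is `2q`
and the expected percentage is `100q`, smooth and monotone in `q`
(verified by Monte-Carlo at 30 rooms and 6 respondents).  Bonus items
are satisfied with an independent `bonus_rate`, default 0 because most
sites cannot meet them; cohort generation uses 0.25 to mimic sparse
bonus uptake.  Named NA scenarios force the patterns that occur in
practice: `single_housing` (in-room social observations NA, the
social-partner item scored 0), `no_breeding` (parental items NA),
`breeding_site` (acclimation, restraint, and recovery NA — no study
procedures), `no_restraint`, and `none`.  All randomness flows from one
seed through a per-facility `SeedSequence` keyed by CRC32 of the
facility ID, so generation is reproducible across processes.

Default cohort settings — 3–10 rooms, 3–6 respondents per facility,
quality spanning 0.6–0.95 — follow the deployment guidance and produce
overall scores spread across roughly the band observed in practice.
What the generator does **not** model: rater disagreement and observer
bias, correlation between items within a room, or drift between
periods.  Passing tests on synthetic data therefore demonstrate the
arithmetic and plumbing, not the psychometric behavior of the
instrument on real facilities.

`generate_to_target` inverts scoring exactly: per subcategory it
enumerates the achievable point grid (a suffix-reachability dynamic
program over items in ID order), picks the largest total whose rounded
percentage equals the target, and assigns values greedily (higher
values first) with the reachability table guaranteeing completion —
fully deterministic.  Requests off the grid raise
`InfeasibleTargetError` (a single weight-3 item can only score 0, 50,
or 100).  `generate_to_points` is the same solver addressed in achieved
points, which is how published decompositions are stated.

## Reproduction choices

The raw facility responses behind the published results are not
available, so reproductions rebuild minimal assessments that realize
the published decompositions: the behavioral row (20/24 + full marks +
parental NA → 96 %) and the environmental row (68 + 86 + 8/16 + bonus 5
over 170 → 98 %) pin the NA and bonus semantics.  The global physical
average (97 %) is the rounded mean of the twelve published Q1 facility
percentages, each realized as a concrete assessment before averaging;
the percentage 99 is not on the single-room physical grid (it would
require shedding exactly one point, and no weight allows that), so that
facility is reconstructed with two rooms.  The feeding-behavior
improvement (74 % → 87 %, +13 points) is recomputed by pooling the
feeding item over all assessed rooms of each period — 31 rooms, then
23 — because the published period averages for that subcategory are
point-pooled rather than facility-averaged (the facility-percentage
mean is ~91, which no parse of the published table reconciles with 74).
Problem sizes throughout (single-room reconstructions, 1000-assessment
oracle sweeps, 30-room Monte-Carlo) were chosen as the smallest sizes
that make each check exact or statistically stable; everything runs in
seconds on one CPU.

## Known limitations

* The overall facility score pools all six categories, including the
  culture-of-care survey, with animal-facing categories; whether the
  published overall figure includes the survey is not stated, so
  consumers who want an animal-facing-only figure should pool the five
  category scores themselves.
* One published subcategory cell (a pain-assessment value of 200) is
  arithmetically impossible under the scoring rule and is treated as a
  typo.
* The published period averages mix two aggregations (facility means
  for most categories, point-pooling for at least one subcategory);
  this package exposes the facility-mean path as the default
  (`global_average`) and leaves point-pooling to an explicit pooled
  pseudo-facility construction.
* English instrument text only; translation workflows are out of scope.
* The tool scores programs, not individual animals — severity and
  cumulative-use assessment are outside its design.
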