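# rabbitwat

A scoring engine and benchmarking toolkit for the **rabbit welfare
assessment tool** — a weighted, 134-descriptor audit instrument used to
evaluate the welfare of rabbits kept in research and commercial breeding
facilities.

Welfare assessment tools turn expert criteria into numbers so that
facilities can find weaknesses in their animal-management programs,
compare themselves against peers, and track improvement over time.  This
package is for animal-welfare scientists, facility behavior/welfare
staff, and program managers who need the scoring arithmetic to be exact,
auditable, and reproducible rather than buried in spreadsheet formulas.

## The instrument and its scoring model

The instrument has six categories — physical, behavioral, environmental,
training, procedural, and culture of care — each divided into named
subcategories (e.g. *Housing* within environmental).  Assessment happens
on three forms:

* **room** — animal- and resource-based observations in the animals'
  home rooms (one record per assessed room);
* **site** — facility-level protocols and programs (one record);
* **coc** — an anonymous culture-of-care survey of staff working with
  the animals (one record per respondent).

Each descriptor $i$ carries a welfare weight $w_i \in \{1,\dots,5\}$ and
is scored $s_i \in \{0, 1, 2\}$ (never/sometimes/always; binary items
map yes → 2, no → 0), or **NA** when it cannot apply (e.g. parental
behavior at a non-breeding site).  A subcategory's percentage is

$$\text{pct} = \operatorname{round}\!\left(100 \cdot
\frac{\sum_{i \in \text{applicable}} s_i\, w_i}
     {\sum_{i \in \text{applicable}} 2\, w_i}\right),$$

with NA items excluded from numerator **and** denominator (NA
renormalization), rounding half away from zero, and multi-unit forms
pooled by summed points.  **Bonus items** reward practices few sites can
offer (digging substrate, remote video monitoring, …): a satisfied bonus
adds its full weight to the numerator only, so a category score can
exceed 100 %.  Category and overall scores pool raw points, never
average percentages.  The packaged instrument's subcategory maxima (46
for *General condition*, 86 for *Resources*, …; 884 non-bonus points in
total, plus bonus headroom of +5/+5/+5/+24) are validated against the
published totals in the test suite.

Benchmarking reports aggregate scorecards across facilities (unweighted
mean of facility percentages, NA-excluded), compute period-over-period
deltas, flag entries below a threshold, and attach the published
per-category improvement recommendations.

A synthetic-submission generator produces complete facility submissions
with a tunable quality level, realistic NA scenarios (single housing,
no breeding, breeding-only sites, no restraint), and an exact
target-inversion mode that builds an assessment scoring any feasible
percentage — this is how the published worked examples are reproduced
without access to the raw (unpublished) facility responses.

## Worked example

```bash
$ rabbitwat generate -o responses.csv -n 3 --seed 42
wrote 3 synthetic facility submission(s) to responses.csv
$ rabbitwat score -r responses.csv -o scores
FAC-01 Q1: overall 61% (2748/4478 points)
FAC-02 Q1: overall 76% (3030/3994 points)
FAC-03 Q1: overall 96% (2303/2392 points)
$ rabbitwat benchmark -r responses.csv -o bench --threshold 80
benchmarked 3 facilities over 1 period(s); 57 entries below 80%
```

`FAC-01` was generated at low quality: it earned 2748 of its 4478
applicable points, so its overall score is 61 %.  The denominator
differs between facilities because they assessed different numbers of
rooms and respondents and have different NA patterns.  Each
`scores/scorecard_*.json` holds the full decomposition, e.g. FAC-01's
behavioral category:

```json
{"name": "behavioral", "achieved": 330, "max": 588, "bonus": 0, "pct": 56}
```

From the Python API, the published facility-A behavioral row — 20/24 on
behavioral assessments, full marks on normal (22), social (42), and
feeding (8) behavior, parental behavior entirely NA — scores

```python
>>> import rabbitwat as rw
>>> inst = rw.load_instrument()
>>> fa = rw.generate_to_points(
...     {"Behavioral assessments": 20, "Parental behavior": None}, inst)
>>> cat = rw.score_facility(fa, inst).category("behavioral")
>>> cat.achieved, cat.max_applicable, cat.pct
(92, 96, 96)
```

92/96 = 95.83 % rounds to 96, with the 12 parental points absent from
both sides of the fraction.

## Layout

| Module | Purpose |
| --- | --- |
| `rabbitwat.instrument` | descriptor schema, packaged instrument, structural maxima |
| `rabbitwat.responses`  | CSV/JSON response I/O, validation, sampling-guidance checks |
| `rabbitwat.scoring`    | item points, unit pooling, NA renormalization, scorecards |
| `rabbitwat.benchmark`  | cross-facility averages, deltas, gap flags, recommendations |
| `rabbitwat.synthetic`  | seeded submission generator and exact target inversion |
| `rabbitwat.cli`        | `rabbitwat validate / score / benchmark / generate / report` |

See `docs/methods.md` for the scoring conventions, generator model, and
design decisions in detail.
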