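"""Deterministic scoring: item points, unit pooling, and NA-renormalized
percentages at subcategory, category, and facility level.

Scoring follows the instrument's weighted-checklist rule.  A graded item
contributes ``score x weight`` points toward a maximum of ``2 x weight``;
an item answered NA is excluded from the achieved score *and* the
maximum, so percentages stay comparable between facilities with different
applicable item sets (a breeding site and a safety-testing site are not
penalized for what cannot apply to them).  Bonus items add their listed
weight to the achieved score when satisfied and never enter a maximum,
which is why a category percentage can exceed 100.

Room and culture-of-care forms may have several units (rooms,
respondents); their points are pooled by summation, with each unit's
applicable items enlarging the denominator, rather than by averaging
per-unit percentages — units with different NA patterns would otherwise
make the denominator ill-defined.  Bonus pooling differs by form to match
how bonuses accrue in practice: room bonuses sum over assessed rooms
(each room with, e.g., digging substrate earns the bonus), site bonuses
count once, and survey bonuses take the rounded mean over respondents.

Percentages are integers, rounded half away from zero at the final step
only; all intermediate arithmetic is exact integer arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .instrument import Descriptor, Instrument
from .responses import NA, FacilityAssessment, Value


def round_half_away(numerator: int, denominator: int) -> int:
    """round(100 * numerator / denominator) with halves away from zero."""
    if denominator <= 0:
        raise ZeroDivisionError("denominator must be positive")
    n = 100 * numerator
    if n >= 0:
        return (2 * n + denominator) // (2 * denominator)
    return -((-2 * n + denominator) // (2 * denominator))


@dataclass(frozen=True)
class SubcategoryScore:
    name: str
    achieved: int
    max_applicable: int
    bonus: int = 0

    @property
    def pct(self) -> int | None:
        """Integer percentage, or None when every item was NA."""
        if self.max_applicable == 0:
            return None
        return round_half_away(self.achieved + self.bonus, self.max_applicable)


@dataclass(frozen=True)
class CategoryScore:
    name: str
    subcategories: tuple[SubcategoryScore, ...]
    bonus: int = 0

    @property
    def achieved(self) -> int:
        return sum(s.achieved for s in self.subcategories)

    @property
    def max_applicable(self) -> int:
        return sum(s.max_applicable for s in self.subcategories)

    @property
    def pct(self) -> int | None:
        if self.max_applicable == 0:
            return None
        return round_half_away(self.achieved + self.bonus, self.max_applicable)


@dataclass(frozen=True)
class FacilityScorecard:
    facility_id: str
    period: str
    categories: tuple[CategoryScore, ...]

    @property
    def overall_achieved(self) -> int:
        return sum(c.achieved + c.bonus for c in self.categories)

    @property
    def overall_max(self) -> int:
        return sum(c.max_applicable for c in self.categories)

    @property
    def overall_pct(self) -> int | None:
        """Facility percentage pooled from raw points of all six categories
        (achieved + bonus over applicable maximum), not a mean of category
        percentages."""
        if self.overall_max == 0:
            return None
        return round_half_away(self.overall_achieved, self.overall_max)

    def category(self, name: str) -> CategoryScore:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(f"no category {name!r} in scorecard")

    def subcategory(self, category: str, name: str) -> SubcategoryScore:
        for s in self.category(category).subcategories:
            if s.name == name:
                return s
        raise KeyError(f"no subcategory {name!r} in {category}")

    def to_dict(self) -> dict:
        return {
            "facility_id": self.facility_id,
            "period": self.period,
            "overall": {
                "achieved": self.overall_achieved,
                "max": self.overall_max,
                "pct": self.overall_pct,
            },
            "categories": [
                {
                    "name": c.name,
                    "achieved": c.achieved,
                    "max": c.max_applicable,
                    "bonus": c.bonus,
                    "pct": c.pct,
                    "subcategories": [
                        {
                            "name": s.name,
                            "achieved": s.achieved,
                            "max": s.max_applicable,
                            "pct": s.pct,
                        }
                        for s in c.subcategories
                    ],
                }
                for c in self.categories
            ],
        }

    def warnings(self) -> list[str]:
        out = []
        for c in self.categories:
            if c.pct is not None and c.pct > 100:
                out.append(
                    f"{self.facility_id}/{self.period}: category {c.name} "
                    f"exceeds 100% ({c.pct}%) through bonus points"
                )
        return out


def item_points(value: Value, descriptor: Descriptor) -> int | None:
    """Points earned by one answer, or None for NA (excluded everywhere).

    Graded/binary non-bonus items earn ``value x weight`` (binary answers
    arrive normalized to 0/2).  A bonus item earns its full signed weight
    when fully satisfied (2 / yes) and nothing otherwise.
    """
    if value is NA:
        return None
    if descriptor.is_bonus:
        return descriptor.weight * descriptor.bonus_sign if value == 2 else 0
    return value * descriptor.weight


def pool_units(
    values: Iterable[Value], descriptor: Descriptor
) -> tuple[int, int]:
    """Pool one descriptor's answers across units (rooms or respondents).

    Returns ``(achieved, max_contribution)`` where the maximum counts
    ``2 x weight`` per unit with a non-NA answer; all-NA contributes
    nothing.  Not used for bonus items (their maximum is always 0).
    """
    achieved = 0
    n_applicable = 0
    for v in values:
        pts = item_points(v, descriptor)
        if pts is None:
            continue
        achieved += pts
        n_applicable += 1
    if descriptor.is_bonus:
        return achieved, 0
    return achieved, n_applicable * 2 * descriptor.weight


def _unit_values(
    assessment: FacilityAssessment, descriptor: Descriptor
) -> list[Value]:
    if descriptor.form == "site":
        return [assessment.site.values.get(descriptor.id, NA)]
    if descriptor.form == "room":
        return [r.values.get(descriptor.id, NA) for r in assessment.rooms]
    return [c.values.get(descriptor.id, NA) for c in assessment.coc]


def score_subcategory(
    assessment: FacilityAssessment, instrument: Instrument, subcategory: str
) -> SubcategoryScore:
    """Score one non-bonus subcategory, pooling site items once and
    room/survey items across their units."""
    items = instrument.select(subcategory=subcategory, bonus=False)
    if not items:
        raise KeyError(f"unknown subcategory {subcategory!r}")
    achieved = 0
    max_applicable = 0
    for d in items:
        a, m = pool_units(_unit_values(assessment, d), d)
        achieved += a
        max_applicable += m
    return SubcategoryScore(
        name=subcategory, achieved=achieved, max_applicable=max_applicable
    )


def category_bonus(
    assessment: FacilityAssessment, instrument: Instrument, category: str
) -> int:
    """Bonus points accrued in a category.

    Site bonuses count once, room bonuses sum over rooms, and survey
    bonuses take the rounded mean over respondents (a per-respondent sum
    would inflate the numerator without touching the pooled denominator).
    """
    total = 0
    for d in instrument.select(category=category, bonus=True):
        unit_pts = [
            p for p in (item_points(v, d) for v in _unit_values(assessment, d))
            if p is not None
        ]
        if not unit_pts:
            continue
        if d.form == "coc":
            s = sum(unit_pts)
            # rounded mean, half away from zero
            total += round_half_away(s, 100 * len(unit_pts))
        else:
            total += sum(unit_pts)
    return total


def score_category(
    assessment: FacilityAssessment, instrument: Instrument, category: str
) -> CategoryScore:
    """Score one category: subcategory points pooled, bonus added to the
    numerator only."""
    subs = tuple(
        score_subcategory(assessment, instrument, sub)
        for _, sub in instrument.subcategories(category)
    )
    if not subs:
        raise KeyError(f"unknown category {category!r}")
    return CategoryScore(
        name=category,
        subcategories=subs,
        bonus=category_bonus(assessment, instrument, category),
    )


def score_facility(
    assessment: FacilityAssessment, instrument: Instrument
) -> FacilityScorecard:
    """Full scorecard for one facility-period: six category scores and the
    overall percentage pooled from raw points."""
    return FacilityScorecard(
        facility_id=assessment.facility_id,
        period=assessment.period,
        categories=tuple(
            score_category(assessment, instrument, cat)
            for cat in instrument.categories
        ),
    )


def write_scorecard_json(scorecard: FacilityScorecard, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(scorecard.to_dict(), indent=1), encoding="utf-8")
    return path


def write_scorecard_csv(scorecard: FacilityScorecard, path: str | Path) -> Path:
    """Long-form CSV: facility, period, level, category, name, achieved,
    max, bonus, pct."""
    import csv as _csv

    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = _csv.writer(fh)
        w.writerow(
            ["facility", "period", "level", "category", "name",
             "achieved", "max", "bonus", "pct"]
        )

        def fmt(p):
            return "NA" if p is None else p

        w.writerow(
            [scorecard.facility_id, scorecard.period, "overall", "", "overall",
             scorecard.overall_achieved, scorecard.overall_max, "",
             fmt(scorecard.overall_pct)]
        )
        for c in scorecard.categories:
            w.writerow(
                [scorecard.facility_id, scorecard.period, "category", c.name,
                 c.name, c.achieved, c.max_applicable, c.bonus, fmt(c.pct)]
            )
            for s in c.subcategories:
                w.writerow(
                    [scorecard.facility_id, scorecard.period, "subcategory",
                     c.name, s.name, s.achieved, s.max_applicable, 0, fmt(s.pct)]
                )
    return path
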