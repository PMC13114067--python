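"""Shared fixtures and an independent brute-force scoring oracle.

The oracle recomputes every percentage with plain loops and exact
fractions, independently of the engine's pooling/rounding code paths, so
engine-vs-oracle agreement is a meaningful check.
"""

from __future__ import annotations

import copy
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rabbitwat import (
    CoCResponse,
    FacilityAssessment,
    RoomAssessment,
    SiteAssessment,
    load_instrument,
)
from rabbitwat.responses import NA


@pytest.fixture(scope="session")
def instrument():
    return load_instrument()


def uniform_assessment(
    instrument,
    value=2,
    *,
    facility_id="FAC",
    period="Q1",
    n_rooms=1,
    n_respondents=1,
    bonus_value=0,
):
    """Assessment with every non-bonus item at ``value`` and every bonus
    item at ``bonus_value``."""

    def v(d):
        return bonus_value if d.is_bonus else value

    rooms = [
        RoomAssessment(
            room_id=f"R{i+1:02d}",
            n_animals=10,
            values={d.id: v(d) for d in instrument.select(form="room")},
        )
        for i in range(n_rooms)
    ]
    site = SiteAssessment(
        values={d.id: v(d) for d in instrument.select(form="site")}
    )
    coc = [
        CoCResponse(
            respondent_id=f"P{i+1:02d}",
            values={d.id: v(d) for d in instrument.select(form="coc")},
        )
        for i in range(n_respondents)
    ]
    return FacilityAssessment(
        facility_id=facility_id, period=period, rooms=rooms, site=site, coc=coc
    )


def random_assessment(instrument, rng, *, na_rate=0.15, max_units=3):
    """Small random assessment over the full value domain including NA."""

    def draw(d):
        if d.na_allowed and rng.random() < na_rate:
            return NA
        if d.response_kind == "binary":
            return int(rng.choice([0, 2]))
        return int(rng.integers(0, 3))

    n_rooms = int(rng.integers(1, max_units + 1))
    n_resp = int(rng.integers(1, max_units + 1))
    rooms = [
        RoomAssessment(
            room_id=f"R{i+1}",
            n_animals=int(rng.integers(1, 50)),
            values={d.id: draw(d) for d in instrument.select(form="room")},
        )
        for i in range(n_rooms)
    ]
    site = SiteAssessment(
        values={d.id: draw(d) for d in instrument.select(form="site")}
    )
    coc = [
        CoCResponse(
            respondent_id=f"P{i+1}",
            values={d.id: draw(d) for d in instrument.select(form="coc")},
        )
        for i in range(n_resp)
    ]
    return FacilityAssessment(
        facility_id="RND", period="Q1", rooms=rooms, site=site, coc=coc
    )


# ---------------------------------------------------------------- oracle

def _round_half_away_float(x: Fraction) -> int:
    if x >= 0:
        return math.floor(x + Fraction(1, 2))
    return -math.floor(-x + Fraction(1, 2))


def _oracle_units(assessment, d):
    if d.form == "site":
        return [assessment.site.values.get(d.id, NA)]
    if d.form == "room":
        return [r.values.get(d.id, NA) for r in assessment.rooms]
    return [c.values.get(d.id, NA) for c in assessment.coc]


def oracle_scorecard(assessment, instrument):
    """Brute-force recomputation of every percentage.

    Returns nested dict: {category: {"pct": .., "bonus": ..,
    "subs": {name: pct}}} plus "overall".
    """
    out = {}
    grand_num = 0
    grand_den = 0
    for cat in instrument.categories:
        cat_num = 0
        cat_den = 0
        subs = {}
        for d_cat, sub in instrument.subcategories(cat):
            num = 0
            den = 0
            for d in instrument:
                if d.subcategory != sub or d.is_bonus or d.category != cat:
                    continue
                for v in _oracle_units(assessment, d):
                    if v is NA:
                        continue
                    num += v * d.weight
                    den += 2 * d.weight
            subs[sub] = (
                None if den == 0
                else _round_half_away_float(Fraction(100 * num, den))
            )
            cat_num += num
            cat_den += den
        bonus = 0
        for d in instrument:
            if not d.is_bonus or d.category != cat:
                continue
            unit_pts = [
                d.weight * d.bonus_sign if v == 2 else 0
                for v in _oracle_units(assessment, d)
                if v is not NA
            ]
            if not unit_pts:
                continue
            if d.form == "coc":
                bonus += _round_half_away_float(
                    Fraction(sum(unit_pts), len(unit_pts))
                )
            else:
                bonus += sum(unit_pts)
        out[cat] = {
            "pct": (
                None if cat_den == 0
                else _round_half_away_float(Fraction(100 * (cat_num + bonus), cat_den))
            ),
            "bonus": bonus,
            "subs": subs,
        }
        grand_num += cat_num + bonus
        grand_den += cat_den
    out["overall"] = (
        None if grand_den == 0
        else _round_half_away_float(Fraction(100 * grand_num, grand_den))
    )
    return out


def assert_matches_oracle(card, assessment, instrument):
    expected = oracle_scorecard(assessment, instrument)
    assert card.overall_pct == expected["overall"]
    for c in card.categories:
        exp = expected[c.name]
        assert c.bonus == exp["bonus"], c.name
        assert c.pct == exp["pct"], c.name
        for s in c.subcategories:
            assert s.pct == exp["subs"][s.name], (c.name, s.name)
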