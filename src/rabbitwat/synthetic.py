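"""Synthetic facility submissions with controlled quality and NA structure.

Real submissions are not published, so everything downstream is exercised
on generated ones.  A facility profile fixes a quality level ``q`` per
category; each graded answer is drawn as the sum of two independent
Bernoulli(q) draws, ``P(2) = q^2``, ``P(1) = 2q(1-q)``, ``P(0) = (1-q)^2``,
so the expected item score is ``2q`` and the expected percentage rises
smoothly and monotonically with ``q``.  Binary answers are Bernoulli(q)
on the same scale.  Bonus items are satisfied with an independent rate
(default 0: most sites cannot meet them).

Named NA scenarios mirror situations where parts of the instrument cannot
apply: single housing (social observations impossible, and the
social-partner item scored 0), sites without breeding (parental items
NA), breeding sites (no study procedures: acclimation, restraint,
recovery NA), and sites that never restrain animals.

:func:`generate_to_target` inverts the scoring rule: it builds an
assessment whose subcategory percentages equal requested values exactly,
solving the integer point grid per subcategory with a deterministic
dynamic program.  Targets that the grid cannot express raise
:class:`InfeasibleTargetError`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .instrument import Instrument
from .responses import (
    NA,
    CoCResponse,
    FacilityAssessment,
    GENDERS,
    RoomAssessment,
    SiteAssessment,
    TENURE_BANDS,
    Value,
)
from .scoring import round_half_away

#: Descriptor ids forced to NA (or 0) by each named scenario.
NA_PATTERNS: dict[str, dict[str, tuple[str, ...]]] = {
    "none": {"na": (), "zero": ()},
    # Singly housed animals: social behavior cannot be observed in-room,
    # and the social-partner item must be scored 0, not NA.
    "single_housing": {
        "na": ("BEH-SB-05", "BEH-SB-06", "BEH-SB-07"),
        "zero": ("BEH-SB-04",),
    },
    # No breeding at the site: parental behavior is not observable.
    "no_breeding": {"na": ("BEH-PB-01", "BEH-PB-02"), "zero": ()},
    # Commercial breeding site: no study procedures, so acclimation,
    # restraint, and recovery do not apply.
    "breeding_site": {
        "na": ("TRN-ACC-01", "PRC-RST-01", "PRC-RST-02", "PRC-RST-03",
               "PRC-RST-04", "PRC-RCV-01"),
        "zero": (),
    },
    # Animals are never restrained in devices.
    "no_restraint": {
        "na": ("PRC-RST-01", "PRC-RST-02", "PRC-RST-03", "PRC-RST-04",
               "TRN-AC-03"),
        "zero": (),
    },
}


class InfeasibleTargetError(ValueError):
    """A requested percentage is not on the subcategory's point grid."""


@dataclass(frozen=True)
class FacilityProfile:
    """Generation parameters for one synthetic facility."""

    facility_id: str = "FAC-01"
    target_quality: float | Mapping[str, float] = 0.8
    na_pattern: str = "none"
    n_rooms: int = 3
    n_respondents: int = 4
    seed: int = 0
    bonus_rate: float = 0.0

    def quality(self, category: str) -> float:
        q = (
            self.target_quality.get(category, 0.8)
            if isinstance(self.target_quality, Mapping)
            else self.target_quality
        )
        if not 0.0 <= q <= 1.0:
            raise ValueError(f"target_quality must be in [0, 1], got {q}")
        return q


def _draw_value(
    rng: np.random.Generator, kind: str, q: float, is_bonus: bool,
    bonus_rate: float,
) -> int:
    if is_bonus:
        return 2 if rng.random() < bonus_rate else 0
    if kind == "binary":
        return 2 if rng.random() < q else 0
    r = rng.random()
    if r < q * q:
        return 2
    if r < q * q + 2 * q * (1 - q):
        return 1
    return 0


def generate_facility(
    profile: FacilityProfile,
    instrument: Instrument,
    period: str = "Q1",
) -> FacilityAssessment:
    """Draw one complete facility submission from a profile.

    Fully reproducible: the same profile (including seed) yields the same
    assessment.
    """
    if profile.na_pattern not in NA_PATTERNS:
        raise ValueError(
            f"unknown na_pattern {profile.na_pattern!r}; "
            f"choose from {sorted(NA_PATTERNS)}"
        )
    if not 0.0 <= profile.bonus_rate <= 1.0:
        raise ValueError("bonus_rate must be in [0, 1]")
    pattern = NA_PATTERNS[profile.na_pattern]
    forced_na, forced_zero = set(pattern["na"]), set(pattern["zero"])
    # crc32 keeps the stream deterministic across processes (str.hash is not)
    rng = np.random.default_rng(
        np.random.SeedSequence(
            entropy=profile.seed,
            spawn_key=(zlib.crc32(profile.facility_id.encode()),),
        )
    )

    def value_for(d) -> Value:
        if d.id in forced_na:
            return NA
        if d.id in forced_zero:
            return 0
        return _draw_value(
            rng, d.response_kind, profile.quality(d.category), d.is_bonus,
            profile.bonus_rate,
        )

    rooms = []
    room_items = instrument.select(form="room")
    for i in range(profile.n_rooms):
        rooms.append(
            RoomAssessment(
                room_id=f"R{i + 1:02d}",
                n_animals=int(rng.integers(8, 400)),
                values={d.id: value_for(d) for d in room_items},
            )
        )
    site = SiteAssessment(
        values={d.id: value_for(d) for d in instrument.select(form="site")}
    )
    coc_items = instrument.select(form="coc")
    coc = []
    for i in range(profile.n_respondents):
        coc.append(
            CoCResponse(
                respondent_id=f"P{i + 1:02d}",
                gender=str(rng.choice(GENDERS)),
                tenure_band=str(rng.choice(TENURE_BANDS[:4])),
                values={d.id: value_for(d) for d in coc_items},
            )
        )
    return FacilityAssessment(
        facility_id=profile.facility_id, period=period,
        rooms=rooms, site=site, coc=coc,
    )


def feasible_percentages(instrument: Instrument, subcategory: str) -> set[int]:
    """All integer percentages a subcategory can score with every item
    applicable (the achievable point grid, rounded)."""
    items = instrument.select(subcategory=subcategory, bonus=False)
    if not items:
        raise KeyError(f"unknown subcategory {subcategory!r}")
    total = sum(2 * d.weight for d in items)
    return {
        round_half_away(a, total) for a in _achievable_sums(items)
    }


def _achievable_sums(items) -> set[int]:
    sums = {0}
    for d in items:
        steps = (0, 2 * d.weight) if d.response_kind == "binary" \
            else (0, d.weight, 2 * d.weight)
        sums = {s + step for s in sums for step in steps}
    return sums


def _suffix_reachable(items) -> list[set[int]]:
    """suffix[i] = point sums achievable from items[i:] (items pre-sorted)."""
    suffix: list[set[int]] = [set() for _ in range(len(items) + 1)]
    suffix[len(items)] = {0}
    for i in range(len(items) - 1, -1, -1):
        d = items[i]
        steps = (0, 2 * d.weight) if d.response_kind == "binary" \
            else (0, d.weight, 2 * d.weight)
        suffix[i] = {s + step for s in suffix[i + 1] for step in steps}
    return suffix


def _assign_points(items, achieved: int) -> dict[str, int]:
    """Deterministic greedy assignment of item values summing to
    ``achieved`` points, in descriptor-id order, preferring higher values;
    a reachability table guarantees completion."""
    items = sorted(items, key=lambda d: d.id)
    suffix = _suffix_reachable(items)
    if achieved not in suffix[0]:
        raise InfeasibleTargetError(
            f"{achieved} points not on the achievable grid "
            f"(max {sum(2 * d.weight for d in items)})"
        )
    remaining = achieved
    values: dict[str, int] = {}
    for i, d in enumerate(items):
        options = (2, 0) if d.response_kind == "binary" else (2, 1, 0)
        for v in options:
            pts = v * d.weight
            if remaining - pts in suffix[i + 1]:
                values[d.id] = v
                remaining -= pts
                break
    return values


def _solve_subcategory(items, target: int) -> dict[str, int]:
    """Assign item values reproducing ``target`` percent exactly: picks the
    largest achievable point total that rounds to the target."""
    items = sorted(items, key=lambda d: d.id)
    total = sum(2 * d.weight for d in items)
    reachable = _suffix_reachable(items)[0]
    candidates = [a for a in reachable if round_half_away(a, total) == target]
    if not candidates:
        grid = sorted({round_half_away(a, total) for a in reachable})
        raise InfeasibleTargetError(
            f"{target}% is not achievable on this subcategory "
            f"(max {total} points; achievable percentages: {grid})"
        )
    return _assign_points(items, max(candidates))


def _solve_bonus(items, target: int) -> dict[str, int]:
    items = sorted(items, key=lambda d: d.id)
    suffix: list[set[int]] = [set() for _ in range(len(items) + 1)]
    suffix[len(items)] = {0}
    for i in range(len(items) - 1, -1, -1):
        w = items[i].weight * items[i].bonus_sign
        suffix[i] = {s + step for s in suffix[i + 1] for step in (0, w)}
    if target not in suffix[0]:
        raise InfeasibleTargetError(
            f"bonus target {target} not a sum of bonus weights "
            f"{[d.weight * d.bonus_sign for d in items]}"
        )
    remaining = target
    values = {}
    for i, d in enumerate(items):
        w = d.weight * d.bonus_sign
        if remaining - w in suffix[i + 1]:
            values[d.id] = 2
            remaining -= w
        else:
            values[d.id] = 0
    return values


def _solve_all(
    subcategory_spec: Mapping[str, int | None],
    instrument: Instrument,
    bonus_targets: Mapping[str, int] | None,
    *,
    as_points: bool,
) -> dict[str, Value]:
    known = {sub for _, sub in instrument.subcategories()}
    unknown = set(subcategory_spec) - known
    if unknown:
        raise KeyError(f"unknown subcategories: {sorted(unknown)}")
    values: dict[str, Value] = {}
    for _, sub in instrument.subcategories():
        items = instrument.select(subcategory=sub, bonus=False)
        full = sum(2 * d.weight for d in items) if as_points else 100
        target = subcategory_spec.get(sub, full)
        if target is None:
            values.update({d.id: NA for d in items})
        elif as_points:
            values.update(_assign_points(items, target))
        else:
            if not 0 <= target <= 100:
                raise InfeasibleTargetError(
                    f"{sub}: target {target} outside [0, 100]"
                )
            values.update(_solve_subcategory(items, target))
    bonus_targets = dict(bonus_targets or {})
    for cat in instrument.categories:
        items = instrument.select(category=cat, bonus=True)
        values.update(_solve_bonus(items, bonus_targets.pop(cat, 0)))
    if bonus_targets:
        raise KeyError(f"unknown bonus categories: {sorted(bonus_targets)}")
    return values


def _assemble(
    values: Mapping[str, Value],
    instrument: Instrument,
    seed: int,
    facility_id: str,
    period: str,
) -> FacilityAssessment:
    rng = np.random.default_rng(seed)
    room = RoomAssessment(
        room_id="R01",
        n_animals=int(rng.integers(8, 400)),
        values={d.id: values[d.id] for d in instrument.select(form="room")},
    )
    site = SiteAssessment(
        values={d.id: values[d.id] for d in instrument.select(form="site")}
    )
    resp = CoCResponse(
        respondent_id="P01",
        values={d.id: values[d.id] for d in instrument.select(form="coc")},
    )
    return FacilityAssessment(
        facility_id=facility_id, period=period, rooms=[room], site=site,
        coc=[resp],
    )


def generate_to_target(
    subcategory_targets: Mapping[str, int | None],
    instrument: Instrument,
    seed: int = 0,
    bonus_targets: Mapping[str, int] | None = None,
    facility_id: str = "TARGET",
    period: str = "Q1",
) -> FacilityAssessment:
    """Build a one-room, one-respondent assessment whose scored subcategory
    percentages equal the targets exactly.

    ``subcategory_targets`` maps subcategory name to an integer percentage
    or ``None`` for all-NA; unmentioned subcategories score 100.
    ``bonus_targets`` maps category name to bonus points (default: no
    bonus satisfied).  Raises :class:`InfeasibleTargetError` when a target
    is not on the subcategory's achievable point grid.
    """
    values = _solve_all(
        subcategory_targets, instrument, bonus_targets, as_points=False
    )
    return _assemble(values, instrument, seed, facility_id, period)


def generate_to_points(
    subcategory_points: Mapping[str, int | None],
    instrument: Instrument,
    seed: int = 0,
    bonus_targets: Mapping[str, int] | None = None,
    facility_id: str = "TARGET",
    period: str = "Q1",
) -> FacilityAssessment:
    """Like :func:`generate_to_target` but in achieved points per
    subcategory (``None`` for all-NA; unmentioned subcategories take full
    marks).  Useful when reproducing published score decompositions stated
    in points rather than percentages."""
    values = _solve_all(
        subcategory_points, instrument, bonus_targets, as_points=True
    )
    return _assemble(values, instrument, seed, facility_id, period)


def generate_cohort(
    n_facilities: int,
    instrument: Instrument,
    quality_range: tuple[float, float] = (0.6, 0.95),
    seed: int = 0,
    period: str = "Q1",
    bonus_rate: float = 0.25,
) -> list[FacilityAssessment]:
    """Reproducible cohort of facilities spanning a quality range, with
    varied room counts, respondent counts, and NA scenarios."""
    if n_facilities < 1:
        raise ValueError("n_facilities must be >= 1")
    lo, hi = quality_range
    qualities = (
        np.linspace(lo, hi, n_facilities) if n_facilities > 1
        else np.array([(lo + hi) / 2])
    )
    rng = np.random.default_rng(seed)
    patterns = sorted(NA_PATTERNS)
    cohort = []
    for i, q in enumerate(qualities):
        profile = FacilityProfile(
            facility_id=f"FAC-{i + 1:02d}",
            target_quality=float(q),
            na_pattern=patterns[int(rng.integers(len(patterns)))],
            n_rooms=int(rng.integers(3, 11)),
            n_respondents=int(rng.integers(3, 7)),
            seed=int(rng.integers(2**31)),
            bonus_rate=bonus_rate,
        )
        cohort.append(generate_facility(profile, instrument, period=period))
    return cohort
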