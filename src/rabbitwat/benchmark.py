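"""Cross-facility benchmarking: global averages, longitudinal deltas,
gap flagging, and category-level improvement recommendations.

Facilities differ enormously in size, so cross-facility aggregation uses
the unweighted mean of facility percentages (NA-excluded) rather than
pooling raw points, which would let the largest sites dominate.  Deltas
compare the same facility across two assessment periods and propagate NA.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .instrument import CATEGORIES, Instrument
from .scoring import FacilityScorecard, round_half_away


def mean_pct(values: Sequence[int]) -> int:
    """Unweighted mean of integer percentages, rounded half away from zero."""
    if not values:
        raise ValueError("mean of no values")
    return round_half_away(sum(values), 100 * len(values))


def _lookup(card: FacilityScorecard, level: str, name: str) -> int | None:
    if level == "overall":
        return card.overall_pct
    if level == "category":
        return card.category(name).pct
    if level == "subcategory":
        for c in card.categories:
            for s in c.subcategories:
                if s.name == name:
                    return s.pct
        raise KeyError(f"no subcategory {name!r}")
    raise ValueError(f"unknown level {level!r}")


def global_average(
    scorecards: Iterable[FacilityScorecard],
    level: str,
    name: str,
    period: str,
) -> int:
    """Mean of facility percentages for one level/name in one period,
    over facilities with a non-NA value."""
    values = [
        pct
        for card in scorecards
        if card.period == period
        and (pct := _lookup(card, level, name)) is not None
    ]
    if not values:
        raise ValueError(f"no data for {level}/{name} in period {period!r}")
    return mean_pct(values)


def period_delta(
    scorecards: Iterable[FacilityScorecard],
    facility: str,
    level: str,
    name: str,
    periods: tuple[str, str] | None = None,
) -> int | None:
    """Later-minus-earlier change in percentage points for one facility.

    ``periods`` defaults to the two periods present for the facility, in
    sorted order.  Returns None when either period's value is NA.
    """
    cards = {c.period: c for c in scorecards if c.facility_id == facility}
    if periods is None:
        if len(cards) != 2:
            raise ValueError(
                f"facility {facility!r} has {len(cards)} period(s); "
                f"pass periods explicitly"
            )
        periods = tuple(sorted(cards))  # type: ignore[assignment]
    earlier, later = periods
    if earlier not in cards or later not in cards:
        raise ValueError(f"facility {facility!r} missing a period in {periods}")
    a = _lookup(cards[earlier], level, name)
    b = _lookup(cards[later], level, name)
    if a is None or b is None:
        return None
    return b - a


@dataclass(frozen=True)
class GapFlag:
    facility: str
    period: str
    level: str
    name: str
    pct: int


@dataclass
class BenchmarkReport:
    """Cross-facility view over a set of scorecards."""

    scorecards: list[FacilityScorecard]

    @property
    def periods(self) -> tuple[str, ...]:
        return tuple(sorted({c.period for c in self.scorecards}))

    @property
    def facilities(self) -> tuple[str, ...]:
        return tuple(sorted({c.facility_id for c in self.scorecards}))

    def average(self, level: str, name: str, period: str) -> int:
        return global_average(self.scorecards, level, name, period)

    def delta(
        self, facility: str, level: str, name: str,
        periods: tuple[str, str] | None = None,
    ) -> int | None:
        return period_delta(self.scorecards, facility, level, name, periods)

    def flag_gaps(self, threshold_pct: int) -> list[GapFlag]:
        """Every category/subcategory entry strictly below the threshold,
        sorted ascending by percentage, ties broken by name then facility.

        "Above threshold" is the strict complement: a facility counts as
        above when pct > threshold.
        """
        if not 0 <= threshold_pct <= 100:
            raise ValueError("threshold must be in [0, 100]")
        flags: list[GapFlag] = []
        for card in self.scorecards:
            for c in card.categories:
                if c.pct is not None and c.pct < threshold_pct:
                    flags.append(
                        GapFlag(card.facility_id, card.period, "category",
                                c.name, c.pct)
                    )
                for s in c.subcategories:
                    if s.pct is not None and s.pct < threshold_pct:
                        flags.append(
                            GapFlag(card.facility_id, card.period,
                                    "subcategory", s.name, s.pct)
                        )
        flags.sort(key=lambda f: (f.pct, f.name, f.facility, f.period))
        return flags

    def n_above(self, level: str, name: str, threshold_pct: int) -> int:
        """Number of facilities scoring strictly above the threshold on any
        assessment (a facility counts once if any of its periods qualifies)."""
        above = set()
        for card in self.scorecards:
            pct = _lookup(card, level, name)
            if pct is not None and pct > threshold_pct:
                above.add(card.facility_id)
        return len(above)

    def to_table(self) -> "pandas.DataFrame":  # noqa: F821
        """Benchmark table: category and subcategory rows, one column per
        facility-period, Average columns (one per period) last."""
        import pandas as pd

        cols = [
            (f, p) for f in self.facilities for p in self.periods
            if any(c.facility_id == f and c.period == p for c in self.scorecards)
        ]
        by_key = {(c.facility_id, c.period): c for c in self.scorecards}
        rows: list[tuple[str, str, str]] = [("overall", "", "Overall")]
        template = by_key[cols[0]]
        for cat in template.categories:
            rows.append(("category", cat.name, cat.name))
            for s in cat.subcategories:
                rows.append(("subcategory", cat.name, s.name))
            rows.append(("bonus", cat.name, "Bonus"))
        data = {}
        for f, p in cols:
            card = by_key[(f, p)]
            col = []
            for level, cat, name in rows:
                if level == "overall":
                    col.append(card.overall_pct)
                elif level == "category":
                    col.append(card.category(cat).pct)
                elif level == "bonus":
                    col.append(card.category(cat).bonus)
                else:
                    col.append(card.subcategory(cat, name).pct)
            data[f"{f} {p}"] = col
        for p in self.periods:
            col = []
            for level, cat, name in rows:
                if level == "bonus":
                    col.append(None)
                    continue
                lvl = "overall" if level == "overall" else level
                nm = name if level != "overall" else ""
                try:
                    col.append(self.average(lvl, nm, p))
                except ValueError:
                    col.append(None)
            data[f"Average {p}"] = col
        index = pd.MultiIndex.from_tuples(
            [(cat or "overall", name) for _, cat, name in rows],
            names=["category", "name"],
        )
        return pd.DataFrame(data, index=index)

    def write_csv(self, path: str | Path) -> Path:
        path = Path(path)
        table = self.to_table()
        table.to_csv(path, na_rep="NA")
        return path

    def write_json(self, path: str | Path, threshold_pct: int = 80) -> Path:
        path = Path(path)
        payload = {
            "facilities": list(self.facilities),
            "periods": list(self.periods),
            "scorecards": [c.to_dict() for c in self.scorecards],
            "averages": {
                p: {
                    "overall": self._safe_avg("overall", "", p),
                    "categories": {
                        c: self._safe_avg("category", c, p)
                        for c in CATEGORIES
                    },
                }
                for p in self.periods
            },
            "flags": [
                {"facility": f.facility, "period": f.period, "level": f.level,
                 "name": f.name, "pct": f.pct}
                for f in self.flag_gaps(threshold_pct)
            ],
            "threshold_pct": threshold_pct,
        }
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path

    def _safe_avg(self, level: str, name: str, period: str) -> int | None:
        try:
            return self.average(level, name, period)
        except (ValueError, KeyError):
            return None


def load_recommendations() -> dict[str, list[str]]:
    """Packaged category -> improvement recommendations mapping."""
    ref = resources.files("rabbitwat.data").joinpath("recommendations.json")
    return json.loads(ref.read_text(encoding="utf-8"))


def recommend(category: str) -> list[str]:
    """Improvement recommendations for one category."""
    recs = load_recommendations()
    if category not in recs:
        raise KeyError(f"unknown category {category!r}")
    return list(recs[category])
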