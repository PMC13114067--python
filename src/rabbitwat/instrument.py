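"""Instrument schema: descriptors, weights, forms, and structural maxima.

The assessment instrument is a weighted checklist of welfare descriptors
organized in a two-level hierarchy (six categories, each split into named
subcategories).  Every descriptor carries an integer welfare weight
expressing its importance to rabbit welfare; a graded item scored 0/1/2
contributes ``score x weight`` points, so its maximum contribution is
``2 x weight``.  Bonus items reward practices that are beneficial but not
feasible at most sites: they add their full weight to the achieved score
when satisfied and are excluded from every maximum.

The published instrument (134 descriptors) ships with the package and is
loaded by :func:`load_instrument` when no path is given.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

CATEGORIES: tuple[str, ...] = (
    "physical",
    "behavioral",
    "environmental",
    "training",
    "procedural",
    "culture_of_care",
)

FORMS: tuple[str, ...] = ("room", "site", "coc")

RESPONSE_KINDS: tuple[str, ...] = ("graded", "binary")

#: Name of the pseudo-subcategory that holds bonus items in the packaged file.
BONUS_SUBCATEGORY = "Bonus"


class InstrumentError(ValueError):
    """Raised when an instrument file is structurally invalid."""


@dataclass(frozen=True)
class Descriptor:
    """One scorable item of the instrument."""

    id: str
    category: str
    subcategory: str
    form: str
    weight: int
    response_kind: str = "graded"
    is_bonus: bool = False
    bonus_sign: int = 1
    text: str = ""
    na_allowed: bool = True

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise InstrumentError(f"{self.id}: unknown category {self.category!r}")
        if self.form not in FORMS:
            raise InstrumentError(f"{self.id}: unknown form {self.form!r}")
        if self.response_kind not in RESPONSE_KINDS:
            raise InstrumentError(
                f"{self.id}: unknown response kind {self.response_kind!r}"
            )
        if self.bonus_sign not in (1, -1):
            raise InstrumentError(f"{self.id}: bonus_sign must be +1 or -1")
        if self.is_bonus:
            # Bonus items contribute their listed weight verbatim; the
            # published instrument includes bonus values above 5.
            if self.weight < 1:
                raise InstrumentError(f"{self.id}: bonus weight must be positive")
        elif self.weight not in (1, 2, 3, 4, 5):
            raise InstrumentError(
                f"{self.id}: weight {self.weight} outside the allowed range 1-5"
            )

    @property
    def max_points(self) -> int:
        """Maximum achievable points: 2 x weight for scored items, the
        listed weight for bonus items (which never enter a denominator)."""
        return self.weight if self.is_bonus else 2 * self.weight


@dataclass(frozen=True)
class Instrument:
    """A validated, ordered collection of descriptors."""

    descriptors: tuple[Descriptor, ...]
    version: str = "1"
    _by_id: dict[str, Descriptor] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        by_id: dict[str, Descriptor] = {}
        for d in self.descriptors:
            if d.id in by_id:
                raise InstrumentError(f"duplicate descriptor id {d.id!r}")
            by_id[d.id] = d
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, descriptor_id: str) -> Descriptor:
        try:
            return self._by_id[descriptor_id]
        except KeyError:
            raise KeyError(f"unknown descriptor id {descriptor_id!r}") from None

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self._by_id

    @property
    def categories(self) -> tuple[str, ...]:
        """Categories in canonical order, restricted to those present."""
        present = {d.category for d in self.descriptors}
        return tuple(c for c in CATEGORIES if c in present)

    def subcategories(self, category: str | None = None) -> tuple[tuple[str, str], ...]:
        """Ordered (category, subcategory) pairs of non-bonus subcategories."""
        seen: list[tuple[str, str]] = []
        for d in self.descriptors:
            if d.is_bonus:
                continue
            key = (d.category, d.subcategory)
            if key not in seen and (category is None or d.category == category):
                seen.append(key)
        return tuple(seen)

    def select(
        self,
        *,
        category: str | None = None,
        subcategory: str | None = None,
        form: str | None = None,
        bonus: bool | None = None,
    ) -> tuple[Descriptor, ...]:
        out = []
        for d in self.descriptors:
            if category is not None and d.category != category:
                continue
            if subcategory is not None and d.subcategory != subcategory:
                continue
            if form is not None and d.form != form:
                continue
            if bonus is not None and d.is_bonus != bonus:
                continue
            out.append(d)
        return tuple(out)


def load_instrument(source: str | Path | None = None) -> Instrument:
    """Load and validate an instrument from a TSV file.

    With ``source=None`` the packaged published instrument is returned.
    The file is tab-separated with a documented header row; lines starting
    with ``#`` are comments.
    """
    if source is None:
        ref = resources.files("rabbitwat.data").joinpath("instrument.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(source).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    reader = csv.DictReader(lines, delimiter="\t")
    required = {
        "id", "category", "subcategory", "form", "weight",
        "response_kind", "is_bonus", "bonus_sign", "text",
    }
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        missing = sorted(required - set(reader.fieldnames or []))
        raise InstrumentError(f"instrument file missing columns: {missing}")
    descriptors = []
    for lineno, row in enumerate(reader, start=2):
        try:
            weight = int(row["weight"])
            bonus_sign = int(row["bonus_sign"])
            is_bonus = row["is_bonus"].strip() in ("1", "true", "True")
        except (TypeError, ValueError) as exc:
            raise InstrumentError(f"line {lineno}: {exc}") from exc
        if not row["subcategory"].strip():
            raise InstrumentError(f"line {lineno}: missing subcategory")
        descriptors.append(
            Descriptor(
                id=row["id"].strip(),
                category=row["category"].strip(),
                subcategory=row["subcategory"].strip(),
                form=row["form"].strip(),
                weight=weight,
                response_kind=row["response_kind"].strip(),
                is_bonus=is_bonus,
                bonus_sign=bonus_sign,
                text=row["text"].strip(),
                na_allowed=row.get("na_allowed", "1") in ("1", "true", "True"),
            )
        )
    return Instrument(descriptors=tuple(descriptors))


def subcategory_max(instrument: Instrument, subcategory: str) -> int:
    """Maximum achievable points of a subcategory: sum of 2 x weight over
    its non-bonus descriptors.  Bonus items never enter the maximum."""
    items = [
        d for d in instrument
        if d.subcategory == subcategory and not d.is_bonus
    ]
    if not items:
        raise KeyError(f"unknown subcategory {subcategory!r}")
    return sum(2 * d.weight for d in items)


def bonus_max(instrument: Instrument, category: str) -> int:
    """Maximum bonus points accruable in a category (sum of bonus weights,
    signed).  Zero for categories without bonus items."""
    if category not in CATEGORIES:
        raise KeyError(f"unknown category {category!r}")
    return sum(
        d.weight * d.bonus_sign
        for d in instrument.select(category=category, bonus=True)
    )


def count_descriptors(
    instrument: Instrument,
    *,
    category: str | None = None,
    form: str | None = None,
    bonus: bool | None = None,
) -> int:
    """Count descriptors under the given filters (all 134 unfiltered on the
    packaged instrument)."""
    return len(instrument.select(category=category, form=form, bonus=bonus))
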