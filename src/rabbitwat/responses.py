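"""Reading, validating, and writing assessment responses.

A facility submits one assessment per period, spread over three forms:

* **room** — one record per assessed room, scored while observing the
  animals in their home environment (with the number of animals housed);
* **site** — a single record covering facility-level protocols;
* **coc** — the anonymous culture-of-care survey, one record per
  respondent, with optional gender and tenure demographics.

Values are ``0``, ``1``, ``2`` or ``NA`` (``None`` in memory); binary
items additionally accept ``yes``/``no``, normalized to ``2``/``0`` on
read.  The on-disk format is a long-form CSV, one row per
``(facility, period, form, unit, descriptor, value)``, with a JSON mirror
carrying identical semantics.  Room and site forms are exhaustive
checklists: a descriptor missing from them is a validation error, whereas
an explicit ``NA`` is a legitimate answer that drops the item from both
the achieved score and the maximum.  A survey question skipped by a
culture-of-care respondent is read back as ``NA``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .instrument import Instrument

#: In-memory representation of a non-applicable answer.
NA = None

Value = int | None

GENDERS = ("woman", "man", "no_answer")
TENURE_BANDS = ("<1y", "1-5y", "6-10y", ">10y", "no_answer")

_META_PREFIX = "@"
_META_N_ANIMALS = "@n_animals"
_META_GENDER = "@gender"
_META_TENURE = "@tenure"


class ResponseValidationError(ValueError):
    """Validation failure; ``errors`` lists every located problem."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__(
            f"{len(errors)} validation error(s):\n" + "\n".join(errors)
        )


@dataclass
class RoomAssessment:
    room_id: str
    n_animals: int = 0
    values: dict[str, Value] = field(default_factory=dict)


@dataclass
class SiteAssessment:
    values: dict[str, Value] = field(default_factory=dict)


@dataclass
class CoCResponse:
    respondent_id: str
    gender: str = "no_answer"
    tenure_band: str = "no_answer"
    values: dict[str, Value] = field(default_factory=dict)


@dataclass
class FacilityAssessment:
    facility_id: str
    period: str
    rooms: list[RoomAssessment] = field(default_factory=list)
    site: SiteAssessment = field(default_factory=SiteAssessment)
    coc: list[CoCResponse] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, str]:
        return (self.facility_id, self.period)


def _normalize_value(raw: str, kind: str, where: str, errors: list[str]) -> Value:
    token = raw.strip()
    low = token.lower()
    if low in ("na", "n/a", "not applicable", "non-applicable"):
        return NA
    if kind == "binary":
        if low in ("yes", "y", "2", "true"):
            return 2
        if low in ("no", "n", "0", "false"):
            return 0
        errors.append(f"{where}: binary value must be yes/no/NA, got {raw!r}")
        return NA
    if token in ("0", "1", "2"):
        return int(token)
    errors.append(f"{where}: value must be 0, 1, 2 or NA, got {raw!r}")
    return NA


def _validate_unit_values(
    values: Mapping[str, Value],
    instrument: Instrument,
    form: str,
    where: str,
    errors: list[str],
    *,
    exhaustive: bool,
) -> None:
    for did, v in values.items():
        if did not in instrument:
            errors.append(f"{where}: unknown descriptor {did!r}")
            continue
        d = instrument[did]
        if d.form != form:
            errors.append(
                f"{where}: descriptor {did} belongs to the {d.form} form, not {form}"
            )
        if v is NA and not d.na_allowed:
            errors.append(f"{where}: descriptor {did} does not allow NA")
        if v is not NA and v not in (0, 1, 2):
            errors.append(f"{where}: descriptor {did} value {v!r} out of domain")
    if exhaustive:
        expected = {d.id for d in instrument.select(form=form)}
        for missing in sorted(expected - set(values)):
            errors.append(
                f"{where}: descriptor {missing} missing (forms are exhaustive; "
                f"use NA if not applicable)"
            )


def validate_assessment(
    assessment: FacilityAssessment, instrument: Instrument
) -> None:
    """Raise :class:`ResponseValidationError` listing every problem."""
    errors: list[str] = []
    fp = f"{assessment.facility_id}/{assessment.period}"
    seen_rooms: set[str] = set()
    for room in assessment.rooms:
        where = f"{fp}/room {room.room_id}"
        if room.room_id in seen_rooms:
            errors.append(f"{where}: duplicate room id")
        seen_rooms.add(room.room_id)
        if room.n_animals < 0:
            errors.append(f"{where}: negative animal count")
        _validate_unit_values(
            room.values, instrument, "room", where, errors, exhaustive=True
        )
    _validate_unit_values(
        assessment.site.values, instrument, "site", f"{fp}/site", errors,
        exhaustive=True,
    )
    seen_resp: set[str] = set()
    for resp in assessment.coc:
        where = f"{fp}/respondent {resp.respondent_id}"
        if resp.respondent_id in seen_resp:
            errors.append(f"{where}: duplicate respondent id")
        seen_resp.add(resp.respondent_id)
        if resp.gender not in GENDERS:
            errors.append(f"{where}: gender must be one of {GENDERS}")
        if resp.tenure_band not in TENURE_BANDS:
            errors.append(f"{where}: tenure band must be one of {TENURE_BANDS}")
        _validate_unit_values(
            resp.values, instrument, "coc", where, errors, exhaustive=False
        )
    if errors:
        raise ResponseValidationError(errors)


def read_responses(
    path: str | Path, instrument: Instrument
) -> list[FacilityAssessment]:
    """Read and fully validate assessments from a CSV or JSON file."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path, instrument)
    return _read_csv(path, instrument)


def _read_csv(path: Path, instrument: Instrument) -> list[FacilityAssessment]:
    errors: list[str] = []
    assessments: dict[tuple[str, str], FacilityAssessment] = {}
    rooms: dict[tuple[str, str, str], RoomAssessment] = {}
    resps: dict[tuple[str, str, str], CoCResponse] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        expected = ["facility", "period", "form", "unit", "descriptor_id", "value"]
        if reader.fieldnames is None or [
            c for c in expected if c not in reader.fieldnames
        ]:
            raise ResponseValidationError(
                [f"{path}: header must contain columns {expected}"]
            )
        for lineno, row in enumerate(reader, start=2):
            fac, period = row["facility"].strip(), row["period"].strip()
            form, unit = row["form"].strip(), row["unit"].strip()
            did, raw = row["descriptor_id"].strip(), row["value"]
            where = f"{path.name}:{lineno}"
            key = (fac, period)
            fa = assessments.setdefault(
                key, FacilityAssessment(facility_id=fac, period=period)
            )
            if form == "room":
                room = rooms.get((fac, period, unit))
                if room is None:
                    room = rooms[(fac, period, unit)] = RoomAssessment(room_id=unit)
                    fa.rooms.append(room)
                if did == _META_N_ANIMALS:
                    try:
                        room.n_animals = int(raw)
                    except ValueError:
                        errors.append(f"{where}: @n_animals must be an integer")
                    continue
                target = room.values
            elif form == "site":
                if unit != "site":
                    errors.append(f"{where}: site rows must use unit='site'")
                target = fa.site.values
            elif form == "coc":
                resp = resps.get((fac, period, unit))
                if resp is None:
                    resp = resps[(fac, period, unit)] = CoCResponse(respondent_id=unit)
                    fa.coc.append(resp)
                if did == _META_GENDER:
                    resp.gender = raw.strip() or "no_answer"
                    continue
                if did == _META_TENURE:
                    resp.tenure_band = raw.strip() or "no_answer"
                    continue
                target = resp.values
            else:
                errors.append(f"{where}: unknown form {form!r}")
                continue
            if did.startswith(_META_PREFIX):
                errors.append(f"{where}: metadata field {did!r} not valid here")
                continue
            kind = instrument[did].response_kind if did in instrument else "graded"
            if did in target:
                errors.append(f"{where}: duplicate row for descriptor {did}")
                continue
            target[did] = _normalize_value(raw, kind, where, errors)
    if errors:
        raise ResponseValidationError(errors)
    out = list(assessments.values())
    all_errors: list[str] = []
    for fa in out:
        try:
            validate_assessment(fa, instrument)
        except ResponseValidationError as exc:
            all_errors.extend(exc.errors)
    if all_errors:
        raise ResponseValidationError(all_errors)
    return out


def _read_json(path: Path, instrument: Instrument) -> list[FacilityAssessment]:
    data = json.loads(path.read_text(encoding="utf-8"))
    out = []
    for fa_obj in data:
        fa = FacilityAssessment(
            facility_id=fa_obj["facility_id"],
            period=fa_obj["period"],
            rooms=[
                RoomAssessment(
                    room_id=r["room_id"],
                    n_animals=int(r.get("n_animals", 0)),
                    values={k: v for k, v in r["values"].items()},
                )
                for r in fa_obj.get("rooms", [])
            ],
            site=SiteAssessment(values=dict(fa_obj.get("site", {}).get("values", {}))),
            coc=[
                CoCResponse(
                    respondent_id=c["respondent_id"],
                    gender=c.get("gender", "no_answer"),
                    tenure_band=c.get("tenure_band", "no_answer"),
                    values=dict(c["values"]),
                )
                for c in fa_obj.get("coc", [])
            ],
        )
        out.append(fa)
    errors: list[str] = []
    seen: set[tuple[str, str]] = set()
    for fa in out:
        if fa.key in seen:
            errors.append(f"duplicate facility-period {fa.key}")
        seen.add(fa.key)
        try:
            validate_assessment(fa, instrument)
        except ResponseValidationError as exc:
            errors.extend(exc.errors)
    if errors:
        raise ResponseValidationError(errors)
    return out


def _fmt(v: Value) -> str:
    return "NA" if v is NA else str(v)


def write_responses(
    assessments: Iterable[FacilityAssessment], path: str | Path
) -> Path:
    """Write assessments to CSV (or JSON when the path ends in .json).

    ``read_responses(write_responses(x))`` reproduces ``x`` exactly,
    including NA values.
    """
    path = Path(path)
    assessments = list(assessments)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "facility_id": fa.facility_id,
                "period": fa.period,
                "rooms": [
                    {
                        "room_id": r.room_id,
                        "n_animals": r.n_animals,
                        "values": dict(r.values),
                    }
                    for r in fa.rooms
                ],
                "site": {"values": dict(fa.site.values)},
                "coc": [
                    {
                        "respondent_id": c.respondent_id,
                        "gender": c.gender,
                        "tenure_band": c.tenure_band,
                        "values": dict(c.values),
                    }
                    for c in fa.coc
                ],
            }
            for fa in assessments
        ]
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")
        return path
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["facility", "period", "form", "unit", "descriptor_id", "value"])
        for fa in assessments:
            for room in fa.rooms:
                writer.writerow(
                    [fa.facility_id, fa.period, "room", room.room_id,
                     _META_N_ANIMALS, room.n_animals]
                )
                for did, v in room.values.items():
                    writer.writerow(
                        [fa.facility_id, fa.period, "room", room.room_id, did, _fmt(v)]
                    )
            for did, v in fa.site.values.items():
                writer.writerow(
                    [fa.facility_id, fa.period, "site", "site", did, _fmt(v)]
                )
            for resp in fa.coc:
                writer.writerow(
                    [fa.facility_id, fa.period, "coc", resp.respondent_id,
                     _META_GENDER, resp.gender]
                )
                writer.writerow(
                    [fa.facility_id, fa.period, "coc", resp.respondent_id,
                     _META_TENURE, resp.tenure_band]
                )
                for did, v in resp.values.items():
                    writer.writerow(
                        [fa.facility_id, fa.period, "coc", resp.respondent_id,
                         did, _fmt(v)]
                    )
    return path


def sampling_check(
    assessment: FacilityAssessment, total_rooms_at_facility: int
) -> list[str]:
    """Advisory warnings against the sampling guidance: assess about 10% of
    rabbit rooms (at least 3, or all rooms if fewer; at most 10) and collect
    3-6 culture-of-care responses."""
    n_rooms = len(assessment.rooms)
    if total_rooms_at_facility < n_rooms:
        raise ValueError("total_rooms_at_facility is below the number assessed")
    warnings: list[str] = []
    floor = min(3, total_rooms_at_facility)
    if n_rooms < floor:
        warnings.append(
            f"only {n_rooms} room(s) assessed; guidance asks for at least {floor}"
        )
    if n_rooms > 10:
        warnings.append(
            f"{n_rooms} rooms assessed; guidance caps room sampling at 10"
        )
    # 10x n_rooms < total <=> n_rooms < 10% of total; the 10-room cap takes
    # precedence for very large facilities.
    if n_rooms < 10 and 10 * n_rooms < total_rooms_at_facility:
        warnings.append(
            f"{n_rooms} of {total_rooms_at_facility} rooms assessed is below "
            f"the ~10% guidance"
        )
    n_coc = len(assessment.coc)
    if not 3 <= n_coc <= 6:
        warnings.append(
            f"{n_coc} culture-of-care response(s); guidance asks for 3-6"
        )
    return warnings
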