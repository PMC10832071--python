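"""Hip-level cohort data model, CSV round-trip, and the reconstructed study cohort.

The unit of analysis is the *hip*, not the patient: bilateral disease
contributes two rows sharing one ``patient_id``. Follow-up is
administratively censored at 5 years; ``event`` marks radiographic collapse
(or total hip replacement) and ``time`` is years from baseline to collapse
or censoring.

Only pre-collapse hips occur here, so the staging/typing enumerations are
restricted to ARCO I/II and JIC A/B/C1/C2.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, fields
from enum import Enum
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union


class Side(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class Etiology(str, Enum):
    IDIOPATHIC = "idiopathic"
    GLUCOCORTICOID = "glucocorticoid"
    ALCOHOL = "alcohol"


class ArcoStage(str, Enum):
    """Pre-collapse ARCO radiographic stages (collapse defines stage III+)."""

    I = "I"
    II = "II"


class JicType(str, Enum):
    """JIC lesion-location types; C1/C2 involve the lateral (outer) column."""

    A = "A"
    B = "B"
    C1 = "C1"
    C2 = "C2"


class AreaCategory(str, Enum):
    """Necrotic-area fraction bins: <30%, 30-50%, >50% of the femoral head."""

    LT30 = "LT30"
    FROM30TO50 = "FROM30TO50"
    GT50 = "GT50"


class CohortValidationError(ValueError):
    """A record (or CSV row) violates the cohort schema."""


CSV_COLUMNS = [
    "patient_id",
    "side",
    "age",
    "sex",
    "bmi",
    "etiology",
    "arco_stage",
    "jic_type",
    "area_fraction",
    "area_category",
    "event",
    "time",
    "censored_at",
]

DEFAULT_HORIZON = 5.0


@dataclass
class HipRecord:
    """One hip's covariates, staging factors, and follow-up outcome.

    ``age``/``sex``/``bmi``/``etiology`` and ``area_fraction`` may be absent
    (``None``) — the reconstructed fixture carries only what the published
    grouped tables determine.
    """

    patient_id: str
    side: Side
    arco_stage: ArcoStage
    jic_type: JicType
    area_category: AreaCategory
    event: bool
    time: float
    censored_at: float = DEFAULT_HORIZON
    age: Optional[float] = None
    sex: Optional[Sex] = None
    bmi: Optional[float] = None
    etiology: Optional[Etiology] = None
    area_fraction: Optional[float] = None

    def validate(self) -> None:
        if not self.patient_id:
            raise CohortValidationError("patient_id is empty")
        if self.time <= 0:
            raise CohortValidationError(f"time must be positive, got {self.time}")
        if self.censored_at <= 0:
            raise CohortValidationError("censored_at must be positive")
        if self.time > self.censored_at + 1e-12:
            raise CohortValidationError(
                f"time {self.time} exceeds censoring horizon {self.censored_at}"
            )
        if not self.event and abs(self.time - self.censored_at) > 1e-9:
            raise CohortValidationError(
                "non-collapsed hips are censored at the horizon: "
                f"time {self.time} != censored_at {self.censored_at}"
            )
        if self.age is not None and self.age <= 0:
            raise CohortValidationError(f"age must be positive, got {self.age}")
        if self.bmi is not None and self.bmi <= 0:
            raise CohortValidationError(f"bmi must be positive, got {self.bmi}")
        if self.area_fraction is not None:
            if not 0.0 <= self.area_fraction <= 1.0:
                raise CohortValidationError(
                    f"area_fraction must lie in [0, 1], got {self.area_fraction}"
                )
            from .scoring import discretize_area

            expected = discretize_area(self.area_fraction)
            if expected is not self.area_category:
                raise CohortValidationError(
                    f"area_category {self.area_category.value} inconsistent with "
                    f"area_fraction {self.area_fraction} (expected {expected.value})"
                )


@dataclass
class Cohort:
    """An ordered collection of hips with a provenance tag."""

    records: list[HipRecord]
    provenance: str = "measured"  # measured | synthetic | reconstructed

    def __post_init__(self) -> None:
        if not self.records:
            raise CohortValidationError("no records")
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
        bad = [pid for pid, c in counts.items() if c > 2]
        if bad:
            raise CohortValidationError(
                f"patient_id may repeat at most twice (bilateral): {bad[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[HipRecord]:
        return iter(self.records)

    @property
    def n_events(self) -> int:
        return sum(r.event for r in self.records)

    def times(self) -> list[float]:
        return [r.time for r in self.records]

    def events(self) -> list[bool]:
        return [r.event for r in self.records]

    def scores(self) -> list[int]:
        """Matrix-model score per hip (see :mod:`nonfh_collapse.scoring`)."""
        from .scoring import matrix_score

        return [
            matrix_score(r.arco_stage, r.jic_type, r.area_category).value
            for r in self.records
        ]

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for r in self.records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "side": r.side.value,
                    "age": r.age,
                    "sex": r.sex.value if r.sex else None,
                    "bmi": r.bmi,
                    "etiology": r.etiology.value if r.etiology else None,
                    "arco_stage": r.arco_stage.value,
                    "jic_type": r.jic_type.value,
                    "area_fraction": r.area_fraction,
                    "area_category": r.area_category.value,
                    "event": int(r.event),
                    "time": r.time,
                    "censored_at": r.censored_at,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_optional_float(text: str, name: str, row: int) -> Optional[float]:
    if text == "" or text is None:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise CohortValidationError(f"row {row}: unparseable {name} {text!r}") from exc


def _parse_enum(enum_cls, text: str, name: str, row: int):
    try:
        return enum_cls(text)
    except ValueError as exc:
        legal = "/".join(e.value for e in enum_cls)
        raise CohortValidationError(
            f"row {row}: unparseable {name} {text!r} (expected {legal})"
        ) from exc


def _parse_optional_enum(enum_cls, text: str, name: str, row: int):
    if text == "" or text is None:
        return None
    return _parse_enum(enum_cls, text, name, row)


def load_cohort(
    path: Union[str, Path], schema_strict: bool = True, provenance: str = "measured"
) -> Cohort:
    """Read a hip-level cohort CSV (schema of :data:`CSV_COLUMNS`).

    With ``schema_strict`` the header must contain every documented column;
    otherwise missing optional-covariate columns are tolerated. Rows that
    violate record invariants are rejected with row-indexed messages.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CohortValidationError("no records")
        required = CSV_COLUMNS if schema_strict else [
            "patient_id", "side", "arco_stage", "jic_type",
            "area_category", "event", "time",
        ]
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise CohortValidationError(f"missing required column(s): {missing}")
        records: list[HipRecord] = []
        for i, row in enumerate(reader, start=1):
            get = lambda k: (row.get(k) or "").strip()
            if get("event") not in {"0", "1"}:
                raise CohortValidationError(
                    f"row {i}: event must be 0 or 1, got {get('event')!r}"
                )
            censored_raw = get("censored_at")
            rec = HipRecord(
                patient_id=get("patient_id"),
                side=_parse_enum(Side, get("side"), "side", i),
                age=_parse_optional_float(get("age"), "age", i),
                sex=_parse_optional_enum(Sex, get("sex"), "sex", i),
                bmi=_parse_optional_float(get("bmi"), "bmi", i),
                etiology=_parse_optional_enum(Etiology, get("etiology"), "etiology", i),
                arco_stage=_parse_enum(ArcoStage, get("arco_stage"), "arco_stage", i),
                jic_type=_parse_enum(JicType, get("jic_type"), "jic_type", i),
                area_fraction=_parse_optional_float(
                    get("area_fraction"), "area_fraction", i
                ),
                area_category=_parse_enum(
                    AreaCategory, get("area_category"), "area_category", i
                ),
                event=get("event") == "1",
                time=_parse_optional_float(get("time"), "time", i),
                censored_at=(
                    float(censored_raw) if censored_raw else DEFAULT_HORIZON
                ),
            )
            try:
                rec.validate()
            except CohortValidationError as exc:
                raise CohortValidationError(f"row {i}: {exc}") from exc
            records.append(rec)
    if not records:
        raise CohortValidationError("no records")
    return Cohort(records=records, provenance=provenance)


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort to CSV; ``load_cohort`` round-trips it field-for-field."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in cohort.records:
            writer.writerow(
                [
                    r.patient_id,
                    r.side.value,
                    "" if r.age is None else repr(r.age),
                    "" if r.sex is None else r.sex.value,
                    "" if r.bmi is None else repr(r.bmi),
                    "" if r.etiology is None else r.etiology.value,
                    r.arco_stage.value,
                    r.jic_type.value,
                    "" if r.area_fraction is None else repr(r.area_fraction),
                    r.area_category.value,
                    int(r.event),
                    repr(r.time),
                    repr(r.censored_at),
                ]
            )


# Reconstructed study cohort ------------------------------------------------
#
# The published grouped tables pin down, per matrix-score stratum
# (sizes 25/62/85/30): cumulative collapses by years 1/3/5 of
# 1/15/31/12, 1/18/46/19, and 1/20/50/27 respectively. Event times are
# placed at the right endpoint of the interval in which collapse is known
# to have occurred (years 1, 3, 5); survivors are administratively
# censored at 5 years.

_FIXTURE_STRATA = {
    # score: (n, events at t=1, additional by t=3, additional by t=5)
    1: (25, 1, 0, 0),
    2: (62, 15, 3, 2),
    4: (85, 31, 15, 4),
    8: (30, 12, 7, 8),
}

# Representative factor combinations with the right point-product; the
# fixture is faithful to the score strata and outcomes only, not to the
# per-factor margins of the full univariate table.
_FIXTURE_FACTORS = {
    1: (ArcoStage.I, JicType.A, AreaCategory.LT30),
    2: (ArcoStage.II, JicType.A, AreaCategory.LT30),
    4: (ArcoStage.II, JicType.C1, AreaCategory.LT30),
    8: (ArcoStage.II, JicType.C1, AreaCategory.GT50),
}


def reconstructed_fixture() -> Cohort:
    """Deterministic 202-hip cohort rebuilt from the published grouped tables.

    Each score stratum carries its published size and cumulative collapse
    counts at years 1/3/5 (events at the interval right endpoints), the
    remainder censored at 5 years. ARCO/JIC/area are representative
    combinations reproducing the stratum score; age/sex/BMI/etiology are
    absent because the grouped tables do not determine them jointly.
    """
    records: list[HipRecord] = []
    idx = 0
    for score, (n, e1, e3, e5) in _FIXTURE_STRATA.items():
        arco, jic, area = _FIXTURE_FACTORS[score]
        outcome = [(1.0, True)] * e1 + [(3.0, True)] * e3 + [(5.0, True)] * e5
        outcome += [(5.0, False)] * (n - e1 - e3 - e5)
        for time, event in outcome:
            idx += 1
            records.append(
                HipRecord(
                    patient_id=f"R{idx:04d}",
                    side=Side.LEFT,
                    arco_stage=arco,
                    jic_type=jic,
                    area_category=area,
                    event=event,
                    time=time,
                )
            )
    return Cohort(records=records, provenance="reconstructed")
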