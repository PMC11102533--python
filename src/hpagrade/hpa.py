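"""Hodapp-Parrish-Anderson (HPA) severity staging of Humphrey visual fields.

The HPA scheme stages glaucomatous field loss from three facets of a single
static-perimetry result:

* the **mean deviation** (MD, dB) — age-corrected average departure of
  sensitivity from normal, more negative meaning worse;
* the **four central points** of the global (total-deviation) plot — the
  sensitivities at (x, y) with |x| = |y| = 3 degrees;
* the **pattern-deviation probability plot** — per-locus flags marking
  depression at P < 5%, < 2%, < 1% or < 0.5% after generalised loss is
  removed.

Each facet grades the field independently on the ordinal scale
``NONE < MILD < MODERATE < SEVERE`` and the most severe per-facet grade is
the overall stage.  Pattern-deviation criteria are expressed as proportions
of the displayed loci so the same rules apply to 24-2 (54 loci) and 30-2
(76 loci) test patterns; proportion comparisons are carried out in exact
rational arithmetic so band boundaries are bit-stable.

All thresholds live in :class:`HpaThresholds` and default to the standard
HPA values; they are configurable so variant staging rules can be expressed
without touching the engine.
"""

from __future__ import annotations

import csv
import enum
import json
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SeverityGrade",
    "SignificanceCategory",
    "Eye",
    "TestPattern",
    "P24_2",
    "P30_2",
    "PATTERNS",
    "get_pattern",
    "HpaThresholds",
    "DEFAULT_THRESHOLDS",
    "CentralPoint",
    "CentralPoints",
    "PatternDeviationMatrix",
    "FieldRecord",
    "GradedField",
    "GradingInputError",
    "P5_OR_WORSE",
    "P1_OR_WORSE",
    "grade_md",
    "grade_central",
    "count_depressed",
    "grade_pd5",
    "grade_pd1",
    "combine_grades",
    "grade_field",
    "record_to_json",
    "record_from_json",
    "report_to_json",
    "write_records_csv",
    "read_records_csv",
]


class GradingInputError(ValueError):
    """Raised when a grading input violates its contract."""


# ---------------------------------------------------------------------------
# Ordinal domain types
# ---------------------------------------------------------------------------

class SeverityGrade(enum.IntEnum):
    """Four-level defect stage; the integer order is the severity order."""

    NONE = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "SeverityGrade":
        key = label.strip().lower()
        if key == "early":  # historical synonym for the mild stage
            key = "mild"
        try:
            return cls[key.upper()]
        except KeyError:
            raise GradingInputError(f"unknown severity grade {label!r}") from None


class SignificanceCategory(enum.IntEnum):
    """Pattern-deviation probability symbol, ordered by significance.

    ``NS`` = not significant; ``P5``/``P2``/``P1``/``P05`` = depressed at
    P < 5%, < 2%, < 1%, < 0.5%.
    """

    NS = 0
    P5 = 1
    P2 = 2
    P1 = 3
    P05 = 4

    @property
    def token(self) -> str:
        return self.name.lower()

    @classmethod
    def from_token(cls, token: str) -> "SignificanceCategory":
        try:
            return cls[token.strip().upper()]
        except KeyError:
            raise GradingInputError(f"unknown significance category {token!r}") from None


class Eye(enum.Enum):
    LEFT = "left"
    RIGHT = "right"

    @classmethod
    def from_token(cls, token: "str | Eye") -> "Eye":
        if isinstance(token, Eye):
            return token
        key = token.strip().lower()
        for eye in cls:
            if key in (eye.value, eye.value[0], {"left": "os", "right": "od"}[eye.value]):
                return eye
        raise GradingInputError(f"unknown eye {token!r}")


# Levels at which pattern-deviation points are counted as depressed.
P5_OR_WORSE = "p5"
P1_OR_WORSE = "p1"


# ---------------------------------------------------------------------------
# Test patterns (canonical Humphrey locus layouts)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestPattern:
    """A Humphrey test-point layout on the 6-degree grid offset 3 degrees.

    Loci are stored in right-eye convention: x positive temporal, y positive
    superior.  The left-eye chart is the x-mirror of this layout.
    """

    name: str
    loci: tuple[tuple[int, int], ...]

    @property
    def locus_count(self) -> int:
        return len(self.loci)

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise GradingInputError(f"duplicate loci in pattern {self.name}")
        for x, y in self.loci:
            if abs(x) % 6 != 3 or abs(y) % 6 != 3:
                raise GradingInputError(
                    f"locus ({x},{y}) off the 3+6k degree grid in {self.name}"
                )


def _grid_row(y: int, xmax: int) -> list[tuple[int, int]]:
    return [(x, y) for x in range(-xmax, xmax + 1, 6)]


def _build_24_2() -> TestPattern:
    # Row extents |x| <= lim for each |y|; the two extra nasal points of the
    # 24-2 sit at x = -27 (nasal is negative x in right-eye convention).
    lims = {21: 9, 15: 15, 9: 21, 3: 21}
    loci: list[tuple[int, int]] = []
    for y in (21, 15, 9, 3, -3, -9, -15, -21):
        loci.extend(_grid_row(y, lims[abs(y)]))
        if abs(y) == 3:
            loci.append((-27, y))
    return TestPattern("24-2", tuple(loci))


def _build_30_2() -> TestPattern:
    lims = {27: 9, 21: 15, 15: 21, 9: 27, 3: 27}
    loci: list[tuple[int, int]] = []
    for y in (27, 21, 15, 9, 3, -3, -9, -15, -21, -27):
        loci.extend(_grid_row(y, lims[abs(y)]))
    return TestPattern("30-2", tuple(loci))


P24_2 = _build_24_2()
P30_2 = _build_30_2()
assert P24_2.locus_count == 54 and P30_2.locus_count == 76

PATTERNS: dict[str, TestPattern] = {"24-2": P24_2, "30-2": P30_2}


def get_pattern(name: "str | TestPattern") -> TestPattern:
    if isinstance(name, TestPattern):
        return name
    try:
        return PATTERNS[name.strip()]
    except KeyError:
        raise GradingInputError(f"unknown test pattern {name!r}") from None


# ---------------------------------------------------------------------------
# Thresholds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HpaThresholds:
    """The numeric boundaries of the HPA bands.

    ``md_*_floor`` are inclusive lower bounds (dB) of the none/mild/moderate
    MD bands; fields below ``md_moderate_floor`` are severe.  ``central_low``
    is the depression cut for the four central points (< 15 dB is depressed)
    and ``central_zero`` the absolute-severity cut (<= 0 dB is severe on its
    own).  ``pd5_*`` are inclusive upper bounds of the mild/moderate bands
    for the proportion depressed at P < 5%; ``pd1_*_sup`` are *exclusive*
    upper bounds of the mild/moderate bands at P < 1% (10/76 already counts
    as moderate, 20/76 as severe).
    """

    md_none_floor: float = -1.0
    md_mild_floor: float = -6.0
    md_moderate_floor: float = -12.0
    central_low: float = 15.0
    central_zero: float = 0.0
    pd5_mild_max: Fraction = Fraction(1, 4)
    pd5_moderate_max: Fraction = Fraction(1, 2)
    pd1_mild_sup: Fraction = Fraction(10, 76)
    pd1_moderate_sup: Fraction = Fraction(20, 76)

    def __post_init__(self) -> None:
        for name in ("pd5_mild_max", "pd5_moderate_max", "pd1_mild_sup", "pd1_moderate_sup"):
            value = getattr(self, name)
            if not isinstance(value, Fraction):
                object.__setattr__(self, name, Fraction(value))
        if not (self.md_none_floor > self.md_mild_floor > self.md_moderate_floor):
            raise GradingInputError("MD floors must strictly decrease none > mild > moderate")
        if not (0 < self.pd5_mild_max < self.pd5_moderate_max < 1):
            raise GradingInputError("P<5% band bounds must satisfy 0 < mild < moderate < 1")
        if not (0 < self.pd1_mild_sup < self.pd1_moderate_sup < 1):
            raise GradingInputError("P<1% band bounds must satisfy 0 < mild < moderate < 1")
        if not self.central_zero < self.central_low:
            raise GradingInputError("central_zero must lie below central_low")

    def to_json(self) -> dict:
        return {
            "md_none_floor": self.md_none_floor,
            "md_mild_floor": self.md_mild_floor,
            "md_moderate_floor": self.md_moderate_floor,
            "central_low": self.central_low,
            "central_zero": self.central_zero,
            "pd5_mild_max": str(self.pd5_mild_max),
            "pd5_moderate_max": str(self.pd5_moderate_max),
            "pd1_mild_sup": str(self.pd1_mild_sup),
            "pd1_moderate_sup": str(self.pd1_moderate_sup),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "HpaThresholds":
        kwargs = dict(obj)
        for name in ("pd5_mild_max", "pd5_moderate_max", "pd1_mild_sup", "pd1_moderate_sup"):
            if name in kwargs and isinstance(kwargs[name], str):
                kwargs[name] = Fraction(kwargs[name])
        return cls(**kwargs)


DEFAULT_THRESHOLDS = HpaThresholds()


# ---------------------------------------------------------------------------
# Field data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CentralPoint:
    """One central-5-degree global-plot reading: quadrant position + dB."""

    x: int
    y: int
    db: float

    def __post_init__(self) -> None:
        if self.x not in (-3, 3) or self.y not in (-3, 3):
            raise GradingInputError(f"central point at ({self.x},{self.y}) is not a +-3 degree quadrant")
        if not math.isfinite(self.db):
            raise GradingInputError("central sensitivity must be finite")


@dataclass(frozen=True)
class CentralPoints:
    """The four innermost global-plot sensitivities, one per quadrant."""

    points: tuple[CentralPoint, CentralPoint, CentralPoint, CentralPoint]

    def __post_init__(self) -> None:
        if len(self.points) != 4:
            raise GradingInputError("exactly four central points required")
        quadrants = {(p.x, p.y) for p in self.points}
        if len(quadrants) != 4:
            raise GradingInputError("central points must cover four distinct quadrants")

    # Fixed quadrant order used when values are given as a bare sequence:
    # upper-nasal, upper-temporal, lower-nasal, lower-temporal (right-eye
    # chart: nasal = negative x).
    _ORDER = ((-3, 3), (3, 3), (-3, -3), (3, -3))

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "CentralPoints":
        if len(values) != 4:
            raise GradingInputError("exactly four central sensitivities required")
        return cls(tuple(CentralPoint(x, y, float(v)) for (x, y), v in zip(cls._ORDER, values)))

    def upper(self) -> tuple[CentralPoint, ...]:
        return tuple(p for p in self.points if p.y > 0)

    def lower(self) -> tuple[CentralPoint, ...]:
        return tuple(p for p in self.points if p.y < 0)


@dataclass(frozen=True)
class PatternDeviationMatrix:
    """Per-locus significance category on a canonical test pattern.

    ``cells`` is keyed by the pattern's loci in right-eye convention; its key
    set must equal the pattern's locus set exactly.
    """

    pattern: TestPattern
    cells: Mapping[tuple[int, int], SignificanceCategory]

    def __post_init__(self) -> None:
        cells = {k: SignificanceCategory(v) for k, v in dict(self.cells).items()}
        object.__setattr__(self, "cells", cells)
        if set(cells) != set(self.pattern.loci):
            raise GradingInputError(
                f"matrix cells do not cover pattern {self.pattern.name} loci exactly"
            )

    @classmethod
    def uniform(cls, pattern: TestPattern, category: SignificanceCategory = SignificanceCategory.NS) -> "PatternDeviationMatrix":
        return cls(pattern, {locus: category for locus in pattern.loci})


@dataclass(frozen=True)
class FieldRecord:
    """One eye's perimetry result: the three inputs the HPA rules consume."""

    eye: Eye
    md: float
    central: CentralPoints
    pd: PatternDeviationMatrix

    def __post_init__(self) -> None:
        if not math.isfinite(self.md):
            raise GradingInputError("mean deviation must be finite")


@dataclass(frozen=True)
class GradedField:
    """Per-criterion grades plus the most-severe-wins overall stage."""

    grade_md: SeverityGrade
    grade_central: SeverityGrade
    grade_pd5: SeverityGrade
    grade_pd1: SeverityGrade
    overall: SeverityGrade
    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = combine_grades(
            [self.grade_md, self.grade_central, self.grade_pd5, self.grade_pd1]
        )
        if self.overall is not expected:
            raise GradingInputError("overall grade must be the most severe per-criterion grade")


# ---------------------------------------------------------------------------
# The rule engine
# ---------------------------------------------------------------------------

def grade_md(md: float, thr: HpaThresholds = DEFAULT_THRESHOLDS) -> SeverityGrade:
    """Stage the field on mean deviation alone.

    NONE for md >= -1 dB, MILD down to -6 dB, MODERATE down to -12 dB,
    SEVERE below that; all floors inclusive.
    """
    if not isinstance(md, (int, float)) or not math.isfinite(md):
        raise GradingInputError(f"mean deviation must be a finite number, got {md!r}")
    if md >= thr.md_none_floor:
        return SeverityGrade.NONE
    if md >= thr.md_mild_floor:
        return SeverityGrade.MILD
    if md >= thr.md_moderate_floor:
        return SeverityGrade.MODERATE
    return SeverityGrade.SEVERE


def grade_central(central: CentralPoints, thr: HpaThresholds = DEFAULT_THRESHOLDS) -> SeverityGrade:
    """Stage the field on the four central global-plot points.

    Any point at or below 0 dB is SEVERE outright; points depressed below
    15 dB in both hemifields are SEVERE; depression confined to one
    hemifield is MODERATE; otherwise NONE.  (This criterion has no mild
    band.)
    """
    if any(p.db <= thr.central_zero for p in central.points):
        return SeverityGrade.SEVERE
    depressed_upper = any(p.db < thr.central_low for p in central.upper())
    depressed_lower = any(p.db < thr.central_low for p in central.lower())
    if depressed_upper and depressed_lower:
        return SeverityGrade.SEVERE
    if depressed_upper or depressed_lower:
        return SeverityGrade.MODERATE
    return SeverityGrade.NONE


def count_depressed(pd: PatternDeviationMatrix, level: str) -> tuple[int, int]:
    """Count loci depressed at the given level.

    ``level`` is :data:`P5_OR_WORSE` (counts P5, P2, P1, P05) or
    :data:`P1_OR_WORSE` (counts P1, P05).  Returns ``(count, total)`` with
    ``total`` the pattern's displayed locus count.
    """
    if level == P5_OR_WORSE:
        cut = SignificanceCategory.P5
    elif level == P1_OR_WORSE:
        cut = SignificanceCategory.P1
    else:
        raise GradingInputError(f"unknown depression level {level!r}")
    count = sum(1 for cat in pd.cells.values() if cat >= cut)
    return count, pd.pattern.locus_count


def _check_counts(count: int, total: int) -> None:
    if not isinstance(count, int) or not isinstance(total, int):
        raise GradingInputError("counts must be integers")
    if total <= 0:
        raise GradingInputError("total locus count must be positive")
    if count < 0 or count > total:
        raise GradingInputError(f"count {count} outside 0..{total}")


def grade_pd5(count: int, total: int, thr: HpaThresholds = DEFAULT_THRESHOLDS) -> SeverityGrade:
    """Stage on the proportion of loci depressed at P < 5%.

    0% NONE; up to 25% (inclusive) MILD; up to 50% (inclusive) MODERATE;
    above 50% SEVERE.  Comparisons are exact rationals, so e.g. 19/76 is
    exactly the mild/moderate boundary and grades MILD.
    """
    _check_counts(count, total)
    if count == 0:
        return SeverityGrade.NONE
    ratio = Fraction(count, total)
    if ratio <= thr.pd5_mild_max:
        return SeverityGrade.MILD
    if ratio <= thr.pd5_moderate_max:
        return SeverityGrade.MODERATE
    return SeverityGrade.SEVERE


def grade_pd1(count: int, total: int, thr: HpaThresholds = DEFAULT_THRESHOLDS) -> SeverityGrade:
    """Stage on the proportion of loci depressed at P < 1%.

    0 NONE; below 10/76 MILD; from 10/76 up to (but excluding) 20/76
    MODERATE; from 20/76 SEVERE.  Exact rational comparison: on a 54-locus
    24-2, 7/54 < 10/76 grades MILD while 8/54 grades MODERATE.
    """
    _check_counts(count, total)
    if count == 0:
        return SeverityGrade.NONE
    ratio = Fraction(count, total)
    if ratio < thr.pd1_mild_sup:
        return SeverityGrade.MILD
    if ratio < thr.pd1_moderate_sup:
        return SeverityGrade.MODERATE
    return SeverityGrade.SEVERE


def combine_grades(grades: Iterable[SeverityGrade]) -> SeverityGrade:
    """Most-severe-wins combination of per-criterion grades."""
    grades = list(grades)
    if not grades:
        raise GradingInputError("cannot combine an empty list of grades")
    return SeverityGrade(max(SeverityGrade(g) for g in grades))


def grade_field(rec: FieldRecord, thr: HpaThresholds = DEFAULT_THRESHOLDS) -> GradedField:
    """Apply all four HPA criteria to a field record and combine them."""
    c5, total = count_depressed(rec.pd, P5_OR_WORSE)
    c1, _ = count_depressed(rec.pd, P1_OR_WORSE)
    g_md = grade_md(rec.md, thr)
    g_c = grade_central(rec.central, thr)
    g5 = grade_pd5(c5, total, thr)
    g1 = grade_pd1(c1, total, thr)
    return GradedField(
        grade_md=g_md,
        grade_central=g_c,
        grade_pd5=g5,
        grade_pd1=g1,
        overall=combine_grades([g_md, g_c, g5, g1]),
        counts={"p5": c5, "p1": c1, "total": total},
    )


# ---------------------------------------------------------------------------
# JSON / CSV interfaces
# ---------------------------------------------------------------------------

def record_to_json(rec: FieldRecord) -> dict:
    """Serialise a field record to the documented JSON schema (v1)."""
    return {
        "schema": "hpagrade.field_record.v1",
        "eye": rec.eye.value,
        "md": rec.md,
        "central": [{"x": p.x, "y": p.y, "db": p.db} for p in rec.central.points],
        "pd": {
            "pattern": rec.pd.pattern.name,
            "cells": [
                {"x": x, "y": y, "category": cat.token}
                for (x, y), cat in sorted(rec.pd.cells.items())
            ],
        },
    }


def record_from_json(obj: Mapping) -> FieldRecord:
    try:
        pattern = get_pattern(obj["pd"]["pattern"])
        cells = {
            (int(c["x"]), int(c["y"])): SignificanceCategory.from_token(c["category"])
            for c in obj["pd"]["cells"]
        }
        central = CentralPoints(
            tuple(CentralPoint(int(p["x"]), int(p["y"]), float(p["db"])) for p in obj["central"])
        )
        return FieldRecord(
            eye=Eye.from_token(obj["eye"]),
            md=float(obj["md"]),
            central=central,
            pd=PatternDeviationMatrix(pattern, cells),
        )
    except (KeyError, TypeError) as exc:
        raise GradingInputError(f"malformed field-record JSON: {exc}") from exc


def report_to_json(graded: GradedField, thr: HpaThresholds = DEFAULT_THRESHOLDS) -> dict:
    """Grading report in the documented JSON schema (v1)."""
    return {
        "schema": "hpagrade.grading_report.v1",
        "grade_md": graded.grade_md.label,
        "grade_central": graded.grade_central.label,
        "grade_pd5": graded.grade_pd5.label,
        "grade_pd1": graded.grade_pd1.label,
        "overall": graded.overall.label,
        "counts": dict(graded.counts),
        "thresholds_used": thr.to_json(),
    }


_CSV_COLUMNS = ["field_id", "eye", "md", "point_type", "x_deg", "y_deg", "value"]


def write_records_csv(path, records: Mapping[str, FieldRecord]) -> None:
    """Long-format CSV: one row per central point and per pattern-deviation
    locus (``point_type`` in {central, pd}); md repeats on every row."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_COLUMNS)
        for field_id, rec in records.items():
            for p in rec.central.points:
                writer.writerow([field_id, rec.eye.value, rec.md, "central", p.x, p.y, p.db])
            for (x, y), cat in sorted(rec.pd.cells.items()):
                writer.writerow([field_id, rec.eye.value, rec.md, "pd", x, y, cat.token])


def read_records_csv(path) -> dict[str, FieldRecord]:
    """Inverse of :func:`write_records_csv`; the test pattern is inferred
    from the set of pattern-deviation loci present for each field."""
    rows: dict[str, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_COLUMNS:
            raise GradingInputError(f"unexpected CSV columns {reader.fieldnames}")
        for row in reader:
            entry = rows.setdefault(
                row["field_id"], {"eye": row["eye"], "md": float(row["md"]), "central": [], "pd": {}}
            )
            x, y = int(row["x_deg"]), int(row["y_deg"])
            if row["point_type"] == "central":
                entry["central"].append(CentralPoint(x, y, float(row["value"])))
            elif row["point_type"] == "pd":
                entry["pd"][(x, y)] = SignificanceCategory.from_token(row["value"])
            else:
                raise GradingInputError(f"unknown point_type {row['point_type']!r}")
    records: dict[str, FieldRecord] = {}
    for field_id, entry in rows.items():
        loci = set(entry["pd"])
        pattern = next((p for p in PATTERNS.values() if set(p.loci) == loci), None)
        if pattern is None:
            raise GradingInputError(f"field {field_id}: loci match no known test pattern")
        records[field_id] = FieldRecord(
            eye=Eye.from_token(entry["eye"]),
            md=entry["md"],
            central=CentralPoints(tuple(entry["central"])),
            pd=PatternDeviationMatrix(pattern, entry["pd"]),
        )
    return records


def load_record(path) -> FieldRecord:
    """Read a single field record from a JSON file."""
    with open(path) as fh:
        return record_from_json(json.load(fh))
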