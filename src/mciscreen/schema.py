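"""Neuropsychological test batteries and case records.

A :class:`BatterySchema` plays the data-standardisation role an ontology
layer would: every test in a battery is declared once with its valid score
range, its CSV column name, and the ontology-style data-property name used
when the trained model is rendered as rules.  Case records are validated
against the schema — out-of-range or non-numeric scores are reported as
violations, and missing cells stay missing (nothing is ever imputed or
defaulted, so downstream inference sees exactly the data that was acquired).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "DEMOGRAPHIC_FIELDS",
    "GOLD_COLUMN",
    "SchemaError",
    "CaseFileError",
    "TestDefinition",
    "BatterySchema",
    "SubjectRecord",
    "Violation",
    "ValidationReport",
    "is_missing",
    "load_schema",
    "dump_schema",
    "validate_record",
    "read_cases",
    "write_cases",
]

#: Demographic fields carried on every record, next to the test scores.
DEMOGRAPHIC_FIELDS = ("subject_id", "evaluation_index", "sex", "age", "education")

#: CSV column holding the optional clinical gold label (0 = Healthy, 1 = MCI).
GOLD_COLUMN = "gold_label"

# Accepted spellings of a missing cell (case-insensitive).
_MISSING_TOKENS = {"", "na", "n/a", "nan", "none", "null"}

_SCHEMA_COLUMNS = (
    "battery_id",
    "test_id",
    "column_name",
    "property_name",
    "min",
    "max",
    "higher_is_better",
    "var_name",
)


class SchemaError(ValueError):
    """A battery schema violates its invariants (duplicates, bad ranges...)."""


class CaseFileError(ValueError):
    """A case CSV cannot be read at all (no header, no subject_id column)."""


def is_missing(cell: object) -> bool:
    """True if a raw CSV cell encodes an absent value."""
    if cell is None:
        return True
    if isinstance(cell, float) and cell != cell:  # NaN
        return True
    if isinstance(cell, str) and cell.strip().lower() in _MISSING_TOKENS:
        return True
    return False


def _derive_var_stem(column_name: str) -> str:
    """Default SWRL variable stem: initials of the column-name tokens.

    ``Praxias_cons`` -> ``PC``, ``cal_rey`` -> ``CR``.  Batteries whose
    conventional abbreviation differs (e.g. Trail Making Test A -> TMA)
    declare an explicit ``var_name`` instead.
    """
    tokens = re.findall(r"[A-Z]+[a-z]*|[a-z]+|\d+", column_name)
    stem = "".join(t[0].upper() for t in tokens if t[0].isalpha())
    return stem or "X"


@dataclass(frozen=True)
class TestDefinition:
    """One test of a battery: identifiers, valid score range, direction."""

    __test__ = False  # "Test" prefix is domain vocabulary, not a pytest class

    test_id: str
    column_name: str
    property_name: str
    value_min: float
    value_max: float
    higher_is_better: bool = True
    var_name: str | None = None

    def __post_init__(self) -> None:
        for attr in ("test_id", "column_name", "property_name"):
            if not getattr(self, attr):
                raise SchemaError(f"test definition with empty {attr}")
        if not self.value_min < self.value_max:
            raise SchemaError(
                f"test {self.test_id!r}: invalid range "
                f"[{self.value_min}, {self.value_max}] (min must be < max)"
            )

    @property
    def var_stem(self) -> str:
        return self.var_name or _derive_var_stem(self.column_name)

    def in_range(self, value: float) -> bool:
        return self.value_min <= value <= self.value_max


@dataclass(frozen=True)
class BatterySchema:
    """An ordered battery of tests plus the fixed demographic fields."""

    battery_id: str
    tests: tuple[TestDefinition, ...]
    demographic_fields: tuple[str, ...] = DEMOGRAPHIC_FIELDS

    def __post_init__(self) -> None:
        if not self.battery_id:
            raise SchemaError("battery_id must be nonempty")
        if not self.tests:
            raise SchemaError(f"battery {self.battery_id!r} declares no tests")
        object.__setattr__(self, "tests", tuple(self.tests))
        for attr in ("test_id", "column_name", "property_name"):
            seen: dict[str, str] = {}
            for t in self.tests:
                key = getattr(t, attr)
                if key in seen:
                    raise SchemaError(
                        f"duplicate {attr} {key!r} shared by tests "
                        f"{seen[key]!r} and {t.test_id!r}"
                    )
                seen[key] = t.test_id

    @property
    def test_ids(self) -> tuple[str, ...]:
        return tuple(t.test_id for t in self.tests)

    def by_id(self, test_id: str) -> TestDefinition:
        for t in self.tests:
            if t.test_id == test_id:
                return t
        raise KeyError(test_id)

    def by_column(self, column_name: str) -> TestDefinition | None:
        for t in self.tests:
            if t.column_name == column_name:
                return t
        return None

    @property
    def property_map(self) -> dict[str, str]:
        """Mapping property_name -> test_id, as used by the rule engine."""
        return {t.property_name: t.test_id for t in self.tests}


@dataclass
class SubjectRecord:
    """One validated case: demographics plus a partial score map.

    ``scores`` may be empty — a record carrying only its identifiers is a
    legitimate screening input (the engine reports it as ``no_data``).
    """

    subject_id: str
    evaluation_index: int = 1
    sex: str | None = None
    age: float | None = None
    education: float | None = None
    scores: dict[str, float] = field(default_factory=dict)
    gold_label: int | None = None
    battery_id: str | None = None

    def to_row(self, schema: BatterySchema) -> dict[str, str]:
        """Render back to a raw CSV row (column-name keys, '' for missing)."""
        row = {
            "subject_id": self.subject_id,
            "evaluation_index": str(self.evaluation_index),
            "sex": "" if self.sex is None else str(self.sex),
            "age": _num_str(self.age),
            "education": _num_str(self.education),
        }
        for t in schema.tests:
            row[t.column_name] = (
                _num_str(self.scores[t.test_id]) if t.test_id in self.scores else ""
            )
        if self.gold_label is not None:
            row[GOLD_COLUMN] = str(self.gold_label)
        return row


def _num_str(v: float | None) -> str:
    if v is None:
        return ""
    return f"{float(v):g}"


@dataclass(frozen=True)
class Violation:
    """One range or parse failure, with enough context to act on it."""

    subject_id: str
    test_id: str
    value: object
    message: str
    value_min: float | None = None
    value_max: float | None = None


@dataclass
class ValidationReport:
    """Batch validation summary for :func:`read_cases`."""

    n_rows: int = 0
    n_valid: int = 0
    n_rejected: int = 0
    violations: list[Violation] = field(default_factory=list)
    unknown_columns: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations and not self.unknown_columns


# ---------------------------------------------------------------------------
# schema file I/O — flat CSV, one row per test
# ---------------------------------------------------------------------------

def load_schema(path: str | Path) -> BatterySchema:
    """Read a battery schema from its flat CSV carrier.

    Columns: battery_id, test_id, column_name, property_name, min, max,
    higher_is_better, var_name (the last one optional/blank).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty schema file")
        rows = list(reader)
    if not rows:
        raise SchemaError(f"{path}: schema declares no tests")
    battery_id = (rows[0].get("battery_id") or "").strip() or path.stem
    tests = []
    for row in rows:
        try:
            vmin = float(row["min"])
            vmax = float(row["max"])
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(
                f"{path}: test {row.get('test_id')!r}: bad range cells ({exc})"
            ) from None
        tests.append(
            TestDefinition(
                test_id=(row.get("test_id") or "").strip(),
                column_name=(row.get("column_name") or "").strip(),
                property_name=(row.get("property_name") or "").strip(),
                value_min=vmin,
                value_max=vmax,
                higher_is_better=_parse_bool(row.get("higher_is_better", "1")),
                var_name=(row.get("var_name") or "").strip() or None,
            )
        )
    return BatterySchema(battery_id=battery_id, tests=tuple(tests))


def dump_schema(schema: BatterySchema, path: str | Path) -> None:
    """Write the canonical flat-CSV form (stable bytes for a given schema)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_SCHEMA_COLUMNS)
        for t in schema.tests:
            writer.writerow(
                [
                    schema.battery_id,
                    t.test_id,
                    t.column_name,
                    t.property_name,
                    _num_str(t.value_min),
                    _num_str(t.value_max),
                    "1" if t.higher_is_better else "0",
                    t.var_name or "",
                ]
            )


def _parse_bool(cell: object) -> bool:
    text = str(cell).strip().lower()
    if text in {"1", "true", "yes", "y"}:
        return True
    if text in {"0", "false", "no", "n"}:
        return False
    raise SchemaError(f"cannot parse boolean cell {cell!r}")


# ---------------------------------------------------------------------------
# record validation
# ---------------------------------------------------------------------------

def validate_record(
    schema: BatterySchema,
    row: Mapping[str, object],
    mode: str = "strict",
) -> tuple[SubjectRecord | None, list[Violation]]:
    """Validate one raw row against the battery schema.

    Present scores are range-checked; absent cells simply stay absent.  In
    ``strict`` mode any violation rejects the record (returns ``None``); in
    ``lenient`` mode the offending scores are dropped and the rest of the
    record is kept.  Either way every violation is reported with the test,
    the offending value and the allowed range.
    """
    if mode not in ("strict", "lenient"):
        raise ValueError(f"mode must be 'strict' or 'lenient', got {mode!r}")
    subject_id = str(row.get("subject_id", "") or "").strip()
    if not subject_id:
        raise ValueError("row has no subject_id")

    violations: list[Violation] = []
    scores: dict[str, float] = {}
    for t in schema.tests:
        cell = row.get(t.column_name)
        if cell is None and t.test_id in row:  # accept test_id keys too
            cell = row.get(t.test_id)
        if is_missing(cell):
            continue
        try:
            value = float(cell)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            violations.append(
                Violation(
                    subject_id,
                    t.test_id,
                    cell,
                    f"non-numeric score {cell!r} for test {t.test_id!r}",
                    t.value_min,
                    t.value_max,
                )
            )
            continue
        if not t.in_range(value):
            violations.append(
                Violation(
                    subject_id,
                    t.test_id,
                    value,
                    f"score {value:g} for test {t.test_id!r} outside "
                    f"[{t.value_min:g}, {t.value_max:g}]",
                    t.value_min,
                    t.value_max,
                )
            )
            continue
        scores[t.test_id] = value

    if violations and mode == "strict":
        return None, violations

    record = SubjectRecord(
        subject_id=subject_id,
        evaluation_index=_parse_int(row.get("evaluation_index"), default=1),
        sex=_parse_opt_str(row.get("sex")),
        age=_parse_opt_float(row.get("age")),
        education=_parse_opt_float(row.get("education")),
        scores=scores,
        gold_label=_parse_gold(row.get(GOLD_COLUMN)),
        battery_id=schema.battery_id,
    )
    return record, violations


def _parse_int(cell: object, default: int) -> int:
    if is_missing(cell):
        return default
    return int(float(str(cell)))


def _parse_opt_str(cell: object) -> str | None:
    if is_missing(cell):
        return None
    return str(cell).strip()


def _parse_opt_float(cell: object) -> float | None:
    if is_missing(cell):
        return None
    return float(str(cell))


def _parse_gold(cell: object) -> int | None:
    if is_missing(cell):
        return None
    label = int(float(str(cell)))
    if label not in (0, 1):
        raise ValueError(f"gold label must be 0 or 1, got {cell!r}")
    return label


# ---------------------------------------------------------------------------
# case CSV I/O
# ---------------------------------------------------------------------------

def read_cases(
    path: str | Path,
    schema: BatterySchema,
    mode: str = "strict",
) -> tuple[list[SubjectRecord], ValidationReport]:
    """Read a case CSV, validating every row against the schema.

    Columns the schema does not know are ignored (reported once each in the
    returned report).  In strict mode rejected rows are counted so that
    ``n_valid + n_rejected == n_rows``.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames
        if header is None:
            raise CaseFileError(f"{path}: no header row")
        if "subject_id" not in header:
            raise CaseFileError(f"{path}: header lacks required column 'subject_id'")
        known = (
            {t.column_name for t in schema.tests}
            | {t.test_id for t in schema.tests}
            | set(DEMOGRAPHIC_FIELDS)
            | {GOLD_COLUMN}
        )
        report = ValidationReport(
            unknown_columns=[c for c in header if c not in known]
        )
        records: list[SubjectRecord] = []
        for row in reader:
            report.n_rows += 1
            record, violations = validate_record(schema, row, mode=mode)
            report.violations.extend(violations)
            if record is None:
                report.n_rejected += 1
            else:
                report.n_valid += 1
                records.append(record)
    return records, report


def write_cases(
    records: Iterable[SubjectRecord],
    schema: BatterySchema,
    path: str | Path,
    include_gold: bool = True,
) -> None:
    """Write records back to CSV (inverse of :func:`read_cases`)."""
    records = list(records)
    columns = list(DEMOGRAPHIC_FIELDS) + [t.column_name for t in schema.tests]
    if include_gold and any(r.gold_label is not None for r in records):
        columns.append(GOLD_COLUMN)
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, lineterminator="\n")
        writer.writeheader()
        for r in records:
            row = r.to_row(schema)
            writer.writerow({c: row.get(c, "") for c in columns})
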