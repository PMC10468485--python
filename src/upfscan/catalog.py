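"""Label-record data model, catalog readers/writers, and validation.

A catalog is an ordered collection of :class:`ProductRecord`, one per packaged
item, carrying the nutrition-facts panel (per 100 g or per 100 mL), the
free-text ingredient list, the food subgroup, and — when available — the
reference NOVA group (1–4) assigned by a trained researcher.

Missing is a first-class value here: an undeclared nutrient is ``None``,
never zero.  This matters because most Brazilian labels at the time of the
study did not declare sugars, and an undeclared quantity must never trigger
a nutrient-excess flag downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "Basis",
    "NutritionFacts",
    "ProductRecord",
    "ValidationIssue",
    "ValidationReport",
    "CatalogError",
    "SchemaError",
    "DuplicateIdError",
    "NumericParseError",
    "read_catalog",
    "write_catalog",
    "validate_record",
    "validate_catalog",
    "write_results",
    "CATALOG_COLUMNS",
]

#: Exact catalog column order for CSV round trips.
CATALOG_COLUMNS = [
    "product_id",
    "name",
    "subgroup",
    "nova_group",
    "basis",
    "energy_kcal",
    "total_fat_g",
    "sat_fat_g",
    "trans_fat_g",
    "sodium_mg",
    "total_sugars_g",
    "added_sugars_g",
    "ingredients_text",
]

REQUIRED_COLUMNS = ["product_id", "subgroup", "basis", "energy_kcal", "ingredients_text"]

NUMERIC_FIELDS = [
    "energy_kcal",
    "total_fat_g",
    "sat_fat_g",
    "trans_fat_g",
    "sodium_mg",
    "total_sugars_g",
    "added_sugars_g",
]


class CatalogError(Exception):
    """Base class for catalog I/O failures."""


class SchemaError(CatalogError):
    """A required column/key is absent from the input."""


class DuplicateIdError(CatalogError):
    """The same product_id appears more than once."""

    def __init__(self, duplicates: Sequence[str]):
        self.duplicates = list(duplicates)
        super().__init__(f"duplicate product_id values: {', '.join(self.duplicates)}")


class NumericParseError(CatalogError):
    """A numeric cell could not be parsed."""

    def __init__(self, row: int, column: str, value: str):
        self.row, self.column, self.value = row, column, value
        super().__init__(f"row {row}: cannot parse {column}={value!r} as a number")


class Basis(str, Enum):
    per_100g = "per_100g"
    per_100ml = "per_100ml"


class NutritionFacts(BaseModel):
    """Per-100 g/100 mL panel quantities; ``None`` means not declared."""

    model_config = ConfigDict(frozen=True)

    basis: Basis
    energy_kcal: float
    total_fat_g: Optional[float] = None
    sat_fat_g: Optional[float] = None
    trans_fat_g: Optional[float] = None
    sodium_mg: Optional[float] = None
    total_sugars_g: Optional[float] = None
    added_sugars_g: Optional[float] = None


class ProductRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    product_id: str
    name: str = ""
    subgroup: str
    nova_group: Optional[int] = None
    facts: NutritionFacts
    ingredients_text: str = ""

    @property
    def sugar_declared(self) -> bool:
        """True when the panel voluntarily declares total sugars."""
        return self.facts.total_sugars_g is not None


@dataclass(frozen=True)
class ValidationIssue:
    product_id: str
    field: str
    message: str
    level: str  # "error" | "warning"


@dataclass
class ValidationReport:
    """Errors exclude a record from downstream stages; warnings never do."""

    errors: list[ValidationIssue] = field(default_factory=list)
    warnings: list[ValidationIssue] = field(default_factory=list)

    def extend(self, issues: Iterable[ValidationIssue]) -> None:
        for issue in issues:
            (self.errors if issue.level == "error" else self.warnings).append(issue)

    @property
    def excluded_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for issue in self.errors:
            seen.setdefault(issue.product_id, None)
        return list(seen)


def _parse_number(raw: object, row: int, column: str) -> Optional[float]:
    if raw is None:
        return None
    if isinstance(raw, (int, float)):
        if isinstance(raw, float) and math.isnan(raw):
            return None
        return float(raw)
    text = str(raw).strip()
    if text == "":
        return None
    try:
        return float(text.replace(",", "."))
    except ValueError:
        raise NumericParseError(row, column, text) from None


def _record_from_mapping(row: dict, index: int) -> ProductRecord:
    nova_raw = row.get("nova_group")
    nova: Optional[int]
    if nova_raw is None or str(nova_raw).strip() == "":
        nova = None
    else:
        parsed = _parse_number(nova_raw, index, "nova_group")
        nova = int(parsed) if parsed is not None else None

    basis_raw = str(row.get("basis", "")).strip()
    try:
        basis = Basis(basis_raw)
    except ValueError:
        raise SchemaError(
            f"row {index}: basis must be one of {[b.value for b in Basis]}, got {basis_raw!r}"
        ) from None

    facts = NutritionFacts(
        basis=basis,
        energy_kcal=_parse_number(row.get("energy_kcal"), index, "energy_kcal"),
        total_fat_g=_parse_number(row.get("total_fat_g"), index, "total_fat_g"),
        sat_fat_g=_parse_number(row.get("sat_fat_g"), index, "sat_fat_g"),
        trans_fat_g=_parse_number(row.get("trans_fat_g"), index, "trans_fat_g"),
        sodium_mg=_parse_number(row.get("sodium_mg"), index, "sodium_mg"),
        total_sugars_g=_parse_number(row.get("total_sugars_g"), index, "total_sugars_g"),
        added_sugars_g=_parse_number(row.get("added_sugars_g"), index, "added_sugars_g"),
    )
    return ProductRecord(
        product_id=str(row.get("product_id", "")).strip(),
        name=str(row.get("name", "") or ""),
        subgroup=str(row.get("subgroup", "")).strip(),
        nova_group=nova,
        facts=facts,
        ingredients_text=str(row.get("ingredients_text", "") or ""),
    )


def read_catalog(path: str | Path, format: Optional[str] = None) -> list[ProductRecord]:
    """Read a product catalog from CSV or JSON.

    Missing optional cells map to ``None`` (missing), never to zero.  Raises
    :class:`SchemaError` when a required column is absent,
    :class:`DuplicateIdError` on repeated ids, and :class:`NumericParseError`
    (with the offending row index) on unparseable numbers.
    """
    path = Path(path)
    if not path.exists():
        raise CatalogError(f"catalog file not found: {path}")
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")

    if fmt == "csv":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
        rows = [
            {k: (v if str(v).strip() != "" else None) for k, v in rec.items()}
            for rec in frame.to_dict(orient="records")
        ]
        columns = list(frame.columns)
    elif fmt == "json":
        with open(path, encoding="utf-8") as handle:
            payload = json.load(handle)
        if not isinstance(payload, list):
            raise SchemaError("JSON catalog must be a list of objects")
        rows = payload
        columns = sorted({key for row in rows for key in row}) if rows else REQUIRED_COLUMNS
    else:
        raise CatalogError(f"unknown catalog format {fmt!r}")

    missing = [col for col in REQUIRED_COLUMNS if col not in columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records = [_record_from_mapping(row, index) for index, row in enumerate(rows)]

    seen: dict[str, int] = {}
    duplicates = []
    for record in records:
        seen[record.product_id] = seen.get(record.product_id, 0) + 1
    duplicates = [pid for pid, count in seen.items() if count > 1]
    if duplicates:
        raise DuplicateIdError(duplicates)
    return records


def _facts_cell(value: Optional[float]) -> str:
    return "" if value is None else format(value, ".12g")


def write_catalog(records: Sequence[ProductRecord], path: str | Path, format: Optional[str] = None) -> None:
    """Write records back out with the canonical column order (CSV) or key set (JSON)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    rows = []
    for rec in records:
        facts = rec.facts
        rows.append(
            {
                "product_id": rec.product_id,
                "name": rec.name,
                "subgroup": rec.subgroup,
                "nova_group": rec.nova_group,
                "basis": facts.basis.value,
                "energy_kcal": facts.energy_kcal,
                "total_fat_g": facts.total_fat_g,
                "sat_fat_g": facts.sat_fat_g,
                "trans_fat_g": facts.trans_fat_g,
                "sodium_mg": facts.sodium_mg,
                "total_sugars_g": facts.total_sugars_g,
                "added_sugars_g": facts.added_sugars_g,
                "ingredients_text": rec.ingredients_text,
            }
        )
    if fmt == "json":
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(rows, handle, ensure_ascii=False, indent=1)
            handle.write("\n")
        return
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write(",".join(CATALOG_COLUMNS) + "\n")
        for row in rows:
            cells = []
            for col in CATALOG_COLUMNS:
                value = row[col]
                if value is None:
                    cells.append("")
                elif col in NUMERIC_FIELDS:
                    cells.append(_facts_cell(value))
                elif col == "nova_group":
                    cells.append(str(value))
                else:
                    text = str(value)
                    if any(ch in text for ch in ',"\n'):
                        text = '"' + text.replace('"', '""') + '"'
                    cells.append(text)
            handle.write(",".join(cells) + "\n")


def validate_record(record: ProductRecord) -> list[ValidationIssue]:
    """Pure consistency checks on one record.

    Negative quantities and out-of-range NOVA groups are errors; a saturated
    fat value exceeding total fat is a warning (both values are kept).
    """
    issues: list[ValidationIssue] = []
    pid = record.product_id
    if pid == "":
        issues.append(ValidationIssue(pid, "product_id", "empty product_id", "error"))
    facts = record.facts
    for name in NUMERIC_FIELDS:
        value = getattr(facts, name)
        if value is not None and value < 0:
            issues.append(ValidationIssue(pid, name, f"negative quantity ({value})", "error"))
    if record.nova_group is not None and record.nova_group not in (1, 2, 3, 4):
        issues.append(
            ValidationIssue(pid, "nova_group", f"nova_group must be 1-4, got {record.nova_group}", "error")
        )
    if (
        facts.sat_fat_g is not None
        and facts.total_fat_g is not None
        and facts.sat_fat_g > facts.total_fat_g
    ):
        issues.append(
            ValidationIssue(
                pid,
                "sat_fat_g",
                f"saturated fat ({facts.sat_fat_g} g) exceeds total fat ({facts.total_fat_g} g)",
                "warning",
            )
        )
    return issues


def validate_catalog(records: Sequence[ProductRecord]) -> ValidationReport:
    report = ValidationReport()
    for record in records:
        report.extend(validate_record(record))
    return report


def write_results(rows: pd.DataFrame, path: str | Path, float_decimals: int = 4) -> None:
    """Write a results table as CSV with a stable column order and fixed float precision.

    Two runs on the same input produce byte-identical files.
    """
    rows.to_csv(
        path,
        index=False,
        float_format=f"%.{float_decimals}f",
        lineterminator="\n",
        encoding="utf-8",
    )
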