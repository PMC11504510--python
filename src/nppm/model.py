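"""Domain types and I/O for product tables and assessment outputs.

One :class:`ProductRecord` holds everything the rule engines need for a single
commercial infant/toddler food product: nutrient composition per 100 g, package
facts, and the on-pack label features (claims, age labels, pouch instructions,
preparation instructions).

The on-disk formats are a flat CSV (one row per product, booleans serialised as
``true``/``false``, missing values as empty cells, claims packed as
``category:text`` entries separated by ``;``) and an equivalent nested JSON
(one object per product).  See ``docs/columns.md`` for the column dictionary.
"""

from __future__ import annotations

import json
import math
import re
from pathlib import Path
from typing import Any, Literal, Optional

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .errors import ProductValidationError, SchemaError

ClaimCategory = Literal["compositional", "nutritional", "health", "marketing"]

ProductGroup = Literal[
    "dry cereals and starches",
    "dairy foods",
    "fruit and vegetable purees",
    "savoury meals",
    "snacks and finger foods",
    "confectionery",
]

PackageType = Literal[
    "pouch",
    "jar",
    "bowl",
    "single-serve packet/sachet",
    "multi-serve box/packet",
]

#: kJ-to-kcal conversion used when a table reports energy in kJ only
#: (Australian labels declare kJ).
KJ_PER_KCAL = 4.184


class Claim(BaseModel):
    """One on-pack claim and its category under the NPPM taxonomy."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    text: str = Field(min_length=1)
    category: ClaimCategory


class LabelInfo(BaseModel):
    """Label and promotion features evaluated by the Part B engine."""

    model_config = ConfigDict(extra="forbid")

    claims: list[Claim] = Field(default_factory=list)
    ingredients_descending_order: bool = True
    #: amounts of added water/fruit reported in the ingredient list where present
    ingredient_list_amounts_complete: bool = True
    age_min_months: Optional[int] = Field(default=None, ge=0, le=48)
    age_max_months: Optional[int] = Field(default=None, ge=0, le=48)
    breastfeeding_statement_present: bool = False
    spoon_or_bowl_suggestion: bool = False
    no_spout_consumption_instruction: bool = False
    on_the_go_claim_present: bool = False
    preparation_instructions_present: bool = False
    preparation_instructions_suitable: bool = False

    @model_validator(mode="after")
    def _age_range_ordered(self) -> "LabelInfo":
        if (
            self.age_min_months is not None
            and self.age_max_months is not None
            and self.age_max_months < self.age_min_months
        ):
            raise ValueError("age_max_months must be >= age_min_months")
        return self


class ProductRecord(BaseModel):
    """One product's composition, packaging and label facts.

    Nutrients are per 100 g of product as sold.  ``fruit_pct`` and
    ``added_water_pct`` are % by weight and are *explicitly* missing (``None``)
    when the label does not report them — an undeclared amount is a distinct
    failure mode from a declared zero.
    """

    model_config = ConfigDict(extra="forbid")

    product_id: str = Field(min_length=1)
    brand: str = Field(min_length=1)
    name_text: str = ""
    subcategory: str = Field(min_length=1)
    product_group: ProductGroup
    package_type: PackageType
    has_spout: bool = False
    serve_size_g: Optional[float] = Field(default=None, gt=0)
    energy_kcal_per_100g: float = Field(ge=0)
    total_sugar_g_per_100g: float = Field(ge=0, le=100)
    sodium_mg_per_100g: float = Field(ge=0)
    protein_g_per_100g: float = Field(ge=0)
    total_fat_g_per_100g: float = Field(ge=0)
    industrial_trans_fat_present: bool = False
    added_free_sugars_present: bool = False
    fruit_pct: Optional[float] = Field(default=None, ge=0, le=100)
    added_water_pct: Optional[float] = Field(default=None, ge=0, le=100)
    fruit_amount_declared: bool = False
    water_amount_declared: bool = False
    cheese_named: bool = False
    protein_named: bool = False
    requires_preparation: bool = False
    label: LabelInfo = Field(default_factory=LabelInfo)

    @model_validator(mode="after")
    def _spout_only_on_pouches(self) -> "ProductRecord":
        if self.has_spout and self.package_type != "pouch":
            raise ValueError("has_spout is only meaningful for pouches")
        return self


# ---------------------------------------------------------------------------
# CSV <-> record plumbing

_BOOL_FIELDS = [
    "has_spout",
    "industrial_trans_fat_present",
    "added_free_sugars_present",
    "fruit_amount_declared",
    "water_amount_declared",
    "cheese_named",
    "protein_named",
    "requires_preparation",
]
_LABEL_BOOL_FIELDS = [
    "ingredients_descending_order",
    "ingredient_list_amounts_complete",
    "breastfeeding_statement_present",
    "spoon_or_bowl_suggestion",
    "no_spout_consumption_instruction",
    "on_the_go_claim_present",
    "preparation_instructions_present",
    "preparation_instructions_suitable",
]
_NUM_FIELDS = [
    "serve_size_g",
    "energy_kcal_per_100g",
    "total_sugar_g_per_100g",
    "sodium_mg_per_100g",
    "protein_g_per_100g",
    "total_fat_g_per_100g",
    "fruit_pct",
    "added_water_pct",
]
_LABEL_INT_FIELDS = ["age_min_months", "age_max_months"]

#: columns that must be present in a CSV product table; energy may instead be
#: supplied as energy_kj_per_100g
MANDATORY_COLUMNS = [
    "product_id",
    "brand",
    "subcategory",
    "product_group",
    "package_type",
    "energy_kcal_per_100g",
    "total_sugar_g_per_100g",
    "sodium_mg_per_100g",
    "protein_g_per_100g",
    "total_fat_g_per_100g",
]

CSV_COLUMNS = (
    ["product_id", "brand", "name_text", "subcategory", "product_group", "package_type"]
    + _BOOL_FIELDS[:1]
    + _NUM_FIELDS
    + _BOOL_FIELDS[1:]
    + ["claims"]
    + _LABEL_BOOL_FIELDS
    + _LABEL_INT_FIELDS
)


def _parse_bool(raw: str, *, context: str) -> bool:
    low = raw.strip().lower()
    if low in {"true", "1", "yes"}:
        return True
    if low in {"false", "0", "no"}:
        return False
    raise ProductValidationError(f"{context}: cannot parse boolean value {raw!r}")


def parse_claims(packed: str) -> list[dict[str, str]]:
    """Parse the packed CSV claims column ``category:text;category:text``."""
    claims: list[dict[str, str]] = []
    for chunk in packed.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        category, _, text = chunk.partition(":")
        claims.append({"category": category.strip(), "text": text.strip()})
    return claims


def pack_claims(claims: list[Claim]) -> str:
    return ";".join(f"{c.category}:{c.text}" for c in claims)


def _row_to_mapping(row: dict[str, str], row_no: int) -> dict[str, Any]:
    pid = row.get("product_id", f"<row {row_no}>") or f"<row {row_no}>"
    data: dict[str, Any] = {}
    label: dict[str, Any] = {}
    for key in ["product_id", "brand", "name_text", "subcategory", "product_group", "package_type"]:
        if key in row and row[key] != "":
            data[key] = row[key]
    for key in _NUM_FIELDS:
        raw = row.get(key, "")
        if raw != "":
            try:
                data[key] = float(raw)
            except ValueError as exc:
                raise ProductValidationError(
                    f"product {pid}: field {key}: not a number: {raw!r}",
                    product_id=pid,
                    field=key,
                ) from exc
    # kJ fallback: Australian labels report kJ; convert when kcal is absent
    if "energy_kcal_per_100g" not in data and row.get("energy_kj_per_100g", "") != "":
        data["energy_kcal_per_100g"] = float(row["energy_kj_per_100g"]) / KJ_PER_KCAL
    for key in _BOOL_FIELDS:
        raw = row.get(key, "")
        if raw != "":
            data[key] = _parse_bool(raw, context=f"product {pid}: field {key}")
    for key in _LABEL_BOOL_FIELDS:
        raw = row.get(key, "")
        if raw != "":
            label[key] = _parse_bool(raw, context=f"product {pid}: field {key}")
    for key in _LABEL_INT_FIELDS:
        raw = row.get(key, "")
        if raw != "":
            label[key] = int(float(raw))
    if row.get("claims", "") != "":
        label["claims"] = parse_claims(row["claims"])
    data["label"] = label
    return data


def _validate_mapping(data: dict[str, Any], row_no: int) -> ProductRecord:
    pid = str(data.get("product_id", f"<row {row_no}>"))
    try:
        return ProductRecord.model_validate(data)
    except ValidationError as exc:
        first = exc.errors()[0]
        field = ".".join(str(p) for p in first["loc"])
        raise ProductValidationError(
            f"product {pid} (row {row_no}): field {field}: {first['msg']}",
            product_id=pid,
            field=field,
        ) from exc


def read_products(path: str | Path, format: str | None = None) -> list[ProductRecord]:
    """Read and validate a product table from CSV or JSON.

    The format is inferred from the file suffix unless given explicitly.
    Raises :class:`SchemaError` when mandatory columns are missing and
    :class:`ProductValidationError` (naming product_id and field) on the first
    out-of-range value.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        raw = json.loads(path.read_text())
        if not isinstance(raw, list):
            raise SchemaError("JSON product table must be a list of objects")
        records = []
        for i, obj in enumerate(raw, start=1):
            missing = [c for c in MANDATORY_COLUMNS if c not in obj]
            if missing:
                raise SchemaError(f"object {i}: missing mandatory keys: {', '.join(missing)}")
            records.append(_validate_mapping(obj, i))
        return records
    if fmt != "csv":
        raise ValueError(f"unknown format {fmt!r}")
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [
        c
        for c in MANDATORY_COLUMNS
        if c not in frame.columns and not (c == "energy_kcal_per_100g" and "energy_kj_per_100g" in frame.columns)
    ]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records = []
    for i, row in enumerate(frame.to_dict(orient="records"), start=2):  # header is line 1
        records.append(_validate_mapping(_row_to_mapping(row, i), i))
    return records


def _record_to_row(record: ProductRecord) -> dict[str, Any]:
    row: dict[str, Any] = {}
    dump = record.model_dump()
    label = dump.pop("label")
    for key in CSV_COLUMNS:
        if key == "claims":
            row[key] = pack_claims(record.label.claims)
        elif key in dump:
            value = dump[key]
            row[key] = "" if value is None else value
        else:
            value = label[key]
            row[key] = "" if value is None else value
        if isinstance(row[key], bool):
            row[key] = "true" if row[key] else "false"
    return row


def write_products(records: list[ProductRecord], path: str | Path, format: str | None = None) -> None:
    """Write a product table as CSV or JSON (inverse of :func:`read_products`)."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        path.write_text(json.dumps([r.model_dump() for r in records], indent=1))
        return
    frame = pd.DataFrame([_record_to_row(r) for r in records], columns=CSV_COLUMNS)
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Assessment output (long form)

ASSESSMENT_COLUMNS = [
    "product_id",
    "part",
    "requirement_id",
    "applicable",
    "passed",
    "observed",
    "unit",
    "threshold",
    "deviation_pct",
    "flag_required",
    "note",
]


def write_assessments(assessments: list, path: str | Path, format: str | None = None) -> None:
    """Write assessments in long form: one row per (product, requirement).

    CSV columns: see :data:`ASSESSMENT_COLUMNS`.  The JSON alternative is a
    lossless nested dump of each :class:`~nppm.pipeline.ProductAssessment`.
    Refuses an empty list rather than producing an empty file.
    """
    if not assessments:
        raise ValueError("refusing to write an empty assessment list")
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "json":
        path.write_text(json.dumps([a.to_dict() for a in assessments], indent=1))
        return
    rows = []
    for a in assessments:
        for part, results in (("A", a.part_a), ("B", a.part_b)):
            for r in results:
                rows.append(
                    {
                        "product_id": a.product_id,
                        "part": part,
                        "requirement_id": r.requirement_id,
                        "applicable": "true" if r.applicable else "false",
                        "passed": "" if r.passed is None else ("true" if r.passed else "false"),
                        "observed": "" if r.observed is None else r.observed,
                        "unit": r.unit or "",
                        "threshold": "" if r.threshold is None else r.threshold,
                        "deviation_pct": "" if r.deviation_pct is None else r.deviation_pct,
                        "flag_required": ""
                        if r.flag_required is None
                        else ("true" if r.flag_required else "false"),
                        "note": r.note,
                    }
                )
    pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS).to_csv(path, index=False)


def read_assessments(path: str | Path) -> list:
    """Read a long-form assessment CSV back into ProductAssessment objects.

    Rollups are recomputed from the constituent checks, so a write->read
    round-trip is the identity on verdicts.
    """
    from .part_a import CheckResult
    from .pipeline import ProductAssessment, _rollups

    frame = pd.read_csv(Path(path), dtype=str, keep_default_na=False)
    missing = [c for c in ASSESSMENT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing assessment column(s): {', '.join(missing)}")
    by_product: dict[str, dict[str, list[CheckResult]]] = {}
    order: list[str] = []
    for row in frame.to_dict(orient="records"):
        pid = row["product_id"]
        if pid not in by_product:
            by_product[pid] = {"A": [], "B": []}
            order.append(pid)
        result = CheckResult(
            requirement_id=row["requirement_id"],
            applicable=row["applicable"] == "true",
            passed=None if row["passed"] == "" else row["passed"] == "true",
            observed=None if row["observed"] == "" else float(row["observed"]),
            unit=row["unit"] or None,
            threshold=None if row["threshold"] == "" else float(row["threshold"]),
            deviation_pct=None if row["deviation_pct"] == "" else float(row["deviation_pct"]),
            flag_required=None if row["flag_required"] == "" else row["flag_required"] == "true",
            note=row["note"],
        )
        by_product[pid][row["part"]].append(result)
    assessments = []
    for pid in order:
        part_a, part_b = by_product[pid]["A"], by_product[pid]["B"]
        meets_a, meets_b, flag = _rollups(part_a, part_b)
        assessments.append(
            ProductAssessment(
                product_id=pid,
                part_a=part_a,
                part_b=part_b,
                meets_all_nutrient=meets_a,
                meets_all_promotion=meets_b,
                high_sugar_flag_required=flag,
            )
        )
    return assessments


# ---------------------------------------------------------------------------
# Claim tagging (assistive; authoritative categories come from the input table)


def load_claim_lexicon(path: str | Path | None = None) -> list[tuple[re.Pattern, str]]:
    """Load an ordered pattern->category lexicon (YAML list of {pattern, category})."""
    if path is None:
        path = Path(__file__).parent / "data" / "claim_lexicon.yaml"
    entries = yaml.safe_load(Path(path).read_text())
    lexicon = []
    for entry in entries:
        lexicon.append((re.compile(entry["pattern"], re.IGNORECASE), entry["category"]))
    return lexicon


def tag_claim(text: str, lexicon: list[tuple[re.Pattern, str]]) -> Claim:
    """Categorise a claim string by first lexicon match; default ``marketing``.

    Assistive only — the study's canonical categorisation is manual, and the
    engines take categories from the input table when present.
    """
    if not text or not text.strip():
        raise ValueError("claim text must be non-empty")
    for pattern, category in lexicon:
        if pattern.search(text):
            return Claim(text=text, category=category)
    return Claim(text=text, category="marketing")
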