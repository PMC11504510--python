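"""Orchestration: sampling, per-product assessment, and summary reporting.

The summary mirrors the published compliance table: for every requirement a
numerator (products passing), a denominator (products to which the requirement
applied and could be evaluated), and the proportion rounded half-up to integer
percent.  Denominators always count applicable products only — never the full
sample — matching the convention "of the N products subject to ...".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._util import round_half_up
from .model import ProductRecord
from .part_a import (
    NUTRIENT_REQUIREMENTS,
    PART_A_REQUIREMENTS,
    CheckResult,
    evaluate_part_a,
    meets_all_nutrient_requirements,
)
from .part_b import PART_B_REQUIREMENTS, evaluate_part_b, meets_all_promotional_requirements
from .ruleset import RuleSet

logger = logging.getLogger(__name__)


@dataclass
class ProductAssessment:
    """All check results for one product plus rollup verdicts."""

    product_id: str
    part_a: list[CheckResult]
    part_b: list[CheckResult]
    meets_all_nutrient: bool
    meets_all_promotion: bool
    high_sugar_flag_required: Optional[bool]

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return {
            "product_id": self.product_id,
            "part_a": [asdict(r) for r in self.part_a],
            "part_b": [asdict(r) for r in self.part_b],
            "meets_all_nutrient": self.meets_all_nutrient,
            "meets_all_promotion": self.meets_all_promotion,
            "high_sugar_flag_required": self.high_sugar_flag_required,
        }


@dataclass(frozen=True)
class Row:
    """One summary line: numerator / denominator -> percent (half-up)."""

    numerator: int
    denominator: int

    @property
    def proportion_pct(self) -> Optional[int]:
        if self.denominator == 0:
            return None
        return round_half_up(self.numerator / self.denominator * 100.0)

    @property
    def failure_pct(self) -> Optional[int]:
        if self.denominator == 0:
            return None
        return round_half_up((self.denominator - self.numerator) / self.denominator * 100.0)


@dataclass
class SummaryReport:
    """Per-requirement compliance fractions plus overall and per-package rows."""

    requirements: dict[str, Row]
    all_nutrient: Row
    all_promotion: Row
    high_sugar_flag_required: Row
    package_type: dict[str, Row] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def to_rows(self) -> list[tuple[str, int, int, Optional[int]]]:
        out = []
        for req, row in self.requirements.items():
            out.append((req, row.numerator, row.denominator, row.proportion_pct))
        out.append(
            (
                "all_nutrient",
                self.all_nutrient.numerator,
                self.all_nutrient.denominator,
                self.all_nutrient.proportion_pct,
            )
        )
        out.append(
            (
                "all_promotion",
                self.all_promotion.numerator,
                self.all_promotion.denominator,
                self.all_promotion.proportion_pct,
            )
        )
        out.append(
            (
                "high_sugar_flag_required",
                self.high_sugar_flag_required.numerator,
                self.high_sugar_flag_required.denominator,
                self.high_sugar_flag_required.proportion_pct,
            )
        )
        return out

    def to_markdown(self) -> str:
        lines = [
            "| requirement | met | subject to | % met |",
            "| --- | ---: | ---: | ---: |",
        ]
        for req, num, den, pct in self.to_rows():
            pct_text = "-" if pct is None else str(pct)
            lines.append(f"| {req} | {num} | {den} | {pct_text} |")
        if self.package_type:
            lines.append("")
            lines.append("| package type | criteria met | criteria applicable | % met |")
            lines.append("| --- | ---: | ---: | ---: |")
            for ptype, row in self.package_type.items():
                lines.append(
                    f"| {ptype} | {row.numerator} | {row.denominator} | {row.proportion_pct} |"
                )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Sampling


def sample_products(
    products: list[ProductRecord], max_per_subcategory: int = 5, seed: int = 0
) -> list[ProductRecord]:
    """Rapid-evaluation sampling: up to N products per subcategory across brands.

    Per subcategory: if at most ``max_per_subcategory`` products exist, all are
    selected.  Otherwise one product is drawn uniformly per brand; remaining
    slots are filled uniformly from the rest.  When there are more brands than
    slots, a uniform subset of brands contributes one product each.
    Deterministic for a given seed; output preserves input order.
    """
    if not products:
        warnings.warn("sample_products called with no products", stacklevel=2)
        return []
    rng = np.random.default_rng(seed)
    by_subcat: dict[str, list[int]] = {}
    for idx, product in enumerate(products):
        by_subcat.setdefault(product.subcategory, []).append(idx)

    chosen: set[int] = set()
    for subcat in sorted(by_subcat):
        indices = by_subcat[subcat]
        if len(indices) <= max_per_subcategory:
            chosen.update(indices)
            continue
        by_brand: dict[str, list[int]] = {}
        for idx in indices:
            by_brand.setdefault(products[idx].brand, []).append(idx)
        brands = sorted(by_brand)
        if len(brands) >= max_per_subcategory:
            picked_brands = rng.choice(len(brands), size=max_per_subcategory, replace=False)
            for b in picked_brands:
                members = by_brand[brands[b]]
                chosen.add(members[rng.integers(len(members))])
        else:
            selected = []
            for brand in brands:
                members = by_brand[brand]
                selected.append(members[rng.integers(len(members))])
            remaining = [i for i in indices if i not in selected]
            extra = max_per_subcategory - len(selected)
            if extra > 0 and remaining:
                picks = rng.choice(len(remaining), size=min(extra, len(remaining)), replace=False)
                selected.extend(remaining[p] for p in picks)
            chosen.update(selected)
    return [products[i] for i in sorted(chosen)]


# ---------------------------------------------------------------------------
# Assessment and aggregation


def _rollups(
    part_a: list[CheckResult], part_b: list[CheckResult]
) -> tuple[bool, bool, Optional[bool]]:
    flag = next(
        (r.flag_required for r in part_a if r.requirement_id == "high_sugar_flag" and r.applicable),
        None,
    )
    return (
        meets_all_nutrient_requirements(part_a),
        meets_all_promotional_requirements(part_b),
        flag,
    )


def assess(products: list[ProductRecord], rules: RuleSet) -> list[ProductAssessment]:
    """Run both engines over every product; deterministic."""
    assessments = []
    for product in products:
        try:
            part_a = evaluate_part_a(product, rules)
            part_b = evaluate_part_b(product, rules)
        except Exception as exc:
            raise type(exc)(f"product {product.product_id}: {exc}") from exc
        meets_a, meets_b, flag = _rollups(part_a, part_b)
        assessments.append(
            ProductAssessment(
                product_id=product.product_id,
                part_a=part_a,
                part_b=part_b,
                meets_all_nutrient=meets_a,
                meets_all_promotion=meets_b,
                high_sugar_flag_required=flag,
            )
        )
    return assessments


def summarize(assessments: list[ProductAssessment]) -> SummaryReport:
    """Aggregate assessments into the compliance-table summary.

    Per requirement, the denominator counts assessments where the check was
    applicable and evaluable; insufficient-input verdicts are excluded from
    numerator and denominator alike.
    """
    if not assessments:
        raise ValueError("summarize requires at least one assessment")

    requirements: dict[str, Row] = {}
    evaluable_ids = [r for r in PART_A_REQUIREMENTS if r != "high_sugar_flag"] + PART_B_REQUIREMENTS
    for requirement_id in evaluable_ids:
        num = den = 0
        for a in assessments:
            for r in a.part_a + a.part_b:
                if r.requirement_id == requirement_id and r.applicable and r.passed is not None:
                    den += 1
                    num += int(r.passed)
        requirements[requirement_id] = Row(num, den)

    flag_num = sum(1 for a in assessments if a.high_sugar_flag_required is True)
    flag_den = sum(1 for a in assessments if a.high_sugar_flag_required is not None)

    nutrient_subject = [
        a
        for a in assessments
        if any(
            r.requirement_id in NUTRIENT_REQUIREMENTS and r.applicable for r in a.part_a
        )
    ]
    all_nutrient = Row(
        sum(1 for a in nutrient_subject if a.meets_all_nutrient), len(nutrient_subject)
    )
    all_promotion = Row(
        sum(1 for a in assessments if a.meets_all_promotion), len(assessments)
    )

    return SummaryReport(
        requirements=requirements,
        all_nutrient=all_nutrient,
        all_promotion=all_promotion,
        high_sugar_flag_required=Row(flag_num, flag_den),
        metadata={"n_products": len(assessments)},
    )


def package_type_compliance(
    assessments: list[ProductAssessment], products: list[ProductRecord]
) -> dict[str, Row]:
    """Share of applicable criteria met, pooled across products per package type.

    Counts every applicable, evaluable Part A and Part B check (the
    informational high-in-sugar flag is excluded).  Types with no products are
    omitted.
    """
    type_of = {p.product_id: p.package_type for p in products}
    counts: dict[str, list[int]] = {}
    for a in assessments:
        ptype = type_of.get(a.product_id)
        if ptype is None:
            raise KeyError(f"no product record for assessment {a.product_id}")
        met, applicable = counts.setdefault(ptype, [0, 0])
        for r in a.part_a + a.part_b:
            if r.applicable and r.passed is not None:
                counts[ptype][1] += 1
                counts[ptype][0] += int(r.passed)
    return {ptype: Row(met, applicable) for ptype, (met, applicable) in sorted(counts.items())}
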