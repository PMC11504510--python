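"""Part A engine: composition and content-labelling requirements.

Evaluates one product against the NPPM nutrient thresholds: energy density
(minimum per 100 g, or a 50 kcal/serve cap for snacks), sodium per 100 kcal
(with a higher limit where cheese is named in the product name), total sugar as
% of energy, the added-free-sugar and industrial-trans-fat prohibitions,
added-water and fruit-content rules, protein minima (per 100 kcal and % by
weight), the fat maximum, and the informational "high in sugar" flag.

Conventions:

* threshold comparisons are exact and inclusive (``observed <= max`` passes,
  ``observed >= min`` passes) — only the *reported* deviation is rounded;
* a check a subcategory does not define is not applicable (``passed`` missing);
* an applicable check whose inputs are missing (e.g. no serve size) yields a
  missing verdict with a note and a logged warning, and is excluded from both
  numerator and denominator downstream;
* the high-in-sugar flag records whether the flag would be *required*, it is
  never a pass/fail verdict on the product.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from ._util import round_half_up
from .model import ProductRecord
from .ruleset import RuleSet, SubcategoryRules

logger = logging.getLogger(__name__)

#: fixed evaluation order; evaluate_part_a always returns one result per id
PART_A_REQUIREMENTS = [
    "category_permitted",
    "energy_density",
    "sodium",
    "total_sugar",
    "added_sugar",
    "fruit_content",
    "added_water",
    "protein_content",
    "protein_weight",
    "total_fat",
    "trans_fat",
    "high_sugar_flag",
]

#: requirement ids that count toward "meets all nutrient content requirements"
NUTRIENT_REQUIREMENTS = [
    "energy_density",
    "sodium",
    "total_sugar",
    "added_sugar",
    "fruit_content",
    "added_water",
    "protein_content",
    "protein_weight",
    "total_fat",
    "trans_fat",
]


@dataclass
class CheckResult:
    """Outcome of one requirement on one product.

    ``deviation_pct`` is the raw signed relative departure from the threshold,
    ``(observed - threshold) / threshold * 100``; use
    :attr:`deviation_pct_rounded` for the half-up integer convention used in
    reporting (e.g. 42.8 % water against a 25 % limit reports +71).
    """

    requirement_id: str
    applicable: bool
    passed: Optional[bool] = None
    observed: Optional[float] = None
    unit: Optional[str] = None
    threshold: Optional[float] = None
    deviation_pct: Optional[float] = None
    flag_required: Optional[bool] = None
    note: str = ""

    def __post_init__(self) -> None:
        if not self.applicable and self.passed is not None:
            raise ValueError("not-applicable check cannot carry a verdict")

    @property
    def deviation_pct_rounded(self) -> Optional[int]:
        if self.deviation_pct is None:
            return None
        return round_half_up(self.deviation_pct)


# ---------------------------------------------------------------------------
# Per-100-kcal normalisations


def pct_energy_from_sugar(
    sugar_g_per_100g: float, energy_kcal_per_100g: float, factor_kcal_per_g: float = 4.0
) -> float:
    """Share of energy contributed by total sugar, in percent."""
    if energy_kcal_per_100g <= 0:
        raise ValueError("energy must be > 0 to compute % energy from sugar")
    return sugar_g_per_100g * factor_kcal_per_g / energy_kcal_per_100g * 100.0


def sodium_per_100kcal(sodium_mg_per_100g: float, energy_kcal_per_100g: float) -> float:
    """Sodium normalised to mg per 100 kcal."""
    if energy_kcal_per_100g <= 0:
        raise ValueError("energy must be > 0 to normalise sodium per 100 kcal")
    return sodium_mg_per_100g / energy_kcal_per_100g * 100.0


def per_100kcal(amount_per_100g: float, energy_kcal_per_100g: float) -> float:
    """Generic per-100 g -> per-100 kcal normalisation."""
    if energy_kcal_per_100g <= 0:
        raise ValueError("energy must be > 0 to normalise per 100 kcal")
    return amount_per_100g / energy_kcal_per_100g * 100.0


def energy_per_serve(energy_kcal_per_100g: float, serve_size_g: float) -> float:
    """Energy in one serve, kcal."""
    if serve_size_g <= 0:
        raise ValueError("serve size must be > 0")
    return energy_kcal_per_100g * serve_size_g / 100.0


def raw_deviation_pct(observed: float, threshold: float) -> float:
    """Signed relative departure from a threshold, percent (positive above)."""
    if threshold <= 0:
        raise ValueError("deviation is only defined for a positive threshold")
    return (observed - threshold) / threshold * 100.0


def deviation_pct(observed: float, threshold: float) -> int:
    """Reported deviation: raw deviation rounded half-up to the nearest integer.

    deviation_pct(42.8, 25) == 71: a vegetable puree at 42.8 % added water
    exceeds the 25 % limit by 71 %.
    """
    return round_half_up(raw_deviation_pct(observed, threshold))


# ---------------------------------------------------------------------------
# Evaluation


def _na(requirement_id: str, note: str = "") -> CheckResult:
    return CheckResult(requirement_id=requirement_id, applicable=False, note=note)


def _insufficient(requirement_id: str, product_id: str, note: str, **kw) -> CheckResult:
    logger.warning("product %s: %s: %s", product_id, requirement_id, note)
    return CheckResult(requirement_id=requirement_id, applicable=True, passed=None, note=note, **kw)


def _max_check(requirement_id: str, observed: float, threshold: float, unit: str) -> CheckResult:
    return CheckResult(
        requirement_id=requirement_id,
        applicable=True,
        passed=observed <= threshold,
        observed=observed,
        unit=unit,
        threshold=threshold,
        deviation_pct=raw_deviation_pct(observed, threshold) if threshold > 0 else None,
    )


def _min_check(requirement_id: str, observed: float, threshold: float, unit: str) -> CheckResult:
    return CheckResult(
        requirement_id=requirement_id,
        applicable=True,
        passed=observed >= threshold,
        observed=observed,
        unit=unit,
        threshold=threshold,
        deviation_pct=raw_deviation_pct(observed, threshold) if threshold > 0 else None,
    )


def _energy_density(product: ProductRecord, sub: SubcategoryRules) -> CheckResult:
    if sub.energy_max_kcal_per_serve is not None:
        if product.serve_size_g is None:
            return _insufficient(
                "energy_density",
                product.product_id,
                "serve size missing; cannot evaluate kcal per serve",
                threshold=sub.energy_max_kcal_per_serve,
                unit="kcal/serve",
            )
        observed = energy_per_serve(product.energy_kcal_per_100g, product.serve_size_g)
        return _max_check("energy_density", observed, sub.energy_max_kcal_per_serve, "kcal/serve")
    if sub.energy_density_min_kcal_per_100g is not None:
        return _min_check(
            "energy_density",
            product.energy_kcal_per_100g,
            sub.energy_density_min_kcal_per_100g,
            "kcal/100g",
        )
    return _na("energy_density")


def _sodium(product: ProductRecord, sub: SubcategoryRules) -> CheckResult:
    limit = (
        sub.sodium_max_mg_per_100kcal_cheese if product.cheese_named else sub.sodium_max_mg_per_100kcal
    )
    if limit is None:
        return _na("sodium")
    if product.energy_kcal_per_100g <= 0:
        return _insufficient(
            "sodium", product.product_id, "energy is zero; mg/100kcal undefined",
            threshold=limit, unit="mg/100kcal",
        )
    observed = sodium_per_100kcal(product.sodium_mg_per_100g, product.energy_kcal_per_100g)
    result = _max_check("sodium", observed, limit, "mg/100kcal")
    if product.cheese_named:
        result.note = "cheese named: higher sodium limit applies"
    return result


def _total_sugar(product: ProductRecord, sub: SubcategoryRules, factor: float) -> CheckResult:
    if sub.sugar_max_pct_energy is None:
        return _na("total_sugar")
    if product.energy_kcal_per_100g <= 0:
        return _insufficient(
            "total_sugar", product.product_id, "energy is zero; % energy from sugar undefined",
            threshold=sub.sugar_max_pct_energy, unit="% energy",
        )
    observed = pct_energy_from_sugar(
        product.total_sugar_g_per_100g, product.energy_kcal_per_100g, factor
    )
    return _max_check("total_sugar", observed, sub.sugar_max_pct_energy, "% energy")


def _fruit_content(product: ProductRecord, sub: SubcategoryRules) -> CheckResult:
    if sub.fruit_required_pct is None and not sub.fruit_declaration_required:
        return _na("fruit_content")
    if sub.fruit_required_pct is not None:
        if product.fruit_pct is None:
            return _insufficient(
                "fruit_content", product.product_id, "fruit content not reported",
                threshold=sub.fruit_required_pct, unit="% weight",
            )
        return _min_check("fruit_content", product.fruit_pct, sub.fruit_required_pct, "% weight")
    # declaration-only rule: a product containing added fruit must declare the amount
    contains_fruit = product.fruit_pct is not None and product.fruit_pct > 0
    if contains_fruit and not product.fruit_amount_declared:
        return CheckResult(
            requirement_id="fruit_content",
            applicable=True,
            passed=False,
            observed=product.fruit_pct,
            unit="% weight",
            note="contains added fruit but amount not declared",
        )
    return CheckResult(
        requirement_id="fruit_content",
        applicable=True,
        passed=True,
        observed=product.fruit_pct,
        unit="% weight",
    )


def _added_water(product: ProductRecord, sub: SubcategoryRules) -> CheckResult:
    if sub.added_water_max_pct is None:
        return _na("added_water")
    if product.added_water_pct is None:
        return _insufficient(
            "added_water", product.product_id, "added water content not reported",
            threshold=sub.added_water_max_pct, unit="% weight",
        )
    return _max_check("added_water", product.added_water_pct, sub.added_water_max_pct, "% weight")


def _high_sugar_flag(product: ProductRecord, sub: SubcategoryRules, factor: float) -> CheckResult:
    if sub.sugar_flag_threshold_pct_energy is None:
        return _na("high_sugar_flag")
    if product.energy_kcal_per_100g <= 0:
        return _insufficient(
            "high_sugar_flag", product.product_id, "energy is zero; % energy from sugar undefined",
            threshold=sub.sugar_flag_threshold_pct_energy, unit="% energy",
        )
    observed = pct_energy_from_sugar(
        product.total_sugar_g_per_100g, product.energy_kcal_per_100g, factor
    )
    required = observed > sub.sugar_flag_threshold_pct_energy
    return CheckResult(
        requirement_id="high_sugar_flag",
        applicable=True,
        passed=None,  # informational: records flag need, not product compliance
        observed=observed,
        unit="% energy",
        threshold=sub.sugar_flag_threshold_pct_energy,
        flag_required=required,
        note="high-in-sugar flag required" if required else "high-in-sugar flag not required",
    )


def evaluate_part_a(product: ProductRecord, rules: RuleSet) -> list[CheckResult]:
    """Evaluate one product against all Part A requirements.

    Returns exactly one :class:`CheckResult` per id in
    :data:`PART_A_REQUIREMENTS`, in that order.  Applicability is driven solely
    by the ruleset; for a non-permitted category (confectionery) every nutrient
    check is not applicable and only ``category_permitted`` carries a (failing)
    verdict.
    """
    sub = rules.rules_for(product.subcategory)
    factor = rules.sugar_energy_factor_kcal_per_g

    results = [
        CheckResult(
            requirement_id="category_permitted",
            applicable=True,
            passed=sub.category_permitted,
            note="" if sub.category_permitted else "category not permitted for 6-36 months",
        )
    ]
    if not sub.category_permitted:
        for requirement_id in PART_A_REQUIREMENTS[1:]:
            results.append(_na(requirement_id, note="category not permitted"))
        return results

    results.append(_energy_density(product, sub))
    results.append(_sodium(product, sub))
    results.append(_total_sugar(product, sub, factor))

    if sub.added_sugar_prohibited:
        results.append(
            CheckResult(
                requirement_id="added_sugar",
                applicable=True,
                passed=not product.added_free_sugars_present,
            )
        )
    else:
        results.append(_na("added_sugar"))

    results.append(_fruit_content(product, sub))
    results.append(_added_water(product, sub))

    if sub.protein_min_g_per_100kcal is not None:
        if product.energy_kcal_per_100g <= 0:
            results.append(
                _insufficient(
                    "protein_content", product.product_id,
                    "energy is zero; g/100kcal undefined",
                    threshold=sub.protein_min_g_per_100kcal, unit="g/100kcal",
                )
            )
        else:
            observed = per_100kcal(product.protein_g_per_100g, product.energy_kcal_per_100g)
            results.append(
                _min_check("protein_content", observed, sub.protein_min_g_per_100kcal, "g/100kcal")
            )
    else:
        results.append(_na("protein_content"))

    if sub.protein_min_pct_weight is not None:
        results.append(
            _min_check(
                "protein_weight", product.protein_g_per_100g, sub.protein_min_pct_weight, "% weight"
            )
        )
    else:
        results.append(_na("protein_weight"))

    if sub.fat_max_g_per_100kcal is not None:
        if product.energy_kcal_per_100g <= 0:
            results.append(
                _insufficient(
                    "total_fat", product.product_id, "energy is zero; g/100kcal undefined",
                    threshold=sub.fat_max_g_per_100kcal, unit="g/100kcal",
                )
            )
        else:
            observed = per_100kcal(product.total_fat_g_per_100g, product.energy_kcal_per_100g)
            results.append(_max_check("total_fat", observed, sub.fat_max_g_per_100kcal, "g/100kcal"))
    else:
        results.append(_na("total_fat"))

    if sub.trans_fat_prohibited:
        results.append(
            CheckResult(
                requirement_id="trans_fat",
                applicable=True,
                passed=not product.industrial_trans_fat_present,
            )
        )
    else:
        results.append(_na("trans_fat"))

    results.append(_high_sugar_flag(product, sub, factor))
    return results


def meets_all_nutrient_requirements(results: list[CheckResult]) -> bool:
    """True iff every applicable, evaluable Part A check passed.

    The informational high-in-sugar flag is never counted.  Checks with a
    missing verdict (insufficient input) are excluded from the conjunction.
    """
    return all(
        r.passed
        for r in results
        if r.applicable and r.requirement_id != "high_sugar_flag" and r.passed is not None
    )
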