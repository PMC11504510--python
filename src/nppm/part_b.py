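"""Part B engine: labelling and promotional-message requirements.

The NPPM permits no compositional, nutritional, health or marketing claims on
foods for 6-36 months, requires clear product names and ingredient lists,
imposes extra duties on spouted pouches (suggest spoon/bowl feeding, instruct
against sucking from the spout, carry an upper-age label, no "on-the-go"
convenience claims), requires a statement on the importance of continued
breastfeeding up to 2 years or beyond, and disallows age labels below
6 months.
"""

from __future__ import annotations

import warnings

from .errors import VacuousResultWarning
from .model import ProductRecord
from .part_a import CheckResult
from .ruleset import RuleSet

#: fixed evaluation order; evaluate_part_b always returns one result per id
PART_B_REQUIREMENTS = [
    "no_claims",
    "name_clarity",
    "ingredient_clarity",
    "pouch_spoon_suggestion",
    "pouch_no_spout_instruction",
    "pouch_upper_age_label",
    "no_on_the_go_claim",
    "breastfeeding_statement",
    "age_min_label",
    "upper_age_label",
    "preparation_instructions",
]


def _check(requirement_id: str, passed: bool, note: str = "") -> CheckResult:
    return CheckResult(requirement_id=requirement_id, applicable=True, passed=passed, note=note)


def _na(requirement_id: str, note: str = "") -> CheckResult:
    return CheckResult(requirement_id=requirement_id, applicable=False, note=note)


def evaluate_part_b(product: ProductRecord, rules: RuleSet) -> list[CheckResult]:
    """Evaluate one product against all Part B requirements.

    Pouch-specific checks apply only to spouted pouches.  Verdicts never depend
    on the order of the claims list.  ``upper_age_label`` is the general
    requirement (any package should state an upper age); the pouch-specific
    duty is reported separately as ``pouch_upper_age_label``.
    """
    rules.rules_for(product.subcategory)  # unknown subcategory -> error
    label = product.label
    spouted_pouch = product.package_type == "pouch" and product.has_spout

    results = [
        _check(
            "no_claims",
            len(label.claims) == 0,
            "" if not label.claims else f"{len(label.claims)} claim(s) present",
        ),
        _check(
            "name_clarity",
            label.ingredients_descending_order,
            "" if label.ingredients_descending_order else "ingredients not in descending order",
        ),
        _check(
            "ingredient_clarity",
            label.ingredient_list_amounts_complete,
            ""
            if label.ingredient_list_amounts_complete
            else "amount of added water/fruit missing from ingredient list",
        ),
    ]

    if spouted_pouch:
        results.append(_check("pouch_spoon_suggestion", label.spoon_or_bowl_suggestion))
        results.append(
            _check(
                "pouch_no_spout_instruction",
                label.no_spout_consumption_instruction,
                ""
                if label.no_spout_consumption_instruction
                else "no explicit instruction against consuming from the spout",
            )
        )
        results.append(_check("pouch_upper_age_label", label.age_max_months is not None))
        results.append(
            _check(
                "no_on_the_go_claim",
                not label.on_the_go_claim_present,
                "" if not label.on_the_go_claim_present else "'on-the-go' convenience claim present",
            )
        )
    else:
        for requirement_id in (
            "pouch_spoon_suggestion",
            "pouch_no_spout_instruction",
            "pouch_upper_age_label",
            "no_on_the_go_claim",
        ):
            results.append(_na(requirement_id, note="not a spouted pouch"))

    results.append(
        _check(
            "breastfeeding_statement",
            label.breastfeeding_statement_present,
            ""
            if label.breastfeeding_statement_present
            else "no statement on the importance of continued breastfeeding",
        )
    )
    age_ok = label.age_min_months is None or label.age_min_months >= 6
    results.append(
        _check(
            "age_min_label",
            age_ok,
            "" if age_ok else f"labelled suitable from {label.age_min_months} months (< 6)",
        )
    )
    results.append(
        _check(
            "upper_age_label",
            label.age_max_months is not None,
            "" if label.age_max_months is not None else "no upper age limit on package",
        )
    )

    if product.requires_preparation:
        ok = label.preparation_instructions_present and label.preparation_instructions_suitable
        results.append(
            _check(
                "preparation_instructions",
                ok,
                "" if ok else "preparation instructions missing or unsuitable",
            )
        )
    else:
        results.append(_na("preparation_instructions", note="no preparation required"))

    return results


def meets_all_promotional_requirements(results: list[CheckResult]) -> bool:
    """Conjunction over the applicable, evaluable Part B checks.

    An empty applicable set is vacuously true but flagged with a warning.
    """
    applicable = [r for r in results if r.applicable and r.passed is not None]
    if not applicable:
        warnings.warn(
            "no applicable Part B checks; promotion compliance is vacuous",
            VacuousResultWarning,
            stacklevel=2,
        )
        return True
    return all(r.passed for r in applicable)
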