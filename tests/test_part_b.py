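"""Part B engine: claims, label clarity, pouch duties, age labelling."""

import pytest

from nppm import evaluate_part_b, meets_all_promotional_requirements
from nppm.errors import VacuousResultWarning
from nppm.model import Claim, LabelInfo, ProductRecord
from nppm.part_b import PART_B_REQUIREMENTS


def _product(**overrides):
    label = overrides.pop("label", None) or LabelInfo()
    base = dict(
        product_id="X",
        brand="B",
        subcategory="3.3",
        product_group="fruit and vegetable purees",
        package_type="jar",
        energy_kcal_per_100g=70.0,
        total_sugar_g_per_100g=5.0,
        sodium_mg_per_100g=10.0,
        protein_g_per_100g=1.0,
        total_fat_g_per_100g=0.5,
        label=label,
    )
    base.update(overrides)
    return ProductRecord(**base)


def _results(product, rules):
    return {r.requirement_id: r for r in evaluate_part_b(product, rules)}


def test_any_claim_fails_no_claims(rules):
    for category in ("compositional", "nutritional", "health", "marketing"):
        product = _product(label=LabelInfo(claims=[Claim(text="x", category=category)]))
        assert _results(product, rules)["no_claims"].passed is False


def test_claim_order_never_affects_verdicts(rules):
    claims = [
        Claim(text="organic", category="compositional"),
        Claim(text="no nasties", category="marketing"),
    ]
    forward = evaluate_part_b(_product(label=LabelInfo(claims=claims)), rules)
    backward = evaluate_part_b(_product(label=LabelInfo(claims=claims[::-1])), rules)
    assert [(r.requirement_id, r.passed) for r in forward] == [
        (r.requirement_id, r.passed) for r in backward
    ]


def test_spouted_pouch_spoon_ok_but_missing_no_spout_instruction(rules):
    product = _product(
        package_type="pouch",
        has_spout=True,
        label=LabelInfo(spoon_or_bowl_suggestion=True, no_spout_consumption_instruction=False),
    )
    results = _results(product, rules)
    assert results["pouch_spoon_suggestion"].passed is True
    assert results["pouch_no_spout_instruction"].passed is False


def test_pouch_checks_not_applicable_off_pouches(fixture_products, rules):
    pouch_reqs = [
        "pouch_spoon_suggestion",
        "pouch_no_spout_instruction",
        "pouch_upper_age_label",
        "no_on_the_go_claim",
    ]
    for product in fixture_products:
        results = _results(product, rules)
        spouted = product.package_type == "pouch" and product.has_spout
        for req in pouch_reqs:
            assert results[req].applicable == spouted


def test_age_label_below_6_months_fails(rules):
    assert _results(_product(label=LabelInfo(age_min_months=4)), rules)["age_min_label"].passed is False
    assert _results(_product(label=LabelInfo(age_min_months=6)), rules)["age_min_label"].passed is True
    assert _results(_product(), rules)["age_min_label"].passed is True


def test_preparation_check_applicability_and_suitability(rules):
    no_prep = _product(requires_preparation=False)
    assert _results(no_prep, rules)["preparation_instructions"].applicable is False
    suitable = _product(
        requires_preparation=True,
        label=LabelInfo(
            preparation_instructions_present=True, preparation_instructions_suitable=True
        ),
    )
    assert _results(suitable, rules)["preparation_instructions"].passed is True
    unsuitable = _product(
        requires_preparation=True,
        label=LabelInfo(
            preparation_instructions_present=True, preparation_instructions_suitable=False
        ),
    )
    assert _results(unsuitable, rules)["preparation_instructions"].passed is False


def test_fully_compliant_label_meets_all(rules):
    product = _product(
        label=LabelInfo(
            claims=[],
            ingredients_descending_order=True,
            ingredient_list_amounts_complete=True,
            age_min_months=6,
            age_max_months=36,
            breastfeeding_statement_present=True,
        )
    )
    assert meets_all_promotional_requirements(evaluate_part_b(product, rules))


def test_fixture_products_all_fail_promotion(fixture_assessments):
    assert all(not a.meets_all_promotion for a in fixture_assessments)
    # every product carries at least one claim-related failure
    for a in fixture_assessments:
        no_claims = next(r for r in a.part_b if r.requirement_id == "no_claims")
        assert no_claims.passed is False


def test_vacuous_conjunction_warns():
    from nppm.part_a import CheckResult

    empty = [CheckResult(requirement_id="no_claims", applicable=False)]
    with pytest.warns(VacuousResultWarning):
        assert meets_all_promotional_requirements(empty) is True


def test_fixed_cardinality_and_determinism(fixture_products, rules):
    for product in fixture_products:
        first = evaluate_part_b(product, rules)
        assert [r.requirement_id for r in first] == PART_B_REQUIREMENTS
        assert first == evaluate_part_b(product, rules)
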