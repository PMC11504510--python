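"""Part A engine: normalisations, deviations, verdicts, and invariants."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nppm import (
    deviation_pct,
    energy_per_serve,
    evaluate_part_a,
    meets_all_nutrient_requirements,
    pct_energy_from_sugar,
    sodium_per_100kcal,
)
from nppm.part_a import PART_A_REQUIREMENTS, CheckResult


# ---------------------------------------------------------------------------
# Normalisation formulas


@pytest.mark.parametrize(
    "sugar,energy,factor,expected",
    [
        (3.75, 100, 4.0, 15.0),
        (0, 80, 4.0, 0.0),
        (7.39, 100, 4.0, 29.56),  # ~97 % above a 15 % limit
    ],
)
def test_pct_energy_from_sugar(sugar, energy, factor, expected):
    assert pct_energy_from_sugar(sugar, energy, factor) == pytest.approx(expected)


@pytest.mark.parametrize(
    "sodium,energy,expected",
    [(50, 100, 50.0), (100, 200, 50.0), (69, 100, 69.0)],
)
def test_sodium_per_100kcal(sodium, energy, expected):
    assert sodium_per_100kcal(sodium, energy) == pytest.approx(expected)


def test_sodium_69_is_38_pct_above_base_limit():
    assert deviation_pct(sodium_per_100kcal(69, 100), 50) == 38


@pytest.mark.parametrize(
    "energy,serve,expected", [(250, 20, 50.0), (400, 10, 40.0), (500, 25, 125.0)]
)
def test_energy_per_serve(energy, serve, expected):
    assert energy_per_serve(energy, serve) == pytest.approx(expected)


@pytest.mark.parametrize("func", [pct_energy_from_sugar, sodium_per_100kcal])
def test_zero_energy_is_undefined(func):
    with pytest.raises(ValueError):
        func(10, 0)


# ---------------------------------------------------------------------------
# Deviation convention


@pytest.mark.parametrize(
    "observed,threshold,expected",
    [
        (42.8, 25, 71),  # added water 42.8 % against a 25 % limit
        (25, 25, 0),
        (13, 25, -48),
        (53.5, 50, 7),
        (5.22, 4.5, 16),
    ],
)
def test_deviation_pct(observed, threshold, expected):
    assert deviation_pct(observed, threshold) == expected


def test_deviation_requires_positive_threshold():
    with pytest.raises(ValueError):
        deviation_pct(10, 0)


# ---------------------------------------------------------------------------
# evaluate_part_a behaviour


def _results(product, rules):
    return {r.requirement_id: r for r in evaluate_part_a(product, rules)}


def test_water_violator_fails_with_71_pct_deviation(fixture_products, rules):
    veg = next(p for p in fixture_products if p.subcategory == "3.2")
    result = _results(veg, rules)["added_water"]
    assert result.passed is False
    assert result.deviation_pct_rounded == 71


def test_fruit_shortfall_fails(fixture_products, rules):
    product = next(p for p in fixture_products if p.fruit_pct == 99.5)
    result = _results(product, rules)["fruit_content"]
    assert result.passed is False


def test_undeclared_fruit_amount_fails(fixture_products, rules):
    product = next(
        p for p in fixture_products if p.fruit_pct and not p.fruit_amount_declared
    )
    assert _results(product, rules)["fruit_content"].passed is False


def test_trans_fat_passes_when_absent(fixture_products, rules):
    for product in fixture_products:
        result = _results(product, rules)["trans_fat"]
        if result.applicable:
            assert result.passed is True


def test_cheese_named_uses_higher_sodium_limit(fixture_products, rules):
    cheesy = next(p for p in fixture_products if p.cheese_named)
    result = _results(cheesy, rules)["sodium"]
    assert result.threshold == 100.0


def test_missing_serve_size_yields_missing_verdict(fixture_products, rules):
    snack = next(p for p in fixture_products if p.subcategory == "5.1")
    incomplete = snack.model_copy(update={"serve_size_g": None})
    result = _results(incomplete, rules)["energy_density"]
    assert result.applicable and result.passed is None
    assert "serve size" in result.note


def test_confectionery_nutrient_checks_not_applicable(fixture_products, rules):
    sweet = next(p for p in fixture_products if p.subcategory == "6.1")
    results = _results(sweet, rules)
    assert results["category_permitted"].passed is False
    for req, r in results.items():
        if req != "category_permitted":
            assert not r.applicable


def test_fixed_cardinality_and_determinism(fixture_products, rules):
    for product in fixture_products:
        first = evaluate_part_a(product, rules)
        second = evaluate_part_a(product, rules)
        assert [r.requirement_id for r in first] == PART_A_REQUIREMENTS
        assert first == second


def test_high_sugar_flag_is_informational(fixture_products, rules):
    puree = next(p for p in fixture_products if p.subcategory == "3.4")
    flag = _results(puree, rules)["high_sugar_flag"]
    assert flag.applicable and flag.passed is None
    assert flag.flag_required is True


def test_meets_all_ignores_flag_and_conjuncts_the_rest(fixture_products, rules):
    clean = next(p for p in fixture_products if p.product_id == "P05")
    assert meets_all_nutrient_requirements(evaluate_part_a(clean, rules))
    # engineered to fail only the energy-density minimum
    energy_only = clean.model_copy(update={"energy_kcal_per_100g": 59.0,
                                           "sodium_mg_per_100g": 17.7,
                                           "total_sugar_g_per_100g": 1.18,
                                           "total_fat_g_per_100g": 1.77,
                                           "protein_g_per_100g": 2.36})
    results = evaluate_part_a(energy_only, rules)
    failing = [r.requirement_id for r in results if r.applicable and r.passed is False]
    assert failing == ["energy_density"]
    assert not meets_all_nutrient_requirements(results)


def test_not_applicable_check_cannot_carry_verdict():
    with pytest.raises(ValueError):
        CheckResult(requirement_id="sodium", applicable=False, passed=True)


# ---------------------------------------------------------------------------
# Boundary semantics: inclusive limits as printed


def _base_product(fixture_products, subcategory):
    return next(p for p in fixture_products if p.subcategory == subcategory)


def test_sodium_boundary_inclusive(fixture_products, rules):
    base = _base_product(fixture_products, "4.3")
    at_limit = base.model_copy(
        update={"sodium_mg_per_100g": 0.5 * base.energy_kcal_per_100g}
    )
    assert _results(at_limit, rules)["sodium"].passed is True
    above = base.model_copy(
        update={"sodium_mg_per_100g": 0.5 * base.energy_kcal_per_100g * 1.001}
    )
    assert _results(above, rules)["sodium"].passed is False


def test_cheese_sodium_boundary_inclusive(fixture_products, rules):
    base = _base_product(fixture_products, "4.2")
    at_limit = base.model_copy(update={"sodium_mg_per_100g": base.energy_kcal_per_100g})
    assert _results(at_limit, rules)["sodium"].passed is True
    above = base.model_copy(
        update={"sodium_mg_per_100g": base.energy_kcal_per_100g * 1.001}
    )
    assert _results(above, rules)["sodium"].passed is False


def test_sugar_boundary_inclusive(fixture_products, rules):
    base = _base_product(fixture_products, "4.3")
    sugar_at_15pct = 15.0 * base.energy_kcal_per_100g / 400.0
    at_limit = base.model_copy(update={"total_sugar_g_per_100g": sugar_at_15pct})
    assert _results(at_limit, rules)["total_sugar"].passed is True
    above = base.model_copy(update={"total_sugar_g_per_100g": sugar_at_15pct * 1.001})
    assert _results(above, rules)["total_sugar"].passed is False


def test_snack_serve_boundary_inclusive(fixture_products, rules):
    base = _base_product(fixture_products, "5.1")
    at_limit = base.model_copy(
        update={"serve_size_g": 5000.0 / base.energy_kcal_per_100g}
    )
    assert _results(at_limit, rules)["energy_density"].passed is True
    above = base.model_copy(
        update={"serve_size_g": 5000.0 / base.energy_kcal_per_100g * 1.001}
    )
    assert _results(above, rules)["energy_density"].passed is False


def test_water_boundary_inclusive(fixture_products, rules):
    base = _base_product(fixture_products, "3.2")
    at_limit = base.model_copy(update={"added_water_pct": 25.0})
    assert _results(at_limit, rules)["added_water"].passed is True
    above = base.model_copy(update={"added_water_pct": 25.1})
    assert _results(above, rules)["added_water"].passed is False


# ---------------------------------------------------------------------------
# Property tests


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    sodium=st.floats(0.1, 500),
    energy=st.floats(10, 500),
    scale=st.floats(0.1, 10),
)
def test_sodium_normalisation_scaling_invariance(sodium, energy, scale):
    """Scaling sodium and energy together leaves mg/100 kcal unchanged."""
    assert sodium_per_100kcal(sodium * scale, energy * scale) == pytest.approx(
        sodium_per_100kcal(sodium, energy)
    )


@settings(deadline=None, max_examples=60, derandomize=True)
@given(sugar=st.floats(0, 50), extra=st.floats(0.01, 50))
def test_more_sugar_never_rescues_a_failing_sugar_check(rules, sugar, extra):
    from nppm.model import ProductRecord

    def verdict(s):
        product = ProductRecord(
            product_id="X",
            brand="B",
            subcategory="4.3",
            product_group="savoury meals",
            package_type="jar",
            energy_kcal_per_100g=80.0,
            total_sugar_g_per_100g=min(s, 100.0),
            sodium_mg_per_100g=10,
            protein_g_per_100g=3.0,
            total_fat_g_per_100g=1.0,
        )
        return {r.requirement_id: r for r in evaluate_part_a(product, rules)}[
            "total_sugar"
        ].passed

    if verdict(sugar) is False:
        assert verdict(sugar + extra) is False
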