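"""Synthetic product data.

Two generators:

* :func:`generate_fixture` — a deterministic 45-product stand-in for the
  unpublished Australian supermarket sample.  The real per-product data were
  never deposited, so the fixture is *engineered*: every product is specified
  explicitly so that assessing the set under the default ruleset reproduces
  every reported marginal exactly (compliance fractions per requirement,
  pouch structure, and the individual deviation extremes such as a vegetable
  puree at 42.8 % added water, +71 % over the 25 % limit).  It validates the
  engines and the reporter, not the real-world result.

* :func:`generate_random` — seeded random product sets with configurable
  per-requirement noncompliance probabilities, used for property testing
  (zero probabilities must yield 100 % compliance; rate p must be recovered
  empirically at large n).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .errors import GenerationError
from .model import Claim, LabelInfo, ProductRecord
from .ruleset import RuleSet, default_ruleset

# ---------------------------------------------------------------------------
# Fixture target marginals


@dataclass(frozen=True)
class FixtureSpec:
    """Target marginals (numerator, denominator) and structural counts."""

    n_products: int = 45
    n_pouches: int = 16
    pouches_by_group: dict[str, int] = field(
        default_factory=lambda: {
            "savoury meals": 8,
            "fruit and vegetable purees": 4,
            "dairy foods": 4,
        }
    )
    #: requirement id -> (products passing, products subject)
    marginals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "category_permitted": (40, 45),
            "energy_density": (21, 40),
            "sodium": (38, 40),
            "total_sugar": (13, 23),
            "added_sugar": (34, 40),
            "fruit_content": (28, 30),
            "added_water": (0, 1),
            "protein_content": (15, 19),
            "protein_weight": (6, 10),
            "total_fat": (39, 40),
            "trans_fat": (40, 40),
            "no_claims": (0, 45),
            "name_clarity": (18, 45),
            "ingredient_clarity": (29, 45),
            "pouch_spoon_suggestion": (16, 16),
            "pouch_no_spout_instruction": (3, 16),
            "pouch_upper_age_label": (0, 16),
            "no_on_the_go_claim": (12, 16),
            "breastfeeding_statement": (0, 45),
            "age_min_label": (42, 45),
            "upper_age_label": (0, 45),
            "preparation_instructions": (5, 5),
        }
    )
    all_nutrient: tuple[int, int] = (9, 40)
    all_promotion: tuple[int, int] = (0, 45)
    high_sugar_flag_required: tuple[int, int] = (9, 17)

    def check_consistency(self) -> None:
        """Structural sanity of the targets themselves; raises GenerationError."""
        problems = []
        for req, (num, den) in self.marginals.items():
            if not 0 <= num <= den:
                problems.append(f"{req}: numerator {num} outside [0, {den}]")
            if den > self.n_products:
                problems.append(f"{req}: denominator {den} exceeds n={self.n_products}")
        if sum(self.pouches_by_group.values()) != self.n_pouches:
            problems.append("pouch counts per group do not sum to the pouch total")
        for name, (num, den) in (
            ("all_nutrient", self.all_nutrient),
            ("all_promotion", self.all_promotion),
            ("high_sugar_flag_required", self.high_sugar_flag_required),
        ):
            if not 0 <= num <= den <= self.n_products:
                problems.append(f"{name}: {num}/{den} inconsistent with n={self.n_products}")
        sugar_den = self.marginals["total_sugar"][1]
        flag_den = self.high_sugar_flag_required[1]
        if sugar_den + flag_den != self.marginals["sodium"][1]:
            problems.append(
                "sugar-limit and flag denominators must partition the nutrient-subject products"
            )
        if problems:
            raise GenerationError("inconsistent fixture spec: " + "; ".join(problems))


def fixture_spec() -> FixtureSpec:
    return FixtureSpec()


# ---------------------------------------------------------------------------
# The engineered 45-product table
#
# Compact per-product specs; nutrient columns are given on the scale the rules
# use (sugar as % energy, sodium/protein/fat per 100 kcal) and converted to
# per-100 g amounts at build time, so each product's intended verdict and
# deviation are explicit.  g1=1, g2=5, g3=17, g4=14, g5=3, confectionery=5.

_POUCH = {"pkg": "pouch", "spout": True, "spoon": True}

_FIXTURE_ROWS: list[dict[str, Any]] = [
    # -- dry cereals and starches (1 product) ------------------------------
    # fails energy density (-5 %) and the sugar limit (+90 %)
    dict(id="P01", sub="1.1", brand="Little Acre", name="Baby Rice Cereal",
         pkg="single-serve packet/sachet", serve=25, energy=285.0, share=28.5,
         na100=20, prot_g=8.0, fat100=3.0, prep=True),
    # -- dairy foods (5: three pouch desserts fail added sugar; 2.2 clean) --
    dict(id="P02", sub="2.1", brand="Mellow", name="Vanilla Custard Dessert",
         **_POUCH, serve=100, energy=54.0, share=19.95, na100=30, prot_k=4.0,
         fat100=3.0, added_sugar=True, otg=True),
    dict(id="P03", sub="2.1", brand="Mellow", name="Chocolate Rice Pudding",
         **_POUCH, serve=100, energy=48.0, share=18.75, na100=30, prot_k=4.0,
         fat100=3.0, added_sugar=True),
    dict(id="P04", sub="2.1", brand="Cherub", name="Berry Breakfast Cereal Dessert",
         **_POUCH, serve=100, energy=75.0, share=17.4, na100=30, prot_k=4.0,
         fat100=3.0, added_sugar=True),
    dict(id="P05", sub="2.2", brand="Cherub", name="Natural Yoghurt Pouch",
         **_POUCH, serve=100, energy=90.0, share=8.0, na100=30, prot_k=4.0,
         fat100=3.0),
    dict(id="P06", sub="2.2", brand="Dewdrop", name="Cheesy Breakfast Cup",
         pkg="multi-serve box/packet", serve=100, energy=85.0, share=9.0,
         na100=30, prot_k=4.0, fat100=3.0, prep=True),
    # -- fruit and vegetable purees (17) -----------------------------------
    dict(id="P07", sub="3.1", brand="Orchard Lane", name="Apple Puree",
         pkg="jar", serve=90, energy=70.0, share=30.0, na100=10, prot_g=0.5,
         fat100=0.5, fruit=100.0, fruit_decl=True),
    dict(id="P08", sub="3.1", brand="Orchard Lane", name="Pear Puree",
         pkg="jar", serve=90, energy=72.0, share=35.0, na100=10, prot_g=0.5,
         fat100=0.5, fruit=100.0, fruit_decl=True),
    dict(id="P09", sub="3.1", brand="Pip & Pod", name="Mango Banana Puree",
         pkg="jar", serve=90, energy=51.0, share=65.0, na100=10, prot_g=0.5,
         fat100=0.5, fruit=100.0, fruit_decl=True),
    dict(id="P10", sub="3.1", brand="Pip & Pod", name="Peach Puree",
         pkg="jar", serve=90, energy=45.0, share=45.0, na100=10, prot_g=0.5,
         fat100=0.5, fruit=100.0, fruit_decl=True),
    # 99.5 % fruit against the 100 % requirement
    dict(id="P11", sub="3.1", brand="Quince", name="Summer Fruits Puree",
         pkg="jar", serve=90, energy=70.0, share=60.0, na100=10, prot_g=0.5,
         fat100=0.5, fruit=99.5, fruit_decl=True),
    # 42.8 % added water against the 25 % limit (+71 %)
    dict(id="P12", sub="3.2", brand="Greenling", name="Garden Veggie Puree",
         pkg="jar", serve=90, energy=55.0, share=10.0, na100=15, prot_g=1.0,
         fat100=0.8, water=42.8, water_decl=False),
    dict(id="P13", sub="3.3", brand="Sprout", name="Apple Spinach Blend",
         **_POUCH, serve=120, energy=59.94, share=50.0, na100=12, prot_g=0.8,
         fat100=0.6, fruit=60.0, fruit_decl=True, nospout=True),
    dict(id="P14", sub="3.3", brand="Sprout", name="Pumpkin Apple Mash",
         **_POUCH, serve=120, energy=31.2, share=55.0, na100=12, prot_g=0.8,
         fat100=0.6, fruit=55.0, fruit_decl=True, nospout=True),
    dict(id="P15", sub="3.3", brand="Greenling", name="Beet Berry Blend",
         **_POUCH, serve=120, energy=42.0, share=48.0, na100=12, prot_g=0.8,
         fat100=0.6, fruit=50.0, fruit_decl=True, otg=True, age_min=4),
    dict(id="P16", sub="3.3", brand="Greenling", name="Carrot Apple Swirl",
         **_POUCH, serve=120, energy=52.8, share=25.0, na100=12, prot_g=0.8,
         fat100=0.6, fruit=45.0, fruit_decl=True),
    dict(id="P17", sub="3.3", brand="Harvest Tots", name="Sweetcorn Pear Mix",
         pkg="jar", serve=90, energy=75.0, share=20.0, na100=12, prot_g=0.8,
         fat100=0.6, fruit=50.0, fruit_decl=True),
    dict(id="P18", sub="3.4", brand="Aurora Farms", name="Fruity Breakfast Bircher",
         pkg="single-serve packet/sachet", serve=100, energy=70.0, share=52.0,
         na100=15, prot_g=1.5, fat100=1.0, fruit=30.0, fruit_decl=True,
         added_sugar=True),
    dict(id="P19", sub="3.4", brand="Aurora Farms", name="Apple Oat Smoothie Mix",
         pkg="single-serve packet/sachet", serve=100, energy=68.0, share=58.0,
         na100=15, prot_g=1.5, fat100=1.0, fruit=25.0, fruit_decl=True,
         added_sugar=True),
    dict(id="P20", sub="3.4", brand="Bubba Bites", name="Tropical Fruit Yoghurt Blend",
         pkg="single-serve packet/sachet", serve=100, energy=72.0, share=62.0,
         na100=15, prot_g=1.5, fat100=1.0, fruit=35.0, fruit_decl=True,
         added_sugar=True),
    dict(id="P21", sub="3.5", brand="Evergreen", name="Green Smoothie Blend",
         pkg="single-serve packet/sachet", serve=100, energy=39.0, share=38.0,
         na100=12, prot_g=0.8, fat100=0.6, fruit=40.0, fruit_decl=True),
    dict(id="P22", sub="3.5", brand="Evergreen", name="Berry Veggie Smoothie",
         pkg="single-serve packet/sachet", serve=100, energy=36.0, share=32.0,
         na100=12, prot_g=0.8, fat100=0.6, fruit=45.0, fruit_decl=True),
    dict(id="P23", sub="3.5", brand="First Spoon", name="Orchard Veggie Smoothie",
         pkg="single-serve packet/sachet", serve=100, energy=80.0, share=15.0,
         na100=12, prot_g=0.8, fat100=0.6, fruit=55.0, fruit_decl=True),
    # -- savoury meals (14) -------------------------------------------------
    # sugar violations spanning +16 % .. +97 % live in the spouted pouches
    dict(id="P24", sub="4.1", brand="Tiny Table", name="Chicken & Veggie Dinner",
         **_POUCH, serve=120, energy=58.8, share=29.55, na100=35, prot_w=3.48,
         fat100=2.5, protein_named=True, otg=True, age_min=4),
    dict(id="P25", sub="4.1", brand="Tiny Table", name="Beef Casserole",
         **_POUCH, serve=120, energy=49.2, share=27.0, na100=35, prot_w=5.0,
         fat100=2.5, protein_named=True),
    dict(id="P26", sub="4.1", brand="Tiny Table", name="Lamb & Pumpkin Mash",
         **_POUCH, serve=120, energy=46.8, share=25.5, na100=35, prot_w=5.0,
         fat100=2.5, protein_named=True),
    dict(id="P27", sub="4.1", brand="Nestling", name="Salmon & Sweet Potato",
         **_POUCH, serve=120, energy=85.0, share=10.0, na100=35, prot_w=2.8,
         fat100=2.5, protein_named=True, nospout=True),
    dict(id="P28", sub="4.1", brand="Nestling", name="Turkey Risotto Bowl",
         pkg="bowl", serve=110, energy=80.0, share=8.0, na100=25, prot_w=5.0,
         fat100=2.5, protein_named=True),
    # cheese named: the 100 mg/100 kcal sodium limit applies
    dict(id="P29", sub="4.2", brand="Rosella", name="Cheesy Veggie Bake",
         **_POUCH, serve=120, energy=43.2, share=24.0, na100=80, prot_w=1.4,
         fat100=2.5, cheese=True, fruit=10.0, fruit_decl=False),
    dict(id="P30", sub="4.2", brand="Rosella", name="Mac & Cheese",
         **_POUCH, serve=120, energy=40.2, share=22.5, na100=60, prot_w=5.0,
         fat100=2.5, cheese=True, otg=True, age_min=4),
    dict(id="P31", sub="4.2", brand="Rosella", name="Cheesy Tomato Pasta",
         **_POUCH, serve=120, energy=37.2, share=21.0, na100=60, prot_w=5.0,
         fat100=2.5, cheese=True),
    dict(id="P32", sub="4.2", brand="Willow", name="Cauliflower Cheese Mash",
         **_POUCH, serve=120, energy=62.0, share=12.0, na100=60, prot_w=2.0,
         fat100=2.5, cheese=True),
    dict(id="P33", sub="4.2", brand="Willow", name="Cheese & Broccoli Bowl",
         pkg="bowl", serve=110, energy=82.0, share=9.0, na100=70, prot_w=4.5,
         fat100=2.5, cheese=True),
    # sodium violator: 69 mg/100 kcal against the 50 mg base limit (+38 %)
    dict(id="P34", sub="4.3", brand="Nestling", name="Garden Vegetable Medley",
         pkg="jar", serve=110, energy=33.0, share=10.0, na100=69, prot_k=2.49,
         fat100=2.5),
    dict(id="P35", sub="4.3", brand="Nestling", name="Country Veggie Dinner",
         pkg="jar", serve=110, energy=65.0, share=9.0, na100=30, prot_k=2.25,
         fat100=2.5, prep=True),
    dict(id="P36", sub="4.3", brand="Tiny Table", name="Harvest Vegetable Bowl",
         pkg="bowl", serve=110, energy=70.0, share=9.0, na100=30, prot_k=2.04,
         fat100=2.5, prep=True),
    dict(id="P37", sub="4.3", brand="Tiny Table", name="Root Veggie Mash",
         pkg="bowl", serve=110, energy=72.0, share=8.0, na100=30, prot_k=1.83,
         fat100=2.5),
    # -- snacks and finger foods (3) ----------------------------------------
    # sodium +7 % and fat +16 % violators; all snacks meet <=50 kcal/serve
    dict(id="P38", sub="5.1", brand="Bubba Bites", name="Veggie Puff Snacks",
         pkg="multi-serve box/packet", serve=10, energy=400.0, share=5.0,
         na100=53.5, prot_g=7.0, fat100=3.0),
    dict(id="P39", sub="5.1", brand="First Spoon", name="Baby Rice Crackers",
         pkg="multi-serve box/packet", serve=11, energy=420.0, share=6.0,
         na100=30, prot_g=7.0, fat100=5.22),
    dict(id="P40", sub="5.2", brand="Evergreen", name="Freeze-Dried Fruit Bites",
         pkg="multi-serve box/packet", serve=12, energy=350.0, share=10.0,
         na100=20, prot_g=3.0, fat100=2.0, prep=True),
    # -- confectionery (5; category not permitted) --------------------------
    dict(id="P41", sub="6.1", brand="Choco Kid", name="Milk Chocolate Buttons",
         pkg="multi-serve box/packet", serve=20, energy=380.0, sugar_g=60.0,
         sodium_mg=20.0, prot_g=2.0, fat_g=5.0),
    dict(id="P42", sub="6.1", brand="Choco Kid", name="White Choc Animals",
         pkg="multi-serve box/packet", serve=20, energy=380.0, sugar_g=60.0,
         sodium_mg=20.0, prot_g=2.0, fat_g=5.0),
    dict(id="P43", sub="6.1", brand="Choco Kid", name="Fruity Jelly Drops",
         pkg="multi-serve box/packet", serve=20, energy=330.0, sugar_g=70.0,
         sodium_mg=15.0, prot_g=1.0, fat_g=0.5),
    dict(id="P44", sub="6.1", brand="Sweetling", name="Yoghurt Drops",
         pkg="multi-serve box/packet", serve=20, energy=390.0, sugar_g=55.0,
         sodium_mg=25.0, prot_g=3.0, fat_g=8.0),
    dict(id="P45", sub="6.1", brand="Sweetling", name="Honey Teddies",
         pkg="multi-serve box/packet", serve=20, energy=370.0, sugar_g=50.0,
         sodium_mg=20.0, prot_g=4.0, fat_g=6.0),
]

#: products whose ingredient list is not in descending order (27 of 45)
_NAME_CLARITY_FAILS = {
    "P01", "P02", "P03", "P04", "P09", "P10", "P11", "P12", "P13", "P14",
    "P15", "P16", "P18", "P19", "P20", "P21", "P22", "P24", "P25", "P26",
    "P29", "P30", "P31", "P34", "P38", "P39", "P41",
}

#: products missing added-water/fruit amounts from the ingredient list (16 of 45)
_INGREDIENT_CLARITY_FAILS = {
    "P02", "P03", "P04", "P12", "P13", "P14", "P15", "P18", "P19", "P24",
    "P25", "P29", "P30", "P34", "P41", "P42",
}

_BASE_CLAIM = Claim(text="No nasties", category="marketing")


def _build_product(row: dict[str, Any], rules: RuleSet) -> ProductRecord:
    energy = row["energy"]
    factor = rules.sugar_energy_factor_kcal_per_g
    if "share" in row:
        sugar_g = row["share"] * energy / (100.0 * factor)
    else:
        sugar_g = row["sugar_g"]
    sodium_mg = row["na100"] * energy / 100.0 if "na100" in row else row["sodium_mg"]
    if "prot_w" in row:
        protein_g = row["prot_w"]
    elif "prot_k" in row:
        protein_g = row["prot_k"] * energy / 100.0
    else:
        protein_g = row["prot_g"]
    fat_g = row["fat100"] * energy / 100.0 if "fat100" in row else row["fat_g"]

    claims = [_BASE_CLAIM]
    if row.get("protein_named"):
        claims.append(Claim(text="Source of protein", category="nutritional"))
    if row["sub"].startswith("3."):
        claims.append(Claim(text="Organic", category="compositional"))

    label = LabelInfo(
        claims=claims,
        ingredients_descending_order=row["id"] not in _NAME_CLARITY_FAILS,
        ingredient_list_amounts_complete=row["id"] not in _INGREDIENT_CLARITY_FAILS,
        age_min_months=row.get("age_min", 6),
        age_max_months=None,
        breastfeeding_statement_present=False,
        spoon_or_bowl_suggestion=row.get("spoon", False),
        no_spout_consumption_instruction=row.get("nospout", False),
        on_the_go_claim_present=row.get("otg", False),
        preparation_instructions_present=row.get("prep", False),
        preparation_instructions_suitable=row.get("prep", False),
    )
    return ProductRecord(
        product_id=row["id"],
        brand=row["brand"],
        name_text=row["name"],
        subcategory=row["sub"],
        product_group=rules.rules_for(row["sub"]).group,
        package_type=row["pkg"],
        has_spout=row.get("spout", False),
        serve_size_g=row["serve"],
        energy_kcal_per_100g=energy,
        total_sugar_g_per_100g=sugar_g,
        sodium_mg_per_100g=sodium_mg,
        protein_g_per_100g=protein_g,
        total_fat_g_per_100g=fat_g,
        industrial_trans_fat_present=False,
        added_free_sugars_present=row.get("added_sugar", False),
        fruit_pct=row.get("fruit"),
        added_water_pct=row.get("water"),
        fruit_amount_declared=row.get("fruit_decl", False),
        water_amount_declared=row.get("water_decl", False),
        cheese_named=row.get("cheese", False),
        protein_named=row.get("protein_named", False),
        requires_preparation=row.get("prep", False),
        label=label,
    )


def _verify_fixture(products: list[ProductRecord], rules: RuleSet, spec: FixtureSpec) -> None:
    from .pipeline import assess, summarize

    report = summarize(assess(products, rules))
    problems = []
    for req, (num, den) in spec.marginals.items():
        row = report.requirements[req]
        if (row.numerator, row.denominator) != (num, den):
            problems.append(
                f"{req}: expected {num}/{den}, got {row.numerator}/{row.denominator}"
            )
    for name, expected, actual in (
        ("all_nutrient", spec.all_nutrient, report.all_nutrient),
        ("all_promotion", spec.all_promotion, report.all_promotion),
        (
            "high_sugar_flag_required",
            spec.high_sugar_flag_required,
            report.high_sugar_flag_required,
        ),
    ):
        if (actual.numerator, actual.denominator) != expected:
            problems.append(
                f"{name}: expected {expected[0]}/{expected[1]}, "
                f"got {actual.numerator}/{actual.denominator}"
            )
    pouches = [p for p in products if p.package_type == "pouch"]
    if len(pouches) != spec.n_pouches:
        problems.append(f"pouches: expected {spec.n_pouches}, got {len(pouches)}")
    by_group: dict[str, int] = {}
    for p in pouches:
        by_group[p.product_group] = by_group.get(p.product_group, 0) + 1
    if by_group != spec.pouches_by_group:
        problems.append(f"pouch allocation by group: expected {spec.pouches_by_group}, got {by_group}")
    if problems:
        raise GenerationError(
            "fixture does not reproduce its target marginals under the supplied ruleset: "
            + "; ".join(problems)
        )


def generate_fixture(rules: RuleSet | None = None, spec: FixtureSpec | None = None) -> list[ProductRecord]:
    """Build the deterministic 45-product fixture.

    The build is verified at generation time: the products are assessed under
    ``rules`` and every target marginal in ``spec`` must be reproduced exactly,
    otherwise a :class:`GenerationError` names the conflicting constraints
    (e.g. when called with a ruleset whose thresholds differ from the ones the
    table was engineered against).
    """
    rules = rules or default_ruleset()
    spec = spec or fixture_spec()
    spec.check_consistency()
    products = [_build_product(row, rules) for row in _FIXTURE_ROWS]
    _verify_fixture(products, rules, spec)
    return products


def fixture_provenance() -> dict[str, str]:
    """Human-readable note for each engineered constraint in the fixture."""
    spec = fixture_spec()
    notes = {
        req: f"reported marginal: {num} of {den} products met this requirement"
        for req, (num, den) in spec.marginals.items()
    }
    notes["high_sugar_flag_required"] = (
        "reported marginal: 9 of 17 evaluable products would need a high-in-sugar flag"
    )
    notes["all_nutrient"] = "reported marginal: 9 of 40 products met all nutrient requirements"
    notes["all_promotion"] = "reported marginal: no product met all promotion requirements"
    notes["pouches"] = "16 pouches: 8 savoury meals, 4 fruit/vegetable purees, 4 dairy foods"
    notes["deviation_extremes"] = (
        "engineered extremes: added water 42.8 % (+71 %); fruit 99.5 % vs 100 %; "
        "sodium +38 % and +7 %; sugar +16 %..+97 %; fat +16 %; energy -0.1 %..-48 %"
    )
    return notes


# ---------------------------------------------------------------------------
# Randomised generator

#: requirement ids the random generator can perturb
PERTURBABLE = [
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

_PACKAGE_TYPES = [
    "pouch",
    "jar",
    "bowl",
    "single-serve packet/sachet",
    "multi-serve box/packet",
]


class GeneratorConfig(BaseModel):
    """Configuration for the randomised product generator."""

    model_config = ConfigDict(extra="forbid")

    n_products: int = Field(ge=0)
    seed: int = 0
    #: requirement id -> probability of injecting a violation of it
    noncompliance: dict[str, float] = Field(default_factory=dict)
    #: subcategory pool (defaults to every permitted code in the ruleset)
    subcategories: Optional[list[str]] = None

    @field_validator("noncompliance")
    @classmethod
    def _valid_probs(cls, value: dict[str, float]) -> dict[str, float]:
        for key, p in value.items():
            if key not in PERTURBABLE:
                raise ValueError(f"unknown requirement id {key!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {key!r} outside [0, 1]")
        return value


def generate_random(config: GeneratorConfig, rules: RuleSet | None = None) -> list[ProductRecord]:
    """Draw seeded random products with configurable noncompliance rates.

    Baseline draws are compliant on every applicable requirement; for each
    requirement with probability p a violation is injected independently.
    Injections are requirement-local except where composition couples them
    (a protein-content violation in a subcategory that also has a % weight
    minimum necessarily drags the weight check down with it).
    """
    rules = rules or default_ruleset()
    rng = np.random.default_rng(config.seed)
    pool = config.subcategories or [
        code for code, sub in rules.subcategories.items() if sub.category_permitted
    ]
    for code in pool:
        rules.rules_for(code)  # unknown code -> RulesetError

    products = []
    for i in range(config.n_products):
        code = pool[rng.integers(len(pool))]
        sub = rules.rules_for(code)
        pkg = _PACKAGE_TYPES[rng.integers(len(_PACKAGE_TYPES))]
        spouted = pkg == "pouch"
        cheese = "cheese" in sub.name.lower()
        protein_named = "protein named" in sub.name.lower() and "without" not in sub.name.lower()

        def hit(req: str, applicable: bool = True) -> bool:
            p = config.noncompliance.get(req, 0.0)
            return applicable and p > 0 and rng.random() < p

        # --- energy and serve size
        if sub.energy_max_kcal_per_serve is not None:
            energy = float(rng.uniform(300, 450))
            cap = sub.energy_max_kcal_per_serve
            factor_serve = rng.uniform(1.05, 1.5) if hit("energy_density") else rng.uniform(0.4, 0.95)
            serve = float(cap * factor_serve * 100.0 / energy)
        elif sub.energy_density_min_kcal_per_100g is not None:
            low = sub.energy_density_min_kcal_per_100g
            if hit("energy_density"):
                energy = float(low * rng.uniform(0.5, 0.97))
            else:
                energy = float(low * rng.uniform(1.05, 1.5))
            serve = float(rng.uniform(80, 130))
        else:
            energy = float(rng.uniform(60, 120))
            serve = float(rng.uniform(80, 130))

        # --- sodium (mg per 100 kcal)
        limit_na = (
            sub.sodium_max_mg_per_100kcal_cheese if cheese else sub.sodium_max_mg_per_100kcal
        )
        if limit_na is None:
            na100 = float(rng.uniform(5, 45))
        elif hit("sodium"):
            na100 = float(limit_na * rng.uniform(1.05, 1.6))
        else:
            na100 = float(limit_na * rng.uniform(0.1, 0.9))

        # --- sugar (% energy)
        if sub.sugar_max_pct_energy is not None:
            if hit("total_sugar"):
                share = float(sub.sugar_max_pct_energy * rng.uniform(1.05, 1.8))
            else:
                share = float(sub.sugar_max_pct_energy * rng.uniform(0.1, 0.9))
        else:
            share = float(rng.uniform(5, 38))
        sugar_g = min(share * energy / (100.0 * rules.sugar_energy_factor_kcal_per_g), 100.0)

        # --- protein
        if sub.protein_min_pct_weight is not None:
            wmin = sub.protein_min_pct_weight
            cmin = sub.protein_min_g_per_100kcal or 0.0
            if hit("protein_weight"):
                floor = cmin * energy / 100.0  # stay above the per-100kcal minimum
                high = wmin * 0.97
                protein_g = float(rng.uniform(min(floor * 1.02, high), high)) if high > floor else float(wmin * 0.5)
            elif hit("protein_content"):
                protein_g = float((cmin or 1.0) * rng.uniform(0.5, 0.95) * energy / 100.0)
            else:
                protein_g = float(wmin * rng.uniform(1.05, 2.0))
        elif sub.protein_min_g_per_100kcal is not None:
            cmin = sub.protein_min_g_per_100kcal
            factor_p = rng.uniform(0.5, 0.95) if hit("protein_content") else rng.uniform(1.1, 2.0)
            protein_g = float(cmin * factor_p * energy / 100.0)
        else:
            protein_g = float(rng.uniform(0.5, 8.0))

        # --- fat (g per 100 kcal)
        if sub.fat_max_g_per_100kcal is not None:
            factor_f = rng.uniform(1.05, 1.5) if hit("total_fat") else rng.uniform(0.2, 0.9)
            fat_g = float(sub.fat_max_g_per_100kcal * factor_f * energy / 100.0)
        else:
            fat_g = float(rng.uniform(0.5, 5.0))

        # --- fruit and water
        fruit = None
        fruit_decl = False
        if sub.fruit_required_pct is not None:
            if hit("fruit_content"):
                fruit = float(rng.uniform(80, 99.9))
            else:
                fruit = sub.fruit_required_pct
            fruit_decl = True
        elif sub.fruit_declaration_required:
            if hit("fruit_content"):
                fruit = float(rng.uniform(5, 60))
                fruit_decl = False
            elif rng.random() < 0.5:
                fruit = float(rng.uniform(5, 60))
                fruit_decl = True
        water = None
        water_decl = False
        if sub.added_water_max_pct is not None:
            if hit("added_water"):
                water = float(min(sub.added_water_max_pct * rng.uniform(1.05, 1.6), 100.0))
            else:
                water = float(sub.added_water_max_pct * rng.uniform(0.0, 0.9))
            water_decl = True

        trans = bool(hit("trans_fat", sub.trans_fat_prohibited))
        added_sugar = bool(hit("added_sugar", sub.added_sugar_prohibited))

        # --- label
        claims = [Claim(text="Yummy for little ones", category="marketing")] if hit("no_claims") else []
        age_max: Optional[int] = 36
        if hit("upper_age_label"):
            age_max = None
        if spouted and hit("pouch_upper_age_label"):
            age_max = None
        requires_prep = False
        prep_present = prep_suitable = False
        if hit("preparation_instructions"):
            requires_prep = True
            prep_present, prep_suitable = True, False
        elif rng.random() < 0.1:
            requires_prep = True
            prep_present = prep_suitable = True
        label = LabelInfo(
            claims=claims,
            ingredients_descending_order=not hit("name_clarity"),
            ingredient_list_amounts_complete=not hit("ingredient_clarity"),
            age_min_months=4 if hit("age_min_label") else 6,
            age_max_months=age_max,
            breastfeeding_statement_present=not hit("breastfeeding_statement"),
            spoon_or_bowl_suggestion=spouted and not hit("pouch_spoon_suggestion", spouted),
            no_spout_consumption_instruction=spouted
            and not hit("pouch_no_spout_instruction", spouted),
            on_the_go_claim_present=bool(hit("no_on_the_go_claim", spouted)),
            preparation_instructions_present=prep_present,
            preparation_instructions_suitable=prep_suitable,
        )
        products.append(
            ProductRecord(
                product_id=f"R{i:05d}",
                brand=f"Brand {int(rng.integers(20)):02d}",
                name_text=f"{sub.name} product {i}",
                subcategory=code,
                product_group=sub.group,
                package_type=pkg,
                has_spout=spouted,
                serve_size_g=serve,
                energy_kcal_per_100g=energy,
                total_sugar_g_per_100g=sugar_g,
                sodium_mg_per_100g=na100 * energy / 100.0,
                protein_g_per_100g=protein_g,
                total_fat_g_per_100g=fat_g,
                industrial_trans_fat_present=trans,
                added_free_sugars_present=added_sugar,
                fruit_pct=fruit,
                added_water_pct=water,
                fruit_amount_declared=fruit_decl,
                water_amount_declared=water_decl,
                cheese_named=cheese,
                protein_named=protein_named,
                requires_preparation=requires_prep,
                label=label,
            )
        )
    return products
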