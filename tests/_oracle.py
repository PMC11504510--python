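"""Brute-force reference evaluator, independent of the engine code paths.

Re-derives every verdict directly from product fields and ruleset thresholds
with inline arithmetic (no shared helpers), so agreement with the engines is a
meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

from nppm.model import ProductRecord
from nppm.ruleset import RuleSet

# verdict: True/False, None for not-applicable or not-evaluable
Verdict = bool | None


def oracle_part_a(p: ProductRecord, rules: RuleSet) -> dict[str, Verdict]:
    sub = rules.subcategories[p.subcategory]
    out: dict[str, Verdict] = {}
    out["category_permitted"] = sub.category_permitted
    if not sub.category_permitted:
        for req in [
            "energy_density", "sodium", "total_sugar", "added_sugar", "fruit_content",
            "added_water", "protein_content", "protein_weight", "total_fat", "trans_fat",
        ]:
            out[req] = None
        out["high_sugar_flag_required"] = None
        return out

    # energy
    if sub.energy_max_kcal_per_serve is not None:
        if p.serve_size_g is None:
            out["energy_density"] = None
        else:
            out["energy_density"] = (
                p.energy_kcal_per_100g * p.serve_size_g / 100.0 <= sub.energy_max_kcal_per_serve
            )
    elif sub.energy_density_min_kcal_per_100g is not None:
        out["energy_density"] = p.energy_kcal_per_100g >= sub.energy_density_min_kcal_per_100g
    else:
        out["energy_density"] = None

    # sodium
    lim = sub.sodium_max_mg_per_100kcal_cheese if p.cheese_named else sub.sodium_max_mg_per_100kcal
    if lim is None:
        out["sodium"] = None
    elif p.energy_kcal_per_100g <= 0:
        out["sodium"] = None
    else:
        out["sodium"] = p.sodium_mg_per_100g * 100.0 / p.energy_kcal_per_100g <= lim

    # sugar
    if sub.sugar_max_pct_energy is None or p.energy_kcal_per_100g <= 0:
        out["total_sugar"] = None if sub.sugar_max_pct_energy is None else None
    else:
        share = (
            p.total_sugar_g_per_100g
            * rules.sugar_energy_factor_kcal_per_g
            / p.energy_kcal_per_100g
            * 100.0
        )
        out["total_sugar"] = share <= sub.sugar_max_pct_energy

    out["added_sugar"] = (not p.added_free_sugars_present) if sub.added_sugar_prohibited else None

    # fruit
    if sub.fruit_required_pct is not None:
        out["fruit_content"] = None if p.fruit_pct is None else p.fruit_pct >= sub.fruit_required_pct
    elif sub.fruit_declaration_required:
        has_fruit = p.fruit_pct is not None and p.fruit_pct > 0
        out["fruit_content"] = (not has_fruit) or p.fruit_amount_declared
    else:
        out["fruit_content"] = None

    if sub.added_water_max_pct is None:
        out["added_water"] = None
    elif p.added_water_pct is None:
        out["added_water"] = None
    else:
        out["added_water"] = p.added_water_pct <= sub.added_water_max_pct

    if sub.protein_min_g_per_100kcal is None or p.energy_kcal_per_100g <= 0:
        out["protein_content"] = None
    else:
        out["protein_content"] = (
            p.protein_g_per_100g * 100.0 / p.energy_kcal_per_100g >= sub.protein_min_g_per_100kcal
        )
    out["protein_weight"] = (
        p.protein_g_per_100g >= sub.protein_min_pct_weight
        if sub.protein_min_pct_weight is not None
        else None
    )

    if sub.fat_max_g_per_100kcal is None or p.energy_kcal_per_100g <= 0:
        out["total_fat"] = None
    else:
        out["total_fat"] = (
            p.total_fat_g_per_100g * 100.0 / p.energy_kcal_per_100g <= sub.fat_max_g_per_100kcal
        )

    out["trans_fat"] = (not p.industrial_trans_fat_present) if sub.trans_fat_prohibited else None

    if sub.sugar_flag_threshold_pct_energy is None or p.energy_kcal_per_100g <= 0:
        out["high_sugar_flag_required"] = None
    else:
        share = (
            p.total_sugar_g_per_100g
            * rules.sugar_energy_factor_kcal_per_g
            / p.energy_kcal_per_100g
            * 100.0
        )
        out["high_sugar_flag_required"] = share > sub.sugar_flag_threshold_pct_energy
    return out


def oracle_part_b(p: ProductRecord) -> dict[str, Verdict]:
    lab = p.label
    out: dict[str, Verdict] = {}
    out["no_claims"] = len(lab.claims) == 0
    out["name_clarity"] = lab.ingredients_descending_order
    out["ingredient_clarity"] = lab.ingredient_list_amounts_complete
    spouted = p.package_type == "pouch" and p.has_spout
    out["pouch_spoon_suggestion"] = lab.spoon_or_bowl_suggestion if spouted else None
    out["pouch_no_spout_instruction"] = lab.no_spout_consumption_instruction if spouted else None
    out["pouch_upper_age_label"] = (lab.age_max_months is not None) if spouted else None
    out["no_on_the_go_claim"] = (not lab.on_the_go_claim_present) if spouted else None
    out["breastfeeding_statement"] = lab.breastfeeding_statement_present
    out["age_min_label"] = lab.age_min_months is None or lab.age_min_months >= 6
    out["upper_age_label"] = lab.age_max_months is not None
    out["preparation_instructions"] = (
        (lab.preparation_instructions_present and lab.preparation_instructions_suitable)
        if p.requires_preparation
        else None
    )
    return out


def oracle_deviation(observed: float, threshold: float) -> float:
    return (observed - threshold) / threshold * 100.0
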