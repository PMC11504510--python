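"""Product table I/O, validation, and claim tagging."""

import pytest

from nppm import (
    load_claim_lexicon,
    read_assessments,
    read_products,
    tag_claim,
    write_assessments,
    write_products,
)
from nppm.errors import ProductValidationError, SchemaError
from nppm.model import KJ_PER_KCAL

CSV_HEADER = (
    "product_id,brand,subcategory,product_group,package_type,"
    "energy_kcal_per_100g,total_sugar_g_per_100g,sodium_mg_per_100g,"
    "protein_g_per_100g,total_fat_g_per_100g"
)


def _csv(tmp_path, rows, header=CSV_HEADER):
    path = tmp_path / "products.csv"
    path.write_text("\n".join([header] + rows) + "\n")
    return path


def test_well_formed_csv_round_trips(tmp_path):
    rows = [
        f"A{i},BrandX,3.1,fruit and vegetable purees,jar,70,10,10,0.5,0.4"
        for i in range(3)
    ]
    records = read_products(_csv(tmp_path, rows))
    assert len(records) == 3
    out = tmp_path / "again.csv"
    write_products(records, out)
    assert read_products(out) == records


def test_json_round_trip_preserves_label_detail(fixture_products, tmp_path):
    path = tmp_path / "products.json"
    write_products(fixture_products, path)
    assert read_products(path) == fixture_products


def test_csv_round_trip_preserves_fixture(fixture_products, tmp_path):
    path = tmp_path / "fixture.csv"
    write_products(fixture_products, path)
    assert read_products(path) == fixture_products


def test_out_of_range_sugar_names_product_and_field(tmp_path):
    rows = ["A1,BrandX,3.1,fruit and vegetable purees,jar,70,120,10,0.5,0.4"]
    with pytest.raises(ProductValidationError) as err:
        read_products(_csv(tmp_path, rows))
    assert err.value.product_id == "A1"
    assert "total_sugar" in str(err.value)


def test_missing_mandatory_column_is_schema_error(tmp_path):
    header = CSV_HEADER.replace("sodium_mg_per_100g,", "")
    rows = ["A1,BrandX,3.1,fruit and vegetable purees,jar,70,10,0.5,0.4"]
    with pytest.raises(SchemaError, match="sodium_mg_per_100g"):
        read_products(_csv(tmp_path, rows, header=header))


def test_energy_accepted_in_kj_when_kcal_absent(tmp_path):
    header = CSV_HEADER.replace("energy_kcal_per_100g", "energy_kj_per_100g")
    rows = ["A1,BrandX,3.1,fruit and vegetable purees,jar,418.4,10,10,0.5,0.4"]
    (record,) = read_products(_csv(tmp_path, rows, header=header))
    assert record.energy_kcal_per_100g == pytest.approx(418.4 / KJ_PER_KCAL)


def test_missing_fruit_pct_is_none_not_zero(tmp_path):
    rows = ["A1,BrandX,3.1,fruit and vegetable purees,jar,70,10,10,0.5,0.4"]
    (record,) = read_products(_csv(tmp_path, rows))
    assert record.fruit_pct is None
    assert record.added_water_pct is None


def test_fixture_file_has_45_products_16_pouches(fixture_products, tmp_path):
    path = tmp_path / "fixture.csv"
    write_products(fixture_products, path)
    records = read_products(path)
    assert len(records) == 45
    assert sum(1 for r in records if r.package_type == "pouch") == 16


# ---------------------------------------------------------------------------
# Assessment output


def test_assessments_long_form_cardinality(fixture_assessments, tmp_path):
    one = fixture_assessments[0]
    path = tmp_path / "out.csv"
    write_assessments([one], path)
    n_lines = len(path.read_text().strip().splitlines())
    assert n_lines == 1 + len(one.part_a) + len(one.part_b)


def test_assessments_round_trip_preserves_verdicts(fixture_assessments, tmp_path):
    path = tmp_path / "out.csv"
    write_assessments(fixture_assessments, path)
    back = read_assessments(path)
    assert len(back) == len(fixture_assessments)
    for a, b in zip(fixture_assessments, back):
        assert a.product_id == b.product_id
        assert a.meets_all_nutrient == b.meets_all_nutrient
        assert a.meets_all_promotion == b.meets_all_promotion
        assert a.high_sugar_flag_required == b.high_sugar_flag_required
        for ra, rb in zip(a.part_a + a.part_b, b.part_a + b.part_b):
            assert (ra.requirement_id, ra.applicable, ra.passed) == (
                rb.requirement_id,
                rb.applicable,
                rb.passed,
            )


def test_empty_assessment_list_refused(tmp_path):
    with pytest.raises(ValueError):
        write_assessments([], tmp_path / "out.csv")


# ---------------------------------------------------------------------------
# Claim tagging


@pytest.mark.parametrize(
    "text,expected",
    [
        ("no nasties", "marketing"),
        ("Source of protein", "nutritional"),
        ("zzzz-unmatched", "marketing"),
        ("supports healthy growth", "health"),
        ("100% fruit", "compositional"),
    ],
)
def test_tag_claim_lexicon(text, expected):
    lexicon = load_claim_lexicon()
    assert tag_claim(text, lexicon).category == expected


def test_tag_claim_rejects_empty_text():
    with pytest.raises(ValueError):
        tag_claim("  ", load_claim_lexicon())
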