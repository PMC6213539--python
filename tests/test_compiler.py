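import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcaadb.compiler import (
    CompilationReport,
    RecipeDef,
    adjust_by_nitrogen,
    compile_method1,
    compile_method2,
    compile_method3_cooked,
    compile_method4_recipe,
    compile_method5_zero,
    compile_table,
    match_reference,
    report_summary,
)
from bcaadb.errors import (
    DivisionUndefinedError,
    MissingReferenceValuesError,
    NotEligibleError,
    ToleranceViolationError,
    UnresolvedIngredientError,
)
from bcaadb.food_model import BCAATriple
from bcaadb.reference_data import published_report
from tests.conftest import make_item

pos = st.floats(min_value=0.05, max_value=60, allow_nan=False)


# ------------------------------------------------------ nitrogen adjustment


@pytest.mark.parametrize(
    "triple, nq, nr, expected",
    [
        ((2.0, 3.0, 2.5), 1.6, 1.6, (2.0, 3.0, 2.5)),
        ((2.0, 3.0, 2.5), 3.2, 1.6, (4.0, 6.0, 5.0)),
        ((0, 0, 0), 2.0, 1.0, (0, 0, 0)),
    ],
)
def test_adjust_by_nitrogen_scales_by_nitrogen_ratio(triple, nq, nr, expected):
    out = adjust_by_nitrogen(BCAATriple(*triple), nq, nr)
    assert out.as_tuple() == pytest.approx(expected)


def test_adjust_zero_query_nitrogen_gives_zero_triple():
    assert adjust_by_nitrogen(BCAATriple(1, 2, 1), 0.0, 2.0).total() == 0.0


def test_adjust_undefined_when_reference_has_bcaa_but_no_nitrogen():
    with pytest.raises(DivisionUndefinedError):
        adjust_by_nitrogen(BCAATriple(1, 2, 1), 1.0, 0.0)


@settings(derandomize=True)
@given(pos, pos, pos, st.floats(min_value=0, max_value=10), pos)
def test_adjust_homogeneity(i, l, v, a, n):
    # scaling the query nitrogen scales the result: adjust(b, a*n, n) = a*b
    out = adjust_by_nitrogen(BCAATriple(i, l, v), a * n, n)
    expected = (a * i, a * l, a * v)
    assert out.as_tuple() == pytest.approx(expected, rel=1e-12, abs=1e-12)


# ---------------------------------------------------------- reference match


def test_match_picks_the_only_candidate_within_tolerance():
    q = make_item("q", 10.0, name="grilled hake")
    refs = [
        make_item("r14", 14.0, name="grilled hake", bcaa=BCAATriple(1, 2, 1), table_name="t"),
        make_item("r16", 16.0, name="grilled hake", bcaa=BCAATriple(1, 2, 1), table_name="t"),
    ]
    m = match_reference(q, refs)
    assert m.reference_id == "r14"
    assert m.protein_delta == pytest.approx(-4.0)


def test_match_returns_none_outside_tolerance():
    q = make_item("q", 10.0, name="grilled hake")
    refs = [make_item("r16", 16.0, name="grilled hake", bcaa=BCAATriple(1, 2, 1))]
    assert match_reference(q, refs) is None


def test_match_tie_broken_by_minimal_delta_then_reference_id():
    # candidates at protein 8 and 12 have equal |delta| = 2; lexicographic id wins
    q = make_item("q", 10.0, name="lentil stew")
    refs = [
        make_item("rb", 12.0, name="lentil stew", bcaa=BCAATriple(1, 1, 1)),
        make_item("ra", 8.0, name="lentil stew", bcaa=BCAATriple(1, 1, 1)),
    ]
    assert match_reference(q, refs).reference_id == "ra"
    # smaller |delta| dominates the name-equal tie
    refs.append(make_item("rz", 10.5, name="lentil stew", bcaa=BCAATriple(1, 1, 1)))
    assert match_reference(q, refs).reference_id == "rz"


def test_match_explicit_map_is_authoritative_but_tolerance_checked():
    q = make_item("q", 10.0, name="odd name")
    refs = [make_item("rr", 13.0, name="completely different", bcaa=BCAATriple(1, 1, 1),
                      table_name="usda_like")]
    m = match_reference(q, refs, explicit_map={"q": ("usda_like", "rr")})
    assert m.match_source == "explicit_map" and m.reference_id == "rr"
    far = [make_item("rr", 20.0, name="x", bcaa=BCAATriple(1, 1, 1), table_name="usda_like")]
    with pytest.raises(ToleranceViolationError):
        match_reference(q, far, explicit_map={"q": ("usda_like", "rr")})


def test_match_requires_name_similarity_without_explicit_map():
    q = make_item("q", 10.0, name="roasted chestnut puree")
    refs = [make_item("r", 10.0, name="sardine fillet in oil", bcaa=BCAATriple(1, 1, 1))]
    assert match_reference(q, refs) is None


# ------------------------------------------------------------- five methods


def test_method1_equal_nitrogen_transfers_verbatim():
    q = make_item("q", 12.5)  # N = 2.0 with factor 6.25
    r = make_item("r", 12.76, factor=6.38, bcaa=BCAATriple(1.0, 2.0, 1.5))  # N = 2.0
    m = match_reference(q, [r], explicit_map={"q": ("", "r")})
    out = compile_method1(q, m, r)
    assert out.bcaa.as_tuple() == pytest.approx((1.0, 2.0, 1.5))
    assert out.provenance == "method1"


def test_method1_nitrogen_ratio_two_doubles_values():
    q = make_item("q", 25.0)
    r = make_item("r", 12.5, bcaa=BCAATriple(1.0, 2.0, 1.5))
    m = match_reference(q, [r], tolerance=15.0, explicit_map={"q": ("", "r")})
    assert compile_method1(q, m, r).bcaa.as_tuple() == pytest.approx((2.0, 4.0, 3.0))


def test_method1_requires_reference_values():
    q = make_item("q", 10.0)
    r = make_item("r", 10.0)
    m = match_reference(q, [make_item("r", 10.0, bcaa=BCAATriple(1, 1, 1))],
                        explicit_map={"q": ("", "r")})
    with pytest.raises(MissingReferenceValuesError):
        compile_method1(q, m, r)


def test_method1_matches_direct_formula_on_random_inputs():
    rng = np.random.default_rng(42)
    for _ in range(1000):
        qp = rng.uniform(0.1, 40)
        rp = rng.uniform(0.1, 40)
        rf = rng.choice([6.25, 6.38, 5.71])
        ref_b = rng.uniform(0, 4, size=3)
        q = make_item("q", qp)
        r = make_item("r", rp, factor=rf, bcaa=BCAATriple(*ref_b))
        m = match_reference(q, [r], tolerance=1e9, explicit_map={"q": ("", "r")})
        out = compile_method1(q, m, r)
        expected = ref_b * (qp / 6.25) / (rp / rf)
        assert out.bcaa.as_tuple() == pytest.approx(tuple(expected), rel=1e-12)


def test_method2_stores_literature_value_verbatim_with_citation():
    q = make_item("q", 11.0)
    out = compile_method2(q, BCAATriple(0.5, 0.9, 0.6), "ref X")
    assert out.bcaa.as_tuple() == (0.5, 0.9, 0.6)
    assert out.provenance == "method2" and out.citation == "ref X"


def test_method2_zero_triple_keeps_method2_provenance():
    out = compile_method2(make_item("q", 0.05), BCAATriple(0, 0, 0), "ref Y")
    assert out.provenance == "method2"


def test_method2_missing_citation_is_flagged_in_report():
    items = [
        compile_method2(make_item("a", 1.0), BCAATriple(0.1, 0.1, 0.1), ""),
        compile_method2(make_item("b", 1.0), BCAATriple(0.1, 0.1, 0.1), "cited"),
    ]
    rep = CompilationReport.from_items(items)
    assert rep.method2_missing_citation == ["a"]


def test_method3_scales_like_method1_and_preserves_ratios():
    cooked = make_item("c", 25.0)  # N = 4
    raw = make_item("r", 12.5, bcaa=BCAATriple(1.0, 2.0, 1.0))  # N = 2
    out = compile_method3_cooked(cooked, raw)
    assert out.bcaa.as_tuple() == pytest.approx((2.0, 4.0, 2.0))
    assert out.provenance == "method3"


@settings(derandomize=True)
@given(pos, pos, pos, pos, pos)
def test_method3_ratio_preservation_property(qp, rp, i, l, v):
    cooked = make_item("c", qp)
    raw = make_item("r", rp, bcaa=BCAATriple(i, l, v))
    out = compile_method3_cooked(cooked, raw)
    total_out, total_ref = out.bcaa.total(), raw.bcaa.total()
    for a, b in zip(out.bcaa.as_tuple(), raw.bcaa.as_tuple()):
        assert a / total_out == pytest.approx(b / total_ref, rel=1e-12)


def test_method4_two_ingredient_weighted_mean():
    chicken = make_item("ch", 30.0, bcaa=BCAATriple(1.5, 2.0, 1.5), energy=200.0)
    rice = make_item("ri", 2.5, bcaa=BCAATriple(0.3, 0.4, 0.3), energy=130.0)
    recipe = RecipeDef("dish", [("ch", "cooked", 60.0), ("ri", "cooked", 40.0)], 100.0)
    dish = compile_method4_recipe(recipe, [chicken, rice])
    # totals 5.0 and 1.0 g/100 g -> 0.6*5 + 0.4*1 = 3.4
    assert dish.bcaa.total() == pytest.approx(3.4)
    assert dish.protein == pytest.approx(0.6 * 30 + 0.4 * 2.5)
    assert dish.provenance == "method4"


def test_method4_identity_recipe_reproduces_single_ingredient():
    ing = make_item("solo", 10.0, bcaa=BCAATriple(0.5, 1.0, 0.5), energy=100.0)
    recipe = RecipeDef("dish", [("solo", "cooked", 250.0)], 250.0)
    dish = compile_method4_recipe(recipe, [ing])
    assert dish.bcaa.as_tuple() == pytest.approx(ing.bcaa.as_tuple())
    assert dish.protein == pytest.approx(ing.protein)


def test_method4_matches_gram_by_gram_oracle_on_random_recipes():
    rng = np.random.default_rng(7)
    for _ in range(200):
        n = int(rng.integers(2, 7))
        table, ingredients, factors = [], [], {}
        for j in range(n):
            iid = f"i{j}"
            table.append(make_item(iid, float(rng.uniform(0, 30)),
                                   bcaa=BCAATriple(*rng.uniform(0, 3, 3)), energy=100.0))
            state = "raw" if rng.random() < 0.5 else "cooked"
            if state == "raw":
                factors[iid] = float(rng.uniform(0.5, 1.2))
            ingredients.append((iid, state, float(rng.uniform(10, 200))))
        yield_g = float(rng.uniform(100, 500))
        recipe = RecipeDef("d", ingredients, yield_g, factors)
        dish = compile_method4_recipe(recipe, table)
        # independent oracle: accumulate per-gram contributions
        exp = np.zeros(3)
        for (iid, state, grams), item in zip(ingredients, table):
            eff = grams * factors.get(iid, 1.0) if state == "raw" else grams
            per_gram = np.array(item.bcaa.as_tuple()) / 100.0
            exp += eff * per_gram
        exp = exp * 100.0 / yield_g
        assert dish.bcaa.as_tuple() == pytest.approx(tuple(exp), rel=1e-12)


def test_method4_convexity_dish_never_exceeds_richest_ingredient():
    # weighted mean with proportions summing to 1 stays below the max
    a = make_item("a", 20.0, bcaa=BCAATriple(1, 2, 1), energy=100.0)
    b = make_item("b", 5.0, bcaa=BCAATriple(0.2, 0.3, 0.2), energy=100.0)
    recipe = RecipeDef("d", [("a", "cooked", 30.0), ("b", "cooked", 70.0)], 100.0)
    dish = compile_method4_recipe(recipe, [a, b])
    assert dish.bcaa.total() <= max(a.bcaa.total(), b.bcaa.total()) + 1e-12


def test_method4_unresolved_ingredient_is_an_error():
    recipe = RecipeDef("d", [("ghost", "cooked", 100.0)], 100.0)
    with pytest.raises(UnresolvedIngredientError):
        compile_method4_recipe(recipe, [make_item("other", 1.0, bcaa=BCAATriple(0, 0, 0),
                                                  provenance="source_table")])


@pytest.mark.parametrize("group10, group18", [
    ("Fats and oils", "Fats and oil"), ("Sugars and confectioneries", "Sugar and confectionery"),
])
def test_method5_assigns_zero_to_protein_free_items(group10, group18):
    item = make_item("z", 0.0, group10=group10, group18=group18)
    out = compile_method5_zero(item)
    assert out.bcaa.total() == 0.0 and out.provenance == "method5"


def test_method5_rejects_items_with_protein_above_epsilon():
    with pytest.raises(NotEligibleError):
        compile_method5_zero(make_item("drink", 0.3, group10="Beverages", group18="Drinks"))
    # at the default epsilon, 0.1 g is still protein-free
    assert compile_method5_zero(make_item("d2", 0.1)).provenance == "method5"


# ----------------------------------------------------------------- cascade


def test_cascade_counts_on_engineered_fixture(cascade_fixture):
    compiled, report = compile_table(**cascade_fixture)
    totals = report.method_totals()
    assert tuple(totals[c] for c in report.COLUMNS) == (5, 1, 1, 2, 2, 1)
    assert report.total_items == 12
    prov = {it.item_id: it.provenance for it in compiled}
    assert prov["m2_0"] == "method2" and prov["m3_0"] == "method3"
    assert prov["nc_0"] == "not_compiled"


def test_cascade_method1_wins_over_recipe_when_reference_matches(cascade_fixture):
    fx = dict(cascade_fixture)
    # give a method-1 item a recipe too: the earlier method must still win
    fx["recipes"] = fx["recipes"] + [
        RecipeDef("m1_0", [("m1_1", "cooked", 100.0)], 100.0)
    ]
    compiled, _ = compile_table(**fx)
    assert {it.item_id: it.provenance for it in compiled}["m1_0"] == "method1"


def test_cascade_protein_free_item_falls_through_to_method5():
    target = [make_item("water", 0.0, group10="Beverages", group18="Drinks")]
    compiled, report = compile_table(target)
    assert compiled[0].provenance == "method5"


def test_cascade_is_deterministic(cascade_fixture):
    _, r1 = compile_table(**cascade_fixture)
    _, r2 = compile_table(**cascade_fixture)
    assert r1.counts.equals(r2.counts)


def test_cascade_totality(pipeline_result):
    compiled = pipeline_result["compiled"]
    report = pipeline_result["report"]
    valid = set(report.COLUMNS) | {"source_table"}
    assert all(it.provenance in valid for it in compiled)
    assert report.total_items == len(compiled)


# ------------------------------------------------------------------ report


def test_report_summary_on_published_counts():
    summary = report_summary(published_report())
    assert summary["total_compiled"] == 1331
    assert summary["method_totals"] == {
        "method1": 993, "method2": 7, "method3": 6, "method4": 174, "method5": 151,
    }
    assert summary["not_compiled"] == 109
    assert summary["method_share_pct"]["method1"] == 75


def test_report_summary_single_method_share_is_100():
    items = [compile_method5_zero(make_item(f"z{i}", 0.0)) for i in range(4)]
    summary = report_summary(CompilationReport.from_items(items))
    assert summary["method_share_pct"]["method5"] == 100


def test_report_summary_empty_report_is_empty():
    assert report_summary(CompilationReport.from_items([])) == {}


def test_report_row_and_column_sums_match_grand_total(pipeline_result):
    report = pipeline_result["report"]
    assert report.method_totals().sum() == report.total_items
    assert report.group_totals().sum() == report.total_items
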