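import pytest

from bcaadb.food_model import BCAATriple, FoodItem
from bcaadb.compiler import RecipeDef
from bcaadb.pipeline import run_pipeline
from bcaadb.simulate import SimConfig


def make_item(item_id, protein, group10="Meat, poultry, and fish",
              group18="Red meat and poultry", bcaa=None, provenance=None,
              name=None, factor=6.25, energy=None, table_name=""):
    """Terse FoodItem builder for tests."""
    if provenance is None:
        provenance = "source_table" if bcaa is not None else "not_compiled"
    return FoodItem(
        item_id=item_id,
        names={"en": name or item_id},
        group10=group10,
        group18=group18,
        protein=protein,
        nitrogen_factor=factor,
        bcaa=bcaa,
        provenance=provenance,
        energy_kcal=energy,
        table_name=table_name,
    )


@pytest.fixture(scope="session")
def cascade_fixture():
    """Hand-built 12-item target where methods 1-5 fire on {5,1,1,2,2}
    items and one item cannot be compiled."""
    target, references = [], []
    literature, raw_map = {}, {}
    recipes = []

    # 5 items for method 1: same-named reference within protein tolerance
    for i, (p, rp, rf) in enumerate(
        [(20.0, 21.0, 6.25), (10.0, 12.0, 6.38), (5.0, 4.0, 5.71),
         (15.0, 15.0, 6.25), (8.0, 9.5, 6.25)]
    ):
        qid = f"m1_{i}"
        target.append(make_item(qid, p, name=f"target food {i}", energy=150.0))
        references.append(make_item(
            f"ref_{i}", rp, name=f"target food {i}", factor=rf,
            bcaa=BCAATriple(0.9, 1.6, 1.0), table_name="usda_like",
        ))

    # 1 item for method 2: literature value
    target.append(make_item("m2_0", 11.0, name="lit food", energy=120.0))
    literature["m2_0"] = (BCAATriple(0.5, 0.9, 0.6), "ref X")

    # 1 item for method 3: cooked with raw counterpart in references
    target.append(make_item("m3_0", 26.0, name="braised cut", energy=200.0))
    references.append(make_item(
        "raw_0", 13.0, name="uncooked cut stock", bcaa=BCAATriple(1.0, 2.0, 1.0),
        table_name="usda_like",
    ))
    raw_map["m3_0"] = "raw_0"

    # 2 items for method 4: recipes over the method-1 items
    for i in range(2):
        rid = f"m4_{i}"
        target.append(make_item(
            rid, 0.0, group10="Mixed dishes and soups", group18="Mixed Dishes",
            name=f"casserole {i}", energy=None,
        ))
        recipes.append(RecipeDef(
            rid,
            [("m1_0", "cooked", 60.0), ("m1_1", "raw", 50.0)],
            yield_grams=100.0,
            yield_factors={"m1_1": 0.8},
        ))

    # 2 items for method 5: protein-free
    for i in range(2):
        target.append(make_item(
            f"m5_{i}", 0.0, group10="Beverages", group18="Drinks",
            name=f"spring water {i}", energy=0.0,
        ))

    # 1 item no method reaches
    target.append(make_item("nc_0", 3.0, name="mystery morsel", energy=90.0))

    return {
        "target": target,
        "references": references,
        "recipes": recipes,
        "literature": literature,
        "raw_map": raw_map,
    }


@pytest.fixture(scope="session")
def pipeline_result():
    """One mid-sized synthetic study shared by the analysis tests."""
    return run_pipeline(SimConfig(seed=3, n_items=150, n_subjects=400))
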