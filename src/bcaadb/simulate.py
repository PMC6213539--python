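"""Deterministic synthetic fixtures with known ground truth.

The generator emulates the inputs of a BCAA compilation-and-survey
study: a CIQUAL-like target table without amino acids, reference tables
(with varied nitrogen-to-protein factors), literature values, recipes,
and a 24-h recall survey of children/adolescents with anthropometrics.
Every item records the method intended to compile it and its true
amino-acid content; every subject records true intakes, quartile and
misreporter status, so each pipeline stage can be checked against truth.

All randomness flows from ``SimConfig.seed`` through a single
``numpy`` generator; equal seeds give bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from bcaadb.compiler import RecipeDef
from bcaadb.errors import ValidationError
from bcaadb.food_model import BCAATriple, FoodItem
from bcaadb.survey import SubjectProfile

#: Fixture-level 18 -> 10 group mapping (the real breakdown is curated
#: per item; this fixed map is the generator's choice).
GROUP18_TO_10 = {
    "Offal": "Meat, poultry, and fish",
    "Red meat and poultry": "Meat, poultry, and fish",
    "Luncheon meats": "Meat, poultry, and fish",
    "Fish and seafood": "Meat, poultry, and fish",
    "Milk and dairy products": "Dairy products and cheese",
    "Cheese": "Dairy products and cheese",
    "Eggs and related products": "Meat, poultry, and fish",
    "Bread, Pasta, cereals": "Cereals and pasta",
    "Pastries and brioches": "Cereals and pasta",
    "Cakes": "Cereals and pasta",
    "Fruits and vegetables": "Vegetables, fruits",
    "Legumes": "Vegetables, fruits",
    "Nuts and Seeds": "Vegetables, fruits",
    "Mixed Dishes": "Mixed dishes and soups",
    "Fats and oil": "Fats and oils",
    "Sugar and confectionery": "Sugars and confectioneries",
    "Drinks": "Beverages",
    "Herbs, spices and condiments": "Sauces and condiments",
}

#: Mean protein (g/100 g) per subgroup, calibrated qualitatively so that
#: meat/fish rank highest in BCAA and drinks lowest.
GROUP_PROTEIN_MEAN = {
    "Offal": 18.0,
    "Red meat and poultry": 21.0,
    "Luncheon meats": 15.0,
    "Fish and seafood": 19.0,
    "Milk and dairy products": 3.5,
    "Cheese": 22.0,
    "Eggs and related products": 12.5,
    "Bread, Pasta, cereals": 9.0,
    "Pastries and brioches": 6.5,
    "Cakes": 5.0,
    "Fruits and vegetables": 1.2,
    "Legumes": 8.0,
    "Nuts and Seeds": 15.0,
    "Fats and oil": 0.2,
    "Sugar and confectionery": 0.5,
    "Drinks": 0.2,
    "Herbs, spices and condiments": 3.0,
}

#: Relative sampling weight of each non-mixed subgroup in the target table.
GROUP_WEIGHTS = {
    "Offal": 2, "Red meat and poultry": 10, "Luncheon meats": 4,
    "Fish and seafood": 8, "Milk and dairy products": 8, "Cheese": 8,
    "Eggs and related products": 2, "Bread, Pasta, cereals": 10,
    "Pastries and brioches": 3, "Cakes": 3, "Fruits and vegetables": 16,
    "Legumes": 3, "Nuts and Seeds": 2, "Fats and oil": 4,
    "Sugar and confectionery": 4, "Drinks": 9,
    "Herbs, spices and condiments": 4,
}

#: Average ile:leu:val split of total BCAA (protein-typical proportions).
BCAA_SPLIT = np.array([0.27, 0.45, 0.28])

REFERENCE_NITROGEN_FACTORS = (6.25, 6.38, 5.71)
REFERENCE_TABLE_NAMES = ("usda_like", "danish_like", "canadian_like")


@dataclass
class SimConfig:
    """Study conditions of the synthetic fixtures.

    ``method_fractions`` gives the share of target items intended for
    each compilation route; ``planted_logodds`` is the (Q2, Q3, Q4)
    log-odds of obesity relative to Q1 (all zero = null).
    """

    seed: int = 0
    n_items: int = 300
    n_subjects: int = 2000
    days_per_subject: int = 3
    misreporter_fraction: float = 0.05
    planted_logodds: tuple[float, float, float] = (0.0, 0.0, 0.0)
    baseline_obesity: float = 0.30
    method_fractions: dict[str, float] = field(default_factory=lambda: {
        "method1": 0.60, "method2": 0.03, "method3": 0.04,
        "method4": 0.10, "method5": 0.15, "not_compiled": 0.08,
    })
    protein_cv: float = 0.30
    bcaa_per_protein: tuple[float, float] = (0.15, 0.22)
    items_per_meal: tuple[int, int] = (1, 4)
    mean_grams: float = 110.0
    target_energy_mean: float = 2200.0
    target_energy_sd: float = 350.0

    def __post_init__(self) -> None:
        total = sum(self.method_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"method fractions must sum to 1, got {total}")
        if not 0 <= self.misreporter_fraction < 1:
            raise ValidationError("misreporter fraction must be in [0, 1)")


def _uid(rng: np.random.Generator) -> str:
    letters = "abcdefghijklmnopqrstuvwxyz"
    return "".join(rng.choice(list(letters), size=8))


def _draw_composition(rng: np.random.Generator, group18: str, cfg: SimConfig):
    """Protein, BCAA triple and energy density for one item of a subgroup."""
    mean = GROUP_PROTEIN_MEAN[group18]
    sigma = np.sqrt(np.log(1 + cfg.protein_cv**2))
    protein = float(mean * rng.lognormal(-sigma**2 / 2, sigma))
    ratio = float(rng.uniform(*cfg.bcaa_per_protein))
    total = ratio * protein
    split = BCAA_SPLIT + rng.normal(0, 0.01, size=3)
    split = np.clip(split, 0.05, None)
    split = split / split.sum()
    bcaa = BCAATriple(*(total * split))
    energy = float(4.0 * protein + rng.lognormal(np.log(120.0), 0.6))
    return protein, bcaa, energy


def make_food_tables(cfg: SimConfig):
    """Generate the compiler's inputs plus an item-level truth table.

    Returns ``(target, references, recipes, literature, explicit_map,
    raw_map, truth)`` where ``truth`` is a DataFrame (item_id,
    intended_method, true ile/leu/val, energy) recording what a correct
    compilation must produce.
    """
    rng = np.random.default_rng(cfg.seed)
    groups = list(GROUP_WEIGHTS)
    weights = np.array([GROUP_WEIGHTS[g] for g in groups], dtype=float)
    weights /= weights.sum()

    fr = cfg.method_fractions
    n4 = int(round(fr["method4"] * cfg.n_items))
    n_plain = cfg.n_items - n4
    counts = {
        "method1": int(round(fr["method1"] * cfg.n_items)),
        "method2": int(round(fr["method2"] * cfg.n_items)),
        "method3": int(round(fr["method3"] * cfg.n_items)),
        "method5": int(round(fr["method5"] * cfg.n_items)),
    }
    counts["not_compiled"] = n_plain - sum(counts.values())
    if counts["not_compiled"] < 0:
        raise ValidationError("method fractions leave no room for not_compiled items")

    target: list[FoodItem] = []
    references: list[FoodItem] = []
    literature: dict[str, tuple[BCAATriple, str]] = {}
    explicit_map: dict[str, tuple[str, str]] = {}
    raw_map: dict[str, str] = {}
    recipes: list[RecipeDef] = []
    truth_rows: list[dict] = []
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"F{idx:04d}"

    def pick_group() -> str:
        return groups[int(rng.choice(len(groups), p=weights))]

    # --- method 1: a same-named reference within the protein tolerance
    for _ in range(counts["method1"]):
        g18 = pick_group()
        item_id = next_id()
        uid = _uid(rng)
        protein, _, energy = _draw_composition(rng, g18, cfg)
        t = int(rng.integers(0, len(REFERENCE_TABLE_NAMES)))
        ref_factor = REFERENCE_NITROGEN_FACTORS[t]
        ref_protein = max(0.05, protein + float(rng.uniform(-2.0, 2.0)))
        _, ref_bcaa, ref_energy = _draw_composition(rng, g18, cfg)
        ref = FoodItem(
            item_id=f"R{item_id}", names={"en": f"item {uid}"},
            group10=GROUP18_TO_10[g18], group18=g18, protein=ref_protein,
            nitrogen_factor=ref_factor, bcaa=ref_bcaa, provenance="source_table",
            energy_kcal=ref_energy, table_name=REFERENCE_TABLE_NAMES[t],
        )
        references.append(ref)
        target.append(FoodItem(
            item_id=item_id, names={"en": f"item {uid}"},
            group10=GROUP18_TO_10[g18], group18=g18, protein=protein,
            energy_kcal=energy,
        ))
        n_q = protein / 6.25
        n_r = ref_protein / ref_factor
        true = ref_bcaa.scale(n_q / n_r) if n_q > 0 else BCAATriple(0, 0, 0)
        truth_rows.append({"item_id": item_id, "intended_method": "method1",
                           "ile": true.isoleucine, "leu": true.leucine,
                           "val": true.valine, "energy_kcal": energy})

    # --- method 2: literature values stored verbatim
    for _ in range(counts["method2"]):
        g18 = pick_group()
        item_id = next_id()
        protein, bcaa, energy = _draw_composition(rng, g18, cfg)
        target.append(FoodItem(
            item_id=item_id, names={"en": f"item {_uid(rng)}"},
            group10=GROUP18_TO_10[g18], group18=g18, protein=protein,
            energy_kcal=energy,
        ))
        literature[item_id] = (bcaa, f"HPLC study {_uid(rng)[:4]}")
        truth_rows.append({"item_id": item_id, "intended_method": "method2",
                           "ile": bcaa.isoleucine, "leu": bcaa.leucine,
                           "val": bcaa.valine, "energy_kcal": energy})

    # --- method 3: cooked item with a raw counterpart in the references
    for _ in range(counts["method3"]):
        g18 = pick_group()
        item_id = next_id()
        uid = _uid(rng)
        protein_raw, bcaa_raw, energy = _draw_composition(rng, g18, cfg)
        protein_cooked = protein_raw * float(rng.uniform(1.1, 1.5))  # water loss concentrates
        raw = FoodItem(
            item_id=f"R{item_id}", names={"en": f"item {uid} raw"},
            group10=GROUP18_TO_10[g18], group18=g18, protein=protein_raw,
            nitrogen_factor=6.25, bcaa=bcaa_raw, provenance="source_table",
            energy_kcal=energy, table_name="usda_like",
        )
        references.append(raw)
        target.append(FoodItem(
            item_id=item_id, names={"en": f"item {uid} cooked"},
            group10=GROUP18_TO_10[g18], group18=g18, protein=protein_cooked,
            energy_kcal=energy,
        ))
        raw_map[item_id] = f"R{item_id}"
        true = bcaa_raw.scale((protein_cooked / 6.25) / (protein_raw / 6.25))
        truth_rows.append({"item_id": item_id, "intended_method": "method3",
                           "ile": true.isoleucine, "leu": true.leucine,
                           "val": true.valine, "energy_kcal": energy})

    # --- method 5: protein-free items
    m5_groups = ("Fats and oil", "Drinks", "Sugar and confectionery")
    for _ in range(counts["method5"]):
        g18 = m5_groups[int(rng.integers(0, len(m5_groups)))]
        item_id = next_id()
        energy = float(rng.lognormal(np.log(150.0), 0.8))
        target.append(FoodItem(
            item_id=item_id, names={"en": f"item {_uid(rng)}"},
            group10=GROUP18_TO_10[g18], group18=g18, protein=0.0,
            energy_kcal=energy,
        ))
        truth_rows.append({"item_id": item_id, "intended_method": "method5",
                           "ile": 0.0, "leu": 0.0, "val": 0.0,
                           "energy_kcal": energy})

    # --- not compiled: protein-bearing items no method can reach
    for _ in range(counts["not_compiled"]):
        g18 = pick_group()
        item_id = next_id()
        protein, _, energy = _draw_composition(rng, g18, cfg)
        protein = max(protein, 0.2)
        target.append(FoodItem(
            item_id=item_id, names={"en": f"item {_uid(rng)}"},
            group10=GROUP18_TO_10[g18], group18=g18, protein=protein,
            energy_kcal=energy,
        ))
        truth_rows.append({"item_id": item_id, "intended_method": "not_compiled",
                           "ile": np.nan, "leu": np.nan, "val": np.nan,
                           "energy_kcal": energy})

    # --- method 4: mixed dishes from already-compiled base items
    truth_by_id = {r["item_id"]: r for r in truth_rows}
    base_ids = [r["item_id"] for r in truth_rows if r["intended_method"] == "method1"]
    for _ in range(n4):
        item_id = next_id()
        k = int(rng.integers(2, 5))
        chosen = list(rng.choice(base_ids, size=min(k, len(base_ids)), replace=False))
        ingredients = []
        factors = {}
        eff_total = 0.0
        for ing_id in chosen:
            grams = float(rng.uniform(30.0, 120.0))
            if rng.random() < 0.4:
                state = "raw"
                factors[ing_id] = float(rng.uniform(0.6, 1.0))
                eff_total += grams * factors[ing_id]
            else:
                state = "cooked"
                eff_total += grams
            ingredients.append((ing_id, state, grams))
        recipe = RecipeDef(item_id, ingredients, yield_grams=eff_total, yield_factors=factors)
        recipes.append(recipe)
        # truth by gram-by-gram accumulation over ingredient compositions
        ile = leu = val = prot = en = 0.0
        for ing_id, state, grams in ingredients:
            tr = truth_by_id[ing_id]
            eff = grams * factors.get(ing_id, 1.0) if state == "raw" else grams
            w = eff / recipe.yield_grams
            ile += w * tr["ile"]
            leu += w * tr["leu"]
            val += w * tr["val"]
            en += w * tr["energy_kcal"]
            prot += w * next(t for t in target if t.item_id == ing_id).protein
        target.append(FoodItem(
            item_id=item_id, names={"en": f"dish {_uid(rng)}"},
            group10="Mixed dishes and soups", group18="Mixed Dishes",
            protein=prot, energy_kcal=en,
        ))
        truth_rows.append({"item_id": item_id, "intended_method": "method4",
                           "ile": ile, "leu": leu, "val": val, "energy_kcal": en})

    truth = pd.DataFrame(truth_rows).set_index("item_id")
    return target, references, recipes, literature, explicit_map, raw_map, truth


def simulate_quartile_cohort(
    rng: np.random.Generator,
    n: int,
    logodds: tuple[float, float, float] = (0.0, 0.0, 0.0),
    baseline: float = 0.30,
):
    """Model-level cohort for association checks: exact-model plant.

    Quartiles are balanced by construction; age and energy are noise
    covariates with no effect; the outcome follows the logistic model
    the association stage fits, with (Q2, Q3, Q4) log-odds ``logodds``
    relative to Q1.  Returns ``(quartile, outcome, age, energy)``.
    """
    quartile = rng.permutation(np.tile(np.arange(1, 5), n // 4 + 1)[:n])
    age = rng.uniform(9.0, 18.0, size=n)
    energy = rng.normal(2200.0, 350.0, size=n)
    alpha = float(np.log(baseline / (1 - baseline)))
    beta = np.array([0.0, *logodds])
    p = 1.0 / (1.0 + np.exp(-(alpha + beta[quartile - 1])))
    outcome = (rng.random(n) < p).astype(float)
    return quartile, outcome, age, energy


def make_survey(cfg: SimConfig, compiled: list[FoodItem]):
    """Generate recalls, subject profiles and subject-level truth.

    Subjects draw items for each meal of each day; per-subject grams are
    rescaled so reported energy matches a plausible target, after which
    a ``misreporter_fraction`` of subjects is pushed outside the
    1000–4000 kcal screening bounds (half over-, half under-reporters).
    Obesity is sampled from a logistic model on the true intake quartile
    (computed among plausible reporters) with the planted log-odds.

    Returns ``(recalls, profiles, truth)``; ``truth`` records per-subject
    true mean intakes, quartile, obesity and misreporter status.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    menu = [it for it in compiled if it.bcaa is not None]
    if not menu:
        raise ValidationError("compiled table has no usable items")
    comp = pd.DataFrame({
        "item_id": [it.item_id for it in menu],
        "energy": [it.energy_kcal or 0.0 for it in menu],
        "ile": [it.bcaa.isoleucine for it in menu],
        "leu": [it.bcaa.leucine for it in menu],
        "val": [it.bcaa.valine for it in menu],
    })
    meals = ("breakfast", "lunch", "dinner", "snacks")

    n_mis = int(round(cfg.misreporter_fraction * cfg.n_subjects))
    mis_ids = rng.choice(cfg.n_subjects, size=n_mis, replace=False)
    over_set = set(mis_ids[: n_mis // 2].tolist())
    under_set = set(mis_ids[n_mis // 2:].tolist())

    recall_rows = []
    profile_rows = []
    truth_rows = []
    lo, hi = cfg.items_per_meal
    for s in range(cfg.n_subjects):
        sid = f"S{s + 1:05d}"
        age = float(rng.uniform(9.0, 18.0))
        sex = "male" if rng.random() < 0.5 else "female"
        height = float(120 + 4.5 * (age - 9) + rng.normal(0, 6))
        weight = float(20.0 + 3.3 * (age - 9) + rng.normal(0, 5))
        weight = max(weight, 18.0)
        bmi = weight / (height / 100.0) ** 2

        picks = []  # (day, meal, row index in comp, grams)
        for day in range(1, cfg.days_per_subject + 1):
            for meal in meals:
                k = int(rng.integers(lo, hi + 1))
                rows = rng.integers(0, len(comp), size=k)
                for r in rows:
                    grams = float(rng.lognormal(np.log(cfg.mean_grams), 0.5))
                    picks.append((day, meal, int(r), grams))
        grams_arr = np.array([p[3] for p in picks])
        energy_arr = comp["energy"].to_numpy()[[p[2] for p in picks]]
        raw_daily_energy = float((grams_arr / 100.0 * energy_arr).sum()) / cfg.days_per_subject
        if s in over_set:
            target_energy = float(rng.uniform(4200.0, 5200.0))
            mis = "over"
        elif s in under_set:
            target_energy = float(rng.uniform(550.0, 950.0))
            mis = "under"
        else:
            target_energy = float(np.clip(
                rng.normal(cfg.target_energy_mean, cfg.target_energy_sd), 1200.0, 3800.0
            ))
            mis = ""
        scale = target_energy / raw_daily_energy
        idxs = [p[2] for p in picks]
        g_scaled = grams_arr * scale
        sub = comp.iloc[idxs]
        w = g_scaled / 100.0 / cfg.days_per_subject
        true_ile = float((w * sub["ile"].to_numpy()).sum())
        true_leu = float((w * sub["leu"].to_numpy()).sum())
        true_val = float((w * sub["val"].to_numpy()).sum())
        true_energy = float((w * sub["energy"].to_numpy()).sum())
        for (day, meal, r, _), grams in zip(picks, g_scaled):
            recall_rows.append((sid, day, meal, comp["item_id"].iat[r], grams))
        profile_rows.append({
            "subject_id": sid, "age": age, "sex": sex, "weight": weight,
            "height": height, "bmi": bmi,
        })
        truth_rows.append({
            "subject_id": sid, "ile": true_ile, "leu": true_leu, "val": true_val,
            "total_bcaa": true_ile + true_leu + true_val,
            "energy_kcal": true_energy, "misreporter": mis,
        })

    truth = pd.DataFrame(truth_rows).set_index("subject_id")

    # quartiles among plausible reporters; obesity from the planted model
    kept = truth[truth["misreporter"] == ""]
    q = np.quantile(kept["total_bcaa"], [0.25, 0.5, 0.75])
    quartile = 1 + np.searchsorted(q, truth["total_bcaa"].to_numpy(), side="left")
    truth["quartile"] = quartile
    alpha = float(np.log(cfg.baseline_obesity / (1 - cfg.baseline_obesity)))
    beta = np.array([0.0, *cfg.planted_logodds])
    logit = alpha + beta[quartile - 1]
    p_obese = 1.0 / (1.0 + np.exp(-logit))
    obese = rng.random(cfg.n_subjects) < p_obese
    truth["obese"] = obese

    profiles = []
    for row, ob in zip(profile_rows, obese):
        profiles.append(SubjectProfile(
            subject_id=row["subject_id"], age=row["age"], sex=row["sex"],
            weight=row["weight"], height=row["height"], bmi=row["bmi"],
            obesity_flag=bool(ob), activity_level=None,
        ))
    recalls = pd.DataFrame(
        recall_rows, columns=["subject_id", "day_index", "meal", "item_id", "grams"]
    )
    return recalls, profiles, truth
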