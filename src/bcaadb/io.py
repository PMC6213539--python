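"""CSV readers/writers for every table the pipeline exchanges.

All files are UTF-8, comma-separated, dot-decimal, with a header row.
Numeric cells are written with 6 decimals so write/read round-trips are
exact to far better than 1e-6; empty cells mean "absent".  A
``dialect="ciqual"`` flag converts semicolon-separated, comma-decimal
exports on load.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from bcaadb.errors import SchemaError, ValidationError
from bcaadb.food_model import BCAATriple, DEFAULT_NITROGEN_FACTOR, FoodItem
from bcaadb.compiler import RecipeDef
from bcaadb.survey import SubjectProfile


@dataclass(frozen=True)
class TableSchema:
    """Declared columns of a CSV table; required must appear in the header."""

    name: str
    required: tuple[str, ...]
    optional: tuple[str, ...] = ()
    units: dict[str, str] = field(default_factory=dict)

    def validate_header(self, columns) -> None:
        missing = set(self.required) - set(columns)
        if missing:
            raise SchemaError(f"{self.name}: missing required columns {sorted(missing)}")


FOOD_TABLE_SCHEMA = TableSchema(
    name="food_table",
    required=("item_id", "group10", "protein_g"),
    optional=(
        "name_fr", "name_en", "group18", "nitrogen_factor",
        "ile_g", "leu_g", "val_g", "provenance", "energy_kcal_100g",
        "citation", "table_name",
    ),
    units={"protein_g": "g/100 g", "ile_g": "g/100 g", "leu_g": "g/100 g",
           "val_g": "g/100 g", "energy_kcal_100g": "kcal/100 g"},
)

RECALLS_SCHEMA = TableSchema(
    name="recalls",
    required=("subject_id", "day_index", "meal", "item_id", "grams"),
    units={"grams": "g consumed"},
)

PROFILES_SCHEMA = TableSchema(
    name="profiles",
    required=("subject_id", "age", "sex"),
    optional=("weight_kg", "height_cm", "bmi", "obesity_flag", "activity_level", "energy_kcal"),
    units={"weight_kg": "kg", "height_cm": "cm", "energy_kcal": "kcal/day"},
)

RECIPES_SCHEMA = TableSchema(
    name="recipes",
    required=("recipe_id", "ingredient_id", "state", "grams"),
    optional=("yield_factor",),
    units={"grams": "g in recipe"},
)

MAP_SCHEMA = TableSchema(
    name="explicit_map",
    required=("query_id", "reference_table", "reference_id"),
)


def _read_csv(path, dialect: str = "standard") -> pd.DataFrame:
    if dialect == "ciqual":
        df = pd.read_csv(path, sep=";", dtype=str, keep_default_na=False)
        # decimal-comma cells ("0,50") -> dot decimal; text cells untouched
        return df.apply(lambda col: col.str.replace(
            r"^(-?\d+),(\d+)$", r"\1.\2", regex=True))
    return pd.read_csv(path, dtype=str, keep_default_na=False)


def _num(cell: str, default: float | None = None) -> float | None:
    if cell is None or str(cell).strip() == "":
        return default
    try:
        return float(cell)
    except ValueError as exc:
        raise ValidationError(f"non-numeric cell {cell!r}") from exc


def read_food_table(
    path, dialect: str = "standard", strict: bool = False
) -> tuple[list[FoodItem], list[str]]:
    """Load a food-composition table.

    Invalid rows are rejected with a warning (or raise when
    ``strict=True``); valid rows load as :class:`FoodItem`.  Returns the
    items and the list of row-level warnings.
    """
    df = _read_csv(path, dialect)
    FOOD_TABLE_SCHEMA.validate_header(df.columns)
    items: list[FoodItem] = []
    warnings: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # 1-based plus header
        try:
            names = {}
            for lang in ("fr", "en"):
                col = f"name_{lang}"
                if col in df.columns and str(row[col]).strip():
                    names[lang] = str(row[col]).strip()
            if not names:
                names = {"en": str(row["item_id"])}
            ile = _num(row.get("ile_g", ""))
            leu = _num(row.get("leu_g", ""))
            val = _num(row.get("val_g", ""))
            present = [v is not None for v in (ile, leu, val)]
            if any(present) and not all(present):
                raise ValidationError("partial amino-acid triple")
            bcaa = BCAATriple(ile, leu, val) if all(present) else None
            provenance = str(row.get("provenance", "")).strip() or (
                "source_table" if bcaa is not None else "not_compiled"
            )
            items.append(
                FoodItem(
                    item_id=str(row["item_id"]).strip(),
                    names=names,
                    group10=str(row["group10"]).strip(),
                    group18=(str(row.get("group18", "")).strip() or None),
                    protein=_num(row["protein_g"], 0.0),
                    nitrogen_factor=_num(row.get("nitrogen_factor", ""), DEFAULT_NITROGEN_FACTOR),
                    bcaa=bcaa,
                    provenance=provenance,
                    energy_kcal=_num(row.get("energy_kcal_100g", "")),
                    citation=str(row.get("citation", "")).strip(),
                    table_name=str(row.get("table_name", "")).strip(),
                )
            )
        except Exception as exc:
            msg = f"{Path(path).name}:{line}: row rejected ({exc})"
            if strict:
                raise ValidationError(msg) from exc
            warnings.append(msg)
    return items, warnings


FOOD_COLUMNS = (
    "item_id", "name_fr", "name_en", "group10", "group18", "protein_g",
    "nitrogen_factor", "ile_g", "leu_g", "val_g", "provenance",
    "energy_kcal_100g", "citation", "table_name",
)


def food_table_frame(items: list[FoodItem]) -> pd.DataFrame:
    """Food items as a DataFrame in the canonical column order."""
    rows = []
    for it in items:
        rows.append({
            "item_id": it.item_id,
            "name_fr": it.names.get("fr", ""),
            "name_en": it.names.get("en", ""),
            "group10": it.group10,
            "group18": it.group18 or "",
            "protein_g": it.protein,
            "nitrogen_factor": it.nitrogen_factor,
            "ile_g": it.bcaa.isoleucine if it.bcaa else None,
            "leu_g": it.bcaa.leucine if it.bcaa else None,
            "val_g": it.bcaa.valine if it.bcaa else None,
            "provenance": it.provenance,
            "energy_kcal_100g": it.energy_kcal,
            "citation": it.citation,
            "table_name": it.table_name,
        })
    return pd.DataFrame(rows, columns=list(FOOD_COLUMNS))


def write_csv(frame: pd.DataFrame, path, index: bool = False) -> None:
    """Write a DataFrame as deterministic UTF-8 CSV (6-decimal floats).

    The file is written atomically via a temporary sibling so a failed
    write never leaves a partial output behind.
    """
    buf = _io.StringIO()
    frame.to_csv(buf, index=index, float_format="%.6f", lineterminator="\n")
    tmp = f"{path}.tmp"
    with open(tmp, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())
    os.replace(tmp, path)


def write_food_table(items: list[FoodItem], path) -> None:
    write_csv(food_table_frame(items), path)


def read_recipes(path, dialect: str = "standard") -> list[RecipeDef]:
    """Load recipe definitions.

    One row per ingredient; a row whose ``ingredient_id`` is the literal
    ``__yield__`` declares the recipe's yield in its ``grams`` cell.
    """
    df = _read_csv(path, dialect)
    RECIPES_SCHEMA.validate_header(df.columns)
    ingredients: dict[str, list] = {}
    yields: dict[str, float] = {}
    factors: dict[str, dict[str, float]] = {}
    for _, row in df.iterrows():
        rid = str(row["recipe_id"]).strip()
        ing = str(row["ingredient_id"]).strip()
        grams = _num(row["grams"])
        if ing == "__yield__":
            yields[rid] = grams
            continue
        ingredients.setdefault(rid, []).append((ing, str(row["state"]).strip(), grams))
        yf = _num(row.get("yield_factor", ""), None)
        if yf is not None:
            factors.setdefault(rid, {})[ing] = yf
    recipes = []
    for rid, ings in ingredients.items():
        if rid not in yields:
            raise ValidationError(f"recipe {rid!r} has no __yield__ row")
        recipes.append(RecipeDef(rid, ings, yields[rid], factors.get(rid, {})))
    return recipes


def recipes_frame(recipes: list[RecipeDef]) -> pd.DataFrame:
    """Recipes as the one-row-per-ingredient CSV layout (with yield rows)."""
    rows = []
    for r in recipes:
        for iid, state, grams in r.ingredients:
            rows.append({"recipe_id": r.recipe_id, "ingredient_id": iid,
                         "state": state, "grams": grams,
                         "yield_factor": r.yield_factors.get(iid)})
        rows.append({"recipe_id": r.recipe_id, "ingredient_id": "__yield__",
                     "state": "", "grams": r.yield_grams, "yield_factor": None})
    return pd.DataFrame(rows, columns=["recipe_id", "ingredient_id", "state",
                                       "grams", "yield_factor"])


LITERATURE_SCHEMA = TableSchema(
    name="literature",
    required=("item_id", "ile_g", "leu_g", "val_g"),
    optional=("citation",),
    units={"ile_g": "g/100 g", "leu_g": "g/100 g", "val_g": "g/100 g"},
)


def read_literature(path, dialect: str = "standard") -> dict[str, tuple[BCAATriple, str]]:
    df = _read_csv(path, dialect)
    LITERATURE_SCHEMA.validate_header(df.columns)
    return {
        str(r["item_id"]).strip(): (
            BCAATriple(_num(r["ile_g"]), _num(r["leu_g"]), _num(r["val_g"])),
            str(r.get("citation", "")).strip(),
        )
        for _, r in df.iterrows()
    }


def literature_frame(literature: dict[str, tuple[BCAATriple, str]]) -> pd.DataFrame:
    rows = [{"item_id": iid, "ile_g": t.isoleucine, "leu_g": t.leucine,
             "val_g": t.valine, "citation": cite}
            for iid, (t, cite) in literature.items()]
    return pd.DataFrame(rows, columns=["item_id", "ile_g", "leu_g", "val_g", "citation"])


RAW_MAP_SCHEMA = TableSchema(name="raw_map", required=("query_id", "raw_id"))


def read_raw_map(path, dialect: str = "standard") -> dict[str, str]:
    df = _read_csv(path, dialect)
    RAW_MAP_SCHEMA.validate_header(df.columns)
    return {str(r["query_id"]).strip(): str(r["raw_id"]).strip() for _, r in df.iterrows()}


def read_explicit_map(path, dialect: str = "standard") -> dict[str, tuple[str, str]]:
    df = _read_csv(path, dialect)
    MAP_SCHEMA.validate_header(df.columns)
    return {
        str(r["query_id"]).strip(): (str(r["reference_table"]).strip(), str(r["reference_id"]).strip())
        for _, r in df.iterrows()
    }


def read_profiles(path, dialect: str = "standard") -> list[SubjectProfile]:
    df = _read_csv(path, dialect)
    PROFILES_SCHEMA.validate_header(df.columns)
    profiles = []
    for _, row in df.iterrows():
        flag = str(row.get("obesity_flag", "")).strip().lower()
        profiles.append(
            SubjectProfile(
                subject_id=str(row["subject_id"]).strip(),
                age=_num(row["age"]),
                sex=str(row["sex"]).strip(),
                weight=_num(row.get("weight_kg", "")),
                height=_num(row.get("height_cm", "")),
                bmi=_num(row.get("bmi", "")),
                obesity_flag=flag in ("1", "true", "yes", "obese"),
                activity_level=(str(row.get("activity_level", "")).strip() or None),
                energy_kcal=_num(row.get("energy_kcal", "")),
            )
        )
    return profiles


def profiles_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    rows = [{
        "subject_id": p.subject_id,
        "age": p.age,
        "sex": p.sex,
        "weight_kg": p.weight,
        "height_cm": p.height,
        "bmi": p.bmi,
        "obesity_flag": int(p.obesity_flag),
        "activity_level": p.activity_level or "",
        "energy_kcal": p.energy_kcal,
    } for p in profiles]
    return pd.DataFrame(rows, columns=[
        "subject_id", "age", "sex", "weight_kg", "height_cm", "bmi",
        "obesity_flag", "activity_level", "energy_kcal",
    ])


def read_recalls(path, dialect: str = "standard") -> pd.DataFrame:
    df = _read_csv(path, dialect)
    RECALLS_SCHEMA.validate_header(df.columns)
    out = df.copy()
    out["day_index"] = out["day_index"].astype(int)
    out["grams"] = out["grams"].astype(float)
    bad = out[(out["grams"] <= 0) | ~out["meal"].isin(("breakfast", "lunch", "dinner", "snacks"))]
    if len(bad):
        raise ValidationError(f"{len(bad)} invalid recall rows (non-positive grams or bad meal)")
    return out
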