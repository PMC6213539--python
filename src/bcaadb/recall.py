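"""24-h dietary recall records -> per-subject nutrient intakes.

A recall record is one consumed item (subject, day, meal, item, grams).
Intakes are linear in grams: amount = grams/100 x per-100 g composition.
Per-day totals are sums over the day's records; the subject-level value
is the unweighted mean over recorded days.  Food-group aggregation uses
the 18-subgroup level, the resolution at which contribution analyses are
reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from bcaadb.errors import UncompiledItemError, UnknownItemError, ValidationError
from bcaadb.food_model import FoodItem, GROUPS18

MEALS = ("breakfast", "lunch", "dinner", "snacks")

ANALYTES = ("isoleucine", "leucine", "valine", "total_bcaa")


@dataclass(frozen=True)
class RecallRecord:
    """One consumed item in a 24-h recall."""

    subject_id: str
    day_index: int
    meal: str
    item_id: str
    grams: float

    def __post_init__(self) -> None:
        if self.meal not in MEALS:
            raise ValidationError(f"meal must be one of {MEALS}, got {self.meal!r}")
        if self.grams <= 0:
            raise ValidationError(f"grams must be > 0, got {self.grams!r}")
        if not 1 <= self.day_index <= 3:
            raise ValidationError(f"day_index must be 1..3, got {self.day_index!r}")


@dataclass
class IntakeSummary:
    """Per-subject intake: per-day totals and their mean, plus per-group BCAA.

    ``per_day`` maps day_index -> {energy_kcal, protein_g, isoleucine_g,
    leucine_g, valine_g, total_bcaa_g}; ``mean`` holds the unweighted
    mean of those over recorded days.  ``group_bcaa`` maps group18 ->
    mean daily grams per analyte (isoleucine, leucine, valine,
    total_bcaa) and partitions the totals exactly.
    """

    subject_id: str
    per_day: dict[int, dict[str, float]]
    mean: dict[str, float]
    group_bcaa: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def days(self) -> int:
        return len(self.per_day)


def item_intake(record: RecallRecord, item: FoodItem) -> dict[str, float]:
    """Nutrient amounts (g; kcal for energy) contributed by one record."""
    if item.item_id != record.item_id:
        raise UnknownItemError(
            f"record references {record.item_id!r} but item is {item.item_id!r}"
        )
    if item.bcaa is None:
        raise UncompiledItemError(
            f"item {item.item_id!r} has no compiled amino-acid values"
        )
    w = record.grams / 100.0
    return {
        "energy_kcal": w * (item.energy_kcal or 0.0),
        "protein_g": w * item.protein,
        "isoleucine_g": w * item.bcaa.isoleucine,
        "leucine_g": w * item.bcaa.leucine,
        "valine_g": w * item.bcaa.valine,
        "total_bcaa_g": w * item.bcaa.total(),
    }


_NUTRIENTS = ("energy_kcal", "protein_g", "isoleucine_g", "leucine_g", "valine_g", "total_bcaa_g")


def summarize_subject(records: list[RecallRecord], table: list[FoodItem]) -> IntakeSummary:
    """Aggregate one subject's recall records into an intake summary.

    Raises on the first record whose item is unknown or uncompiled —
    silently treating missing amino acids as zero would bias intake
    downward.
    """
    if not records:
        raise ValidationError("no records supplied")
    subject_ids = {r.subject_id for r in records}
    if len(subject_ids) != 1:
        raise ValidationError(f"records span several subjects: {sorted(subject_ids)}")
    by_id = {it.item_id: it for it in table}

    per_day: dict[int, dict[str, float]] = {}
    group: dict[str, dict[str, float]] = {}
    for rec in records:
        item = by_id.get(rec.item_id)
        if item is None:
            raise UnknownItemError(f"unknown item id {rec.item_id!r}")
        amounts = item_intake(rec, item)
        day = per_day.setdefault(rec.day_index, {k: 0.0 for k in _NUTRIENTS})
        for k, v in amounts.items():
            day[k] += v
        g18 = item.group18 or "Mixed Dishes"
        gslot = group.setdefault(g18, {a: 0.0 for a in ANALYTES})
        gslot["isoleucine"] += amounts["isoleucine_g"]
        gslot["leucine"] += amounts["leucine_g"]
        gslot["valine"] += amounts["valine_g"]
        gslot["total_bcaa"] += amounts["total_bcaa_g"]

    n_days = len(per_day)
    mean = {k: sum(d[k] for d in per_day.values()) / n_days for k in _NUTRIENTS}
    group_mean = {
        g: {a: v / n_days for a, v in slot.items()} for g, slot in group.items()
    }
    return IntakeSummary(
        subject_id=next(iter(subject_ids)),
        per_day=dict(sorted(per_day.items())),
        mean=mean,
        group_bcaa=group_mean,
    )


def summarize_survey(recalls: pd.DataFrame, table: list[FoodItem]) -> pd.DataFrame:
    """Vectorized survey-wide intake summary.

    ``recalls`` has columns (subject_id, day_index, meal, item_id,
    grams).  Returns one row per subject: mean daily energy, protein and
    amino-acid intakes plus one ``grp:<group18>:<analyte>`` column per
    food group.  Equivalent to mapping :func:`summarize_subject` over
    subjects, but runs as pandas group-bys for survey-sized inputs.
    """
    required = {"subject_id", "day_index", "meal", "item_id", "grams"}
    missing = required - set(recalls.columns)
    if missing:
        raise ValidationError(f"recalls missing columns: {sorted(missing)}")
    comp = pd.DataFrame(
        {
            "item_id": [it.item_id for it in table],
            "group18": [it.group18 or "Mixed Dishes" for it in table],
            "energy_kcal": [it.energy_kcal or 0.0 for it in table],
            "protein_g": [it.protein for it in table],
            "isoleucine_g": [it.bcaa.isoleucine if it.bcaa else float("nan") for it in table],
            "leucine_g": [it.bcaa.leucine if it.bcaa else float("nan") for it in table],
            "valine_g": [it.bcaa.valine if it.bcaa else float("nan") for it in table],
        }
    )
    unknown = set(recalls["item_id"]) - set(comp["item_id"])
    if unknown:
        raise UnknownItemError(f"unknown item ids: {sorted(unknown)[:5]}")
    uncompiled = {
        it.item_id for it in table if it.bcaa is None
    } & set(recalls["item_id"])
    if uncompiled:
        raise UncompiledItemError(f"records reference uncompiled items: {sorted(uncompiled)[:5]}")

    df = recalls.merge(comp, on="item_id", how="left")
    w = df["grams"] / 100.0
    for col in ("energy_kcal", "protein_g", "isoleucine_g", "leucine_g", "valine_g"):
        df[col] = w * df[col]
    df["total_bcaa_g"] = df["isoleucine_g"] + df["leucine_g"] + df["valine_g"]

    day = df.groupby(["subject_id", "day_index"])[list(_NUTRIENTS)].sum()
    mean = day.groupby("subject_id").mean()

    n_days = day.groupby("subject_id").size()
    gday = (
        df.groupby(["subject_id", "group18"])[
            ["isoleucine_g", "leucine_g", "valine_g", "total_bcaa_g"]
        ]
        .sum()
        .div(n_days, axis=0, level="subject_id")
    )
    gwide = gday.unstack("group18", fill_value=0.0)
    gwide.columns = [f"grp:{g}:{a.removesuffix('_g')}" for a, g in gwide.columns]
    out = mean.join(gwide).fillna(0.0)
    out.index.name = "subject_id"
    return out.sort_index()


def group_columns(intakes: pd.DataFrame, analyte: str = "total_bcaa") -> pd.DataFrame:
    """Extract the per-group columns of one analyte from a survey summary.

    Returns a subject x group18 DataFrame (groups without any intake are
    filled with 0).
    """
    prefix = "grp:"
    suffix = f":{analyte}"
    cols = {
        c[len(prefix):-len(suffix)]: c
        for c in intakes.columns
        if c.startswith(prefix) and c.endswith(suffix)
    }
    out = pd.DataFrame(
        {g: intakes[cols[g]] if g in cols else 0.0 for g in GROUPS18},
        index=intakes.index,
    )
    return out
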