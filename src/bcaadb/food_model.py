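"""Domain types shared by the compiler and the survey pipeline.

All compositions are expressed per 100 g of edible portion.  Total BCAA
is always the sum isoleucine + leucine + valine and is never stored as a
separate field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from bcaadb.errors import InvalidFactorError, ValidationError

#: Default nitrogen-to-protein conversion factor (crude protein, N x 6.25).
DEFAULT_NITROGEN_FACTOR = 6.25

#: The ten top-level food groups, in canonical order.
GROUPS10 = (
    "Dairy products and cheese",
    "Vegetables, fruits",
    "Cereals and pasta",
    "Meat, poultry, and fish",
    "Sugars and confectioneries",
    "Fats and oils",
    "Beverages",
    "Sauces and condiments",
    "Mixed dishes and soups",
    "Items for particular nutritional uses",
)

#: The eighteen analysis subgroups, in canonical order.
GROUPS18 = (
    "Offal",
    "Red meat and poultry",
    "Luncheon meats",
    "Fish and seafood",
    "Milk and dairy products",
    "Cheese",
    "Eggs and related products",
    "Bread, Pasta, cereals",
    "Pastries and brioches",
    "Cakes",
    "Fruits and vegetables",
    "Legumes",
    "Nuts and Seeds",
    "Mixed Dishes",
    "Fats and oil",
    "Sugar and confectionery",
    "Drinks",
    "Herbs, spices and condiments",
)

#: Valid provenance labels for a food item's amino-acid values.
PROVENANCES = (
    "method1",
    "method2",
    "method3",
    "method4",
    "method5",
    "not_compiled",
    "source_table",
)


@dataclass(frozen=True)
class BCAATriple:
    """Isoleucine, leucine and valine in g per 100 g edible portion."""

    isoleucine: float
    leucine: float
    valine: float

    def __post_init__(self) -> None:
        for name in ("isoleucine", "leucine", "valine"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(f"{name} must be finite and >= 0, got {v!r}")

    def total(self) -> float:
        """Total BCAA, the sum of the three components (g/100 g)."""
        return self.isoleucine + self.leucine + self.valine

    def scale(self, a: float) -> "BCAATriple":
        """Component-wise scaling by a nonnegative factor."""
        return BCAATriple(self.isoleucine * a, self.leucine * a, self.valine * a)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.isoleucine, self.leucine, self.valine)


ZERO_TRIPLE = BCAATriple(0.0, 0.0, 0.0)


def total_bcaa(t: BCAATriple) -> float:
    """Total BCAA of a triple: isoleucine + leucine + valine (g/100 g)."""
    return t.total()


def nitrogen_from_protein(protein: float, factor: float = DEFAULT_NITROGEN_FACTOR) -> float:
    """Nitrogen content (g N / 100 g) from protein and a conversion factor.

    Protein tables report crude or specific protein; nitrogen is recovered
    by dividing by the nitrogen-to-protein conversion factor (6.25 for
    crude protein, food-specific values such as 6.38 for milk otherwise).

    Parameters
    ----------
    protein:
        Protein in g per 100 g edible portion, >= 0.
    factor:
        Dimensionless nitrogen-to-protein conversion factor, > 0.
    """
    if factor <= 0 or not math.isfinite(factor):
        raise InvalidFactorError(f"nitrogen factor must be > 0, got {factor!r}")
    if protein < 0:
        raise ValidationError(f"protein must be >= 0, got {protein!r}")
    return protein / factor


@dataclass
class FoodItem:
    """One row of a food-composition table.

    Parameters
    ----------
    item_id:
        Opaque identifier, unique within its table.
    names:
        Language code -> display name; at least one entry.
    group10:
        One of :data:`GROUPS10`.
    group18:
        Optional subgroup from :data:`GROUPS18`.
    protein:
        g protein per 100 g edible portion.
    nitrogen_factor:
        Nitrogen-to-protein conversion factor (default 6.25).
    bcaa:
        Compiled amino-acid values, or ``None`` when not (yet) compiled.
    provenance:
        How the amino-acid values were obtained (one of
        :data:`PROVENANCES`).
    energy_kcal:
        Optional energy density, kcal per 100 g (used by the recall
        pipeline for misreporter exclusion).
    citation:
        Literature citation for ``method2`` items.
    """

    item_id: str
    names: dict[str, str]
    group10: str
    protein: float
    group18: str | None = None
    nitrogen_factor: float = DEFAULT_NITROGEN_FACTOR
    bcaa: BCAATriple | None = None
    provenance: str = "not_compiled"
    energy_kcal: float | None = None
    citation: str = ""
    table_name: str = ""

    def __post_init__(self) -> None:
        if not self.names:
            raise ValidationError(f"item {self.item_id!r} needs at least one name")
        if self.group10 not in GROUPS10:
            raise ValidationError(f"unknown group10 {self.group10!r} for item {self.item_id!r}")
        if self.group18 is not None and self.group18 not in GROUPS18:
            raise ValidationError(f"unknown group18 {self.group18!r} for item {self.item_id!r}")
        if self.protein < 0 or not math.isfinite(self.protein):
            raise ValidationError(f"protein must be >= 0 for item {self.item_id!r}")
        if self.nitrogen_factor <= 0:
            raise InvalidFactorError(f"nitrogen factor must be > 0 for item {self.item_id!r}")
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if self.provenance == "method5":
            if self.bcaa is None or self.bcaa.total() != 0:
                raise ValidationError(
                    f"method5 item {self.item_id!r} must carry an all-zero triple"
                )
        if self.provenance == "not_compiled" and self.bcaa is not None:
            raise ValidationError(
                f"not_compiled item {self.item_id!r} must not carry amino-acid values"
            )

    @property
    def nitrogen(self) -> float:
        """g N per 100 g, protein / nitrogen_factor."""
        return nitrogen_from_protein(self.protein, self.nitrogen_factor)

    def name(self, language: str = "en") -> str:
        """Display name in ``language``, falling back to any available one."""
        if language in self.names:
            return self.names[language]
        return next(iter(self.names.values()))

    @property
    def compiled(self) -> bool:
        return self.bcaa is not None


@dataclass(frozen=True)
class Portion:
    """A named serving size in grams."""

    portion_id: str
    label: str
    grams: float

    def __post_init__(self) -> None:
        if self.grams <= 0:
            raise ValidationError(f"portion {self.portion_id!r} grams must be > 0")


@dataclass
class FoodGroupTaxonomy:
    """The two-level food-group taxonomy (10 groups, 18 subgroups).

    ``mapping`` optionally overrides the subgroup of individual items
    (item_id -> group18); the 10 -> 18 breakdown is not a function (e.g.
    the meat/poultry/fish group splits into four subgroups), so subgroup
    membership is always explicit, never inferred.
    """

    groups10: tuple[str, ...] = GROUPS10
    groups18: tuple[str, ...] = GROUPS18
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.groups10) != 10:
            raise ValidationError("taxonomy requires exactly 10 top-level groups")
        if len(self.groups18) != 18:
            raise ValidationError("taxonomy requires exactly 18 subgroups")
        for g in self.mapping.values():
            if g not in self.groups18:
                raise ValidationError(f"mapping targets unknown subgroup {g!r}")

    def group18_of(self, item: FoodItem) -> str | None:
        """Subgroup for an item: explicit override first, then the item's own."""
        return self.mapping.get(item.item_id, item.group18)
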