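"""Five-method compilation of BCAA values into a target food table.

A target table (CIQUAL-like: protein but no amino acids) is filled by a
provenance-tracked cascade:

1. transfer from a reference table (USDA/Danish/Canadian-like), with the
   amino acids adjusted by the ratio of nitrogen contents;
2. published chromatographic measurements, stored verbatim with their
   citation;
3. similarity transfer from the raw counterpart of a cooked item (same
   nitrogen adjustment; amino-acid ratios are preserved);
4. recipe calculation for mixed dishes, summing ingredient contributions
   per 100 g of finished dish with raw->cooked yield substitution;
5. zero assignment for protein-free items.

The first method that succeeds wins; items that no method can reach are
labelled ``not_compiled``.  Every decision is recorded so the resulting
table is fully auditable, and a method-by-group report mirrors the
compilation summary a database curator would publish.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from difflib import SequenceMatcher

import pandas as pd

from bcaadb.errors import (
    DivisionUndefinedError,
    MissingReferenceValuesError,
    NotEligibleError,
    ToleranceViolationError,
    UnresolvedIngredientError,
    ValidationError,
)
from bcaadb.food_model import (
    BCAATriple,
    DEFAULT_NITROGEN_FACTOR,
    FoodItem,
    GROUPS10,
    ZERO_TRIPLE,
    nitrogen_from_protein,
)

logger = logging.getLogger(__name__)

#: Protein tolerance (g/100 g) within which a reference food is accepted.
PROTEIN_TOLERANCE = 5.0

#: Minimum name-similarity score for a proposed (non-explicit) match.
NAME_SIMILARITY_THRESHOLD = 0.85

#: Protein (g/100 g) at or below which an item counts as protein-free.
PROTEIN_FREE_EPSILON = 0.1

METHODS = ("method1", "method2", "method3", "method4", "method5")


@dataclass(frozen=True)
class ReferenceMatch:
    """A resolved query -> reference pairing."""

    query_id: str
    reference_id: str
    reference_table: str
    protein_delta: float
    match_source: str  # "explicit_map" | "name_similarity"


@dataclass
class RecipeDef:
    """A mixed-dish recipe: ingredients with state and grams, plus yield.

    ``ingredients`` holds ``(item_id, state, grams)`` with state ``raw``
    or ``cooked``; ``yield_factors`` maps item_id -> cooked/raw weight
    ratio applied when a raw ingredient is substituted by its cooked
    equivalent (default 1, no weight change).
    """

    recipe_id: str
    ingredients: list[tuple[str, str, float]]
    yield_grams: float
    yield_factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.yield_grams <= 0:
            raise ValidationError(f"recipe {self.recipe_id!r}: yield_grams must be > 0")
        for item_id, state, grams in self.ingredients:
            if state not in ("raw", "cooked"):
                raise ValidationError(f"recipe {self.recipe_id!r}: bad state {state!r}")
            if grams <= 0:
                raise ValidationError(f"recipe {self.recipe_id!r}: grams must be > 0 for {item_id!r}")

    def effective_grams(self, item_id: str, state: str, grams: float) -> float:
        """Cooked-equivalent grams of one ingredient line.

        Raw ingredients are substituted by their cooked equivalent, so
        their weight is multiplied by the cooked/raw yield factor.
        """
        if state == "raw":
            return grams * self.yield_factors.get(item_id, 1.0)
        return grams


@dataclass
class CompilationReport:
    """Method-by-food-group tally of a compilation run.

    ``counts`` is a DataFrame indexed by group10 with one column per
    method plus ``not_compiled``; every target item is counted exactly
    once.  ``method2_missing_citation`` lists literature-sourced items
    whose citation is empty (audit aid).
    """

    counts: pd.DataFrame
    method2_missing_citation: list[str] = field(default_factory=list)

    COLUMNS = (*METHODS, "not_compiled")

    @classmethod
    def from_items(cls, items: list[FoodItem]) -> "CompilationReport":
        counts = pd.DataFrame(0, index=list(GROUPS10), columns=list(cls.COLUMNS))
        missing = []
        for it in items:
            col = it.provenance if it.provenance in cls.COLUMNS else "not_compiled"
            counts.loc[it.group10, col] += 1
            if it.provenance == "method2" and not it.citation:
                missing.append(it.item_id)
        return cls(counts=counts, method2_missing_citation=sorted(missing))

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "CompilationReport":
        counts = counts.reindex(columns=list(cls.COLUMNS), fill_value=0)
        return cls(counts=counts)

    @property
    def total_items(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def total_compiled(self) -> int:
        return int(self.counts[list(METHODS)].to_numpy().sum())

    def method_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


# ----------------------------------------------------------------- arithmetic


def adjust_by_nitrogen(bcaa_ref: BCAATriple, n_query: float, n_ref: float) -> BCAATriple:
    """Adjust reference amino acids for the nitrogen difference.

    Implements the transfer rule: value of the food in question equals
    the reference value times N(query)/N(reference).  A query without
    nitrogen has no protein, hence a zero triple regardless of the
    reference.

    Raises
    ------
    DivisionUndefinedError
        When the reference has amino acids but no nitrogen — such a
        reference row is internally inconsistent.
    """
    if n_query < 0:
        raise ValidationError(f"query nitrogen must be >= 0, got {n_query!r}")
    if n_query == 0:
        return ZERO_TRIPLE
    if n_ref <= 0:
        if bcaa_ref.total() == 0:
            return ZERO_TRIPLE
        raise DivisionUndefinedError(
            "reference has amino acids but zero nitrogen; adjustment ratio undefined"
        )
    return bcaa_ref.scale(n_query / n_ref)


_token_re = re.compile(r"[^a-z0-9]+")


def _tokens(name: str) -> str:
    """Normalized, sorted token string for similarity scoring."""
    return " ".join(sorted(t for t in _token_re.split(name.lower()) if t))


def name_similarity(a: str, b: str) -> float:
    """Token-set similarity in [0, 1]: SequenceMatcher ratio on sorted tokens."""
    return SequenceMatcher(None, _tokens(a), _tokens(b)).ratio()


def match_reference(
    query: FoodItem,
    references: list[FoodItem],
    tolerance: float = PROTEIN_TOLERANCE,
    explicit_map: dict[str, tuple[str, str]] | None = None,
    similarity_threshold: float = NAME_SIMILARITY_THRESHOLD,
    language: str = "en",
) -> ReferenceMatch | None:
    """Find the reference food for a query item.

    An explicit mapping (query_id -> (table_name, reference_id)) is
    authoritative but still checked against the protein tolerance.
    Otherwise candidates whose name similarity reaches the threshold are
    ranked by |protein difference| (ties broken by reference_id), and the
    best one within tolerance is returned; ``None`` if no candidate
    qualifies.

    Raises
    ------
    ToleranceViolationError
        When the explicit mapping points at a reference whose protein
        differs by more than ``tolerance`` — the map entry is wrong or
        the tolerance must be overridden deliberately.
    """
    if not references:
        return None
    by_key = {(r.table_name, r.item_id): r for r in references}
    if explicit_map and query.item_id in explicit_map:
        table_name, ref_id = explicit_map[query.item_id]
        ref = by_key.get((table_name, ref_id))
        if ref is None:
            return None
        delta = query.protein - ref.protein
        if abs(delta) > tolerance:
            raise ToleranceViolationError(
                f"explicit map {query.item_id!r} -> {ref_id!r}: protein delta "
                f"{delta:+.2f} g exceeds tolerance {tolerance} g"
            )
        return ReferenceMatch(query.item_id, ref.item_id, ref.table_name, delta, "explicit_map")

    candidates = []
    qname = query.name(language)
    for ref in references:
        score = name_similarity(qname, ref.name(language))
        if score < similarity_threshold:
            continue
        delta = query.protein - ref.protein
        if abs(delta) > tolerance:
            continue
        candidates.append((abs(delta), ref.item_id, delta, ref))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, _, delta, best = candidates[0]
    return ReferenceMatch(query.item_id, best.item_id, best.table_name, delta, "name_similarity")


# -------------------------------------------------------------- five methods


def _transfer(query: FoodItem, reference: FoodItem, provenance: str) -> FoodItem:
    if reference.bcaa is None:
        raise MissingReferenceValuesError(
            f"reference {reference.item_id!r} carries no amino-acid values"
        )
    n_query = nitrogen_from_protein(query.protein, DEFAULT_NITROGEN_FACTOR)
    n_ref = reference.nitrogen
    bcaa = adjust_by_nitrogen(reference.bcaa, n_query, n_ref)
    out = FoodItem(**{**query.__dict__, "bcaa": bcaa, "provenance": provenance})
    return out


def compile_method1(query: FoodItem, match: ReferenceMatch, reference: FoodItem) -> FoodItem:
    """Method 1: transfer from another food-composition table.

    The query's nitrogen uses the crude-protein factor 6.25; the
    reference's nitrogen uses its own table-specific factor.
    """
    logger.debug(
        "method1: %s <- %s/%s (delta %.2f g, %s)",
        query.item_id, match.reference_table, match.reference_id,
        match.protein_delta, match.match_source,
    )
    return _transfer(query, reference, "method1")


def compile_method2(query: FoodItem, literature_value: BCAATriple, citation: str = "") -> FoodItem:
    """Method 2: published chromatographic (HPLC/GC) measurement, verbatim."""
    logger.debug("method2: %s from literature (%s)", query.item_id, citation or "no citation")
    return FoodItem(
        **{**query.__dict__, "bcaa": literature_value, "provenance": "method2", "citation": citation}
    )


def compile_method3_cooked(query_cooked: FoodItem, reference_raw: FoodItem) -> FoodItem:
    """Method 3: cooked item from its raw counterpart.

    Cooking is assumed not to change the isoleucine:leucine:valine ratio;
    all change is expressed through the nitrogen ratio, so the arithmetic
    is that of method 1 with the raw item as reference.
    """
    logger.debug("method3: %s <- raw %s", query_cooked.item_id, reference_raw.item_id)
    return _transfer(query_cooked, reference_raw, "method3")


def compile_method4_recipe(recipe: RecipeDef, table: list[FoodItem]) -> FoodItem:
    """Method 4: mixed dish from its recipe.

    Raw ingredients are substituted by cooked equivalents (grams scaled
    by the yield factor); each ingredient contributes its per-100 g
    composition weighted by effective grams / yield grams, and the dish's
    protein and energy follow the same rule.  A deviation of total
    effective grams from the declared yield beyond 20% is logged as a
    warning (evaporation/absorption beyond what the yield factors encode).
    """
    by_id = {it.item_id: it for it in table}
    ile = leu = val = protein = 0.0
    energy = 0.0
    have_energy = True
    eff_total = 0.0
    for item_id, state, grams in recipe.ingredients:
        ing = by_id.get(item_id)
        if ing is None or ing.bcaa is None:
            raise UnresolvedIngredientError(
                f"recipe {recipe.recipe_id!r}: ingredient {item_id!r} missing or not compiled"
            )
        eff = recipe.effective_grams(item_id, state, grams)
        eff_total += eff
        w = eff / recipe.yield_grams
        ile += w * ing.bcaa.isoleucine
        leu += w * ing.bcaa.leucine
        val += w * ing.bcaa.valine
        protein += w * ing.protein
        if ing.energy_kcal is None:
            have_energy = False
        else:
            energy += w * ing.energy_kcal
    if abs(eff_total - recipe.yield_grams) > 0.2 * recipe.yield_grams:
        logger.warning(
            "recipe %s: effective grams %.1f deviate >20%% from yield %.1f",
            recipe.recipe_id, eff_total, recipe.yield_grams,
        )
    first = by_id[recipe.ingredients[0][0]]
    return FoodItem(
        item_id=recipe.recipe_id,
        names={"en": recipe.recipe_id},
        group10="Mixed dishes and soups",
        group18="Mixed Dishes",
        protein=protein,
        nitrogen_factor=DEFAULT_NITROGEN_FACTOR,
        bcaa=BCAATriple(ile, leu, val),
        provenance="method4",
        energy_kcal=energy if have_energy else None,
        table_name=first.table_name,
    )


def compile_method5_zero(query: FoodItem, epsilon: float = PROTEIN_FREE_EPSILON) -> FoodItem:
    """Method 5: zero content for protein-free items.

    Eligibility requires protein at or below ``epsilon`` g/100 g
    (protein tables rarely print an exact zero).
    """
    if query.protein > epsilon:
        raise NotEligibleError(
            f"item {query.item_id!r} has protein {query.protein} g > epsilon {epsilon} g; "
            "use methods 1-4"
        )
    logger.debug("method5: %s assumed zero content", query.item_id)
    return FoodItem(**{**query.__dict__, "bcaa": ZERO_TRIPLE, "provenance": "method5"})


# ------------------------------------------------------------------- cascade


@dataclass
class CompilerConfig:
    """Knobs of the compilation cascade."""

    tolerance: float = PROTEIN_TOLERANCE
    similarity_threshold: float = NAME_SIMILARITY_THRESHOLD
    protein_free_epsilon: float = PROTEIN_FREE_EPSILON
    language: str = "en"


def compile_table(
    target: list[FoodItem],
    references: list[FoodItem] | None = None,
    recipes: list[RecipeDef] | None = None,
    literature: dict[str, tuple[BCAATriple, str]] | None = None,
    explicit_map: dict[str, tuple[str, str]] | None = None,
    raw_map: dict[str, str] | None = None,
    method_override: dict[str, str] | None = None,
    config: CompilerConfig | None = None,
) -> tuple[list[FoodItem], CompilationReport]:
    """Run the five-method cascade over a target table.

    Each target item lacking amino-acid values is attempted with methods
    1 through 5 in order; the first success wins and sets the item's
    provenance.  ``raw_map`` names the raw counterpart (in the target or
    the references) of a cooked item for method 3; ``method_override``
    pins an item to one method, mirroring a curator's manual decision.
    Per-item failures are recorded, never fatal.

    Returns the compiled table (same order as the input) and the
    method-by-group report.
    """
    references = references or []
    recipes_by_id = {r.recipe_id: r for r in recipes or []}
    literature = literature or {}
    raw_map = raw_map or {}
    method_override = method_override or {}
    cfg = config or CompilerConfig()

    compiled: list[FoodItem] = []
    by_id: dict[str, FoodItem] = {}
    ref_by_id = {r.item_id: r for r in references}

    def try_method1(item: FoodItem) -> FoodItem | None:
        match = match_reference(
            item, references, cfg.tolerance, explicit_map, cfg.similarity_threshold, cfg.language
        )
        if match is None:
            return None
        return compile_method1(item, match, ref_by_id[match.reference_id])

    def try_method2(item: FoodItem) -> FoodItem | None:
        if item.item_id not in literature:
            return None
        value, citation = literature[item.item_id]
        return compile_method2(item, value, citation)

    def try_method3(item: FoodItem) -> FoodItem | None:
        raw_id = raw_map.get(item.item_id)
        if raw_id is None:
            return None
        raw = by_id.get(raw_id) or ref_by_id.get(raw_id)
        if raw is None or raw.bcaa is None:
            return None
        return compile_method3_cooked(item, raw)

    def try_method4(item: FoodItem) -> FoodItem | None:
        recipe = recipes_by_id.get(item.item_id)
        if recipe is None:
            return None
        dish = compile_method4_recipe(recipe, compiled + references)
        # keep the target row's identity and grouping; take the computed values
        return FoodItem(
            **{
                **item.__dict__,
                "protein": dish.protein,
                "bcaa": dish.bcaa,
                "provenance": "method4",
                "energy_kcal": item.energy_kcal if item.energy_kcal is not None else dish.energy_kcal,
            }
        )

    def try_method5(item: FoodItem) -> FoodItem | None:
        if item.protein > cfg.protein_free_epsilon:
            return None
        return compile_method5_zero(item, cfg.protein_free_epsilon)

    attempts = {
        "method1": try_method1,
        "method2": try_method2,
        "method3": try_method3,
        "method4": try_method4,
        "method5": try_method5,
    }

    for item in target:
        if item.bcaa is not None:  # already valued in the source table
            result = item
        else:
            order = [method_override[item.item_id]] if item.item_id in method_override else list(METHODS)
            result = None
            for method in order:
                try:
                    result = attempts[method](item)
                except (ToleranceViolationError, MissingReferenceValuesError,
                        UnresolvedIngredientError, NotEligibleError, DivisionUndefinedError) as exc:
                    logger.debug("%s failed for %s: %s", method, item.item_id, exc)
                    result = None
                if result is not None:
                    break
            if result is None:
                logger.debug("not compiled: %s", item.item_id)
                result = item  # provenance stays not_compiled
        compiled.append(result)
        by_id[result.item_id] = result

    return compiled, CompilationReport.from_items(compiled)


def report_summary(report: CompilationReport) -> dict:
    """Totals and whole-percent method shares of a compilation report.

    Shares are 100 x method count / total compiled, rounded to the
    nearest integer percent; an empty report yields an empty summary.
    """
    if report.total_items == 0:
        return {}
    method_totals = report.method_totals()
    total_compiled = report.total_compiled
    shares = {
        m: int(round(100.0 * method_totals[m] / total_compiled)) if total_compiled else math.nan
        for m in METHODS
    }
    return {
        "total_items": report.total_items,
        "total_compiled": total_compiled,
        "not_compiled": int(method_totals["not_compiled"]),
        "method_totals": {m: int(method_totals[m]) for m in METHODS},
        "method_share_pct": shares,
        "group_totals": {g: int(v) for g, v in report.group_totals().items()},
        "method2_missing_citation": list(report.method2_missing_citation),
    }
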