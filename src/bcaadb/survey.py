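"""Survey analysis chain for BCAA intake epidemiology.

Covers, in pipeline order: basal metabolic rate (Harris–Benedict),
GPAQ physical-activity scoring, exclusion of energy-intake misreporters,
stratification of food items into six BCAA-content categories,
quartile assignment of intakes, logistic obesity-association models
with age and energy adjustment, and food-group contribution shares
(Block-style attribution of the population's intake to food groups).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from bcaadb.errors import (
    DegenerateBreaksError,
    DegenerateOutcomeError,
    SeparationError,
    UndefinedContributionError,
    ValidationError,
)
from bcaadb.food_model import FoodItem, GROUPS18

# --------------------------------------------------------------- subjects


@dataclass
class SubjectProfile:
    """Anthropometric and survey metadata for one subject.

    ``obesity_flag`` is accepted as an input (adults: BMI >= 30 kg/m2;
    minors: growth-chart weight class precomputed upstream).
    ``activity_level`` is one of low/moderate/intense, or ``None`` when
    the physical-activity questionnaire is missing.
    """

    subject_id: str
    age: float
    sex: str
    weight: float | None = None
    height: float | None = None
    bmi: float | None = None
    obesity_flag: bool = False
    activity_level: str | None = None
    energy_kcal: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValidationError(f"age must be > 0 for {self.subject_id!r}")
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be male/female, got {self.sex!r}")
        if self.bmi is not None and self.bmi <= 0:
            raise ValidationError(f"bmi must be > 0 for {self.subject_id!r}")
        if self.activity_level is not None and self.activity_level not in ("low", "moderate", "intense"):
            raise ValidationError(f"bad activity level {self.activity_level!r}")


# ------------------------------------------------------------------ BMR


def harris_benedict_bmr(sex: str, weight: float, height: float, age: float) -> float:
    """Basal metabolic rate (kcal/day), original Harris–Benedict equations.

    men:   66.473 + 13.7516 W + 5.0033 H − 6.7550 A
    women: 655.0955 + 9.5634 W + 1.8496 H − 4.6756 A

    with W in kg, H in cm, A in years.
    """
    if weight <= 0 or height <= 0 or age <= 0:
        raise ValidationError("weight, height and age must all be > 0")
    if sex == "male":
        return 66.473 + 13.7516 * weight + 5.0033 * height - 6.7550 * age
    if sex == "female":
        return 655.0955 + 9.5634 * weight + 1.8496 * height - 4.6756 * age
    raise ValidationError(f"sex must be male/female, got {sex!r}")


# ----------------------------------------------------------------- GPAQ

#: MET weights per GPAQ domain (WHO analysis guide).
MET_WEIGHTS = {
    "work_vigorous": 8.0,
    "work_moderate": 4.0,
    "transport": 4.0,
    "leisure_vigorous": 8.0,
    "leisure_moderate": 4.0,
}


@dataclass(frozen=True)
class GPAQAnswers:
    """Numeric core of the 16-item GPAQ questionnaire.

    Each activity domain is (days per week, minutes per typical day);
    the questionnaire's yes/no gating questions are implied by zero
    days.  ``sedentary_minutes`` is recorded but does not enter the
    MET score.
    """

    work_vigorous: tuple[int, float] = (0, 0.0)
    work_moderate: tuple[int, float] = (0, 0.0)
    transport: tuple[int, float] = (0, 0.0)
    leisure_vigorous: tuple[int, float] = (0, 0.0)
    leisure_moderate: tuple[int, float] = (0, 0.0)
    sedentary_minutes: float = 0.0

    def __post_init__(self) -> None:
        for domain in MET_WEIGHTS:
            days, minutes = getattr(self, domain)
            if not 0 <= days <= 7:
                raise ValidationError(f"{domain}: days/week must be 0..7, got {days}")
            if minutes < 0:
                raise ValidationError(f"{domain}: minutes/day must be >= 0")


def gpaq_met_minutes(answers: GPAQAnswers) -> tuple[float, str]:
    """Weekly MET-minutes and WHO activity level from GPAQ answers.

    MET-min/week = sum over domains of days x minutes x MET weight.
    Level: *high* if vigorous activity on >= 3 days with >= 1500
    MET-min/week, or any activity on >= 7 days with >= 3000 MET-min/week;
    *moderate* if >= 600 MET-min/week; else *low*.
    """
    met = 0.0
    total_days = 0
    vig_days = 0
    for domain, weight in MET_WEIGHTS.items():
        days, minutes = getattr(answers, domain)
        met += days * minutes * weight
        total_days += days
        if domain.endswith("vigorous"):
            vig_days += days
    if (vig_days >= 3 and met >= 1500) or (total_days >= 7 and met >= 3000):
        level = "high"
    elif met >= 600:
        level = "moderate"
    else:
        level = "low"
    return met, level


# ------------------------------------------------------- misreporters

#: Physical-activity-level anchors used by the Goldberg-style screen.
PAL_BY_ACTIVITY = {"low": 1.4, "moderate": 1.7, "intense": 2.0}


@dataclass
class ExclusionConfig:
    """Bounds of the misreporter screen.

    With missing activity data, subjects whose mean energy intake is
    strictly above ``energy_high`` or strictly below ``energy_low`` kcal
    are excluded.  With activity data present, the ratio of energy
    intake to Harris–Benedict BMR is compared against the subject's PAL
    anchor scaled by (``ratio_low``, ``ratio_high``).
    """

    energy_low: float = 1000.0
    energy_high: float = 4000.0
    ratio_low: float = 0.6
    ratio_high: float = 1.4


def exclude_misreporters(
    profiles: list[SubjectProfile],
    intakes: pd.DataFrame,
    config: ExclusionConfig | None = None,
) -> tuple[list[SubjectProfile], dict[str, str]]:
    """Screen out implausible energy reporters.

    ``intakes`` is a survey summary with an ``energy_kcal`` column
    indexed by subject_id (a profile's own ``energy_kcal`` is used as a
    fallback).  Returns the kept profiles and a subject_id -> reason map
    for the excluded; kept and excluded partition the input.
    """
    cfg = config or ExclusionConfig()
    kept: list[SubjectProfile] = []
    excluded: dict[str, str] = {}
    for p in profiles:
        if p.subject_id in intakes.index:
            energy = float(intakes.loc[p.subject_id, "energy_kcal"])
        elif p.energy_kcal is not None:
            energy = p.energy_kcal
        else:
            excluded[p.subject_id] = "no energy intake available"
            continue
        if p.activity_level is None or p.weight is None or p.height is None:
            if energy > cfg.energy_high:
                excluded[p.subject_id] = f"over-reporter: {energy:.0f} kcal > {cfg.energy_high:.0f}"
            elif energy < cfg.energy_low:
                excluded[p.subject_id] = f"under-reporter: {energy:.0f} kcal < {cfg.energy_low:.0f}"
            else:
                kept.append(p)
        else:
            bmr = harris_benedict_bmr(p.sex, p.weight, p.height, p.age)
            pal = PAL_BY_ACTIVITY[p.activity_level]
            ratio = energy / bmr
            if ratio < cfg.ratio_low * pal:
                excluded[p.subject_id] = f"under-reporter: EI/BMR {ratio:.2f} < {cfg.ratio_low * pal:.2f}"
            elif ratio > cfg.ratio_high * pal:
                excluded[p.subject_id] = f"over-reporter: EI/BMR {ratio:.2f} > {cfg.ratio_high * pal:.2f}"
            else:
                kept.append(p)
    return kept, excluded


# ------------------------------------------------- content categories

CATEGORY_LABELS = ("A", "B", "C", "D", "E", "F")

#: Published break points (g/100 g) separating categories B..F.
DEFAULT_BREAKS = (0.232, 1.083, 2.658, 4.168)


@dataclass(frozen=True)
class CategoryBreaks:
    """Thresholds separating the six BCAA-content categories.

    Category A is reserved for exactly zero content; B..E are the bins
    with upper bounds at the four thresholds (inclusive) and F is
    everything above the last threshold.
    """

    thresholds: tuple[float, ...] = DEFAULT_BREAKS

    def __post_init__(self) -> None:
        t = self.thresholds
        if len(t) != 4 or any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("breaks must be 4 strictly increasing thresholds")

    def category(self, total: float) -> str:
        """Category of one total-BCAA value (g/100 g)."""
        if total < 0:
            raise ValidationError("total BCAA must be >= 0")
        if total == 0:
            return "A"
        for label, upper in zip("BCDE", self.thresholds):
            if total <= upper:
                return label
        return "F"


def categorize_items(
    table: list[FoodItem], breaks: CategoryBreaks | None = None
) -> tuple[pd.Series, pd.DataFrame]:
    """Stratify compiled items into content categories A–F.

    Returns the per-item category (indexed by item_id) and the
    composition matrix: percent of each category's items per food
    subgroup (columns are categories and sum to 100 where non-empty).
    """
    breaks = breaks or CategoryBreaks()
    uncompiled = [it.item_id for it in table if it.bcaa is None]
    if uncompiled:
        raise ValidationError(f"uncompiled items cannot be categorized: {uncompiled[:5]}")
    cats = pd.Series(
        {it.item_id: breaks.category(it.bcaa.total()) for it in table}, name="category"
    )
    comp = pd.DataFrame(0.0, index=list(GROUPS18), columns=list(CATEGORY_LABELS))
    for it in table:
        g18 = it.group18 or "Mixed Dishes"
        comp.loc[g18, cats[it.item_id]] += 1
    col_sums = comp.sum(axis=0)
    comp = comp.div(col_sums.where(col_sums > 0, 1.0), axis=1) * 100.0
    return cats, comp


def compute_breaks(values: list[float] | np.ndarray, n_bins: int = 5) -> CategoryBreaks:
    """Equal-probability breaks from observed total-BCAA contents.

    Zero values are set aside (they form category A); the thresholds are
    the ``n_bins``-quantiles of the nonzero values (linear interpolation
    between order statistics), rounded to 3 decimals.
    """
    arr = np.asarray(values, dtype=float)
    nonzero = arr[arr > 0]
    if len(np.unique(nonzero)) < n_bins:
        raise DegenerateBreaksError(
            f"need >= {n_bins} distinct nonzero values, got {len(np.unique(nonzero))}"
        )
    qs = np.arange(1, n_bins) / n_bins
    cuts = np.round(np.quantile(nonzero, qs), 3)
    if len(np.unique(cuts)) != len(cuts):
        raise DegenerateBreaksError("quantiles collapse; values too concentrated")
    return CategoryBreaks(tuple(float(c) for c in cuts))


# --------------------------------------------------------- quartiles

#: Published quartile cut-offs (g/day) per analyte.
DEFAULT_QUARTILE_CUTS = {
    "isoleucine": (4.12, 4.8, 5.57),
    "leucine": (6.7, 7.89, 9.2),
    "valine": (4.72, 5.5, 6.36),
    "total_bcaa": (15.6, 18.2, 21.1),
}


@dataclass(frozen=True)
class QuartileCuts:
    """Three increasing cut-offs (g/day) separating intake quartiles."""

    q1: float
    q2: float
    q3: float

    def __post_init__(self) -> None:
        if not self.q1 < self.q2 < self.q3:
            raise ValidationError("quartile cuts must be strictly increasing")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.q1, self.q2, self.q3)


def quartile_assign(
    intakes: list[float] | np.ndarray, cuts: QuartileCuts | None = None
) -> np.ndarray:
    """Assign each intake (g/day) to quartile 1..4.

    With explicit cuts, assignment is closed on the left cut: value <=
    q1 -> Q1, <= q2 -> Q2, <= q3 -> Q3, else Q4.  Without cuts, sample
    quartiles (linear-interpolation quantiles) are computed first.
    """
    arr = np.asarray(intakes, dtype=float)
    if arr.size == 0:
        raise ValidationError("intakes must be non-empty")
    if cuts is None:
        q = np.quantile(arr, [0.25, 0.5, 0.75])
        cuts = QuartileCuts(*[float(c) for c in q])
    return 1 + np.searchsorted(np.asarray(cuts.as_tuple()), arr, side="left").astype(int)


# ------------------------------------------------------- association


@dataclass
class AssociationResult:
    """Quartile-vs-outcome logistic model summary.

    Odds ratios for Q2..Q4 against Q1 (Q1 fixed at 1), Wald 95%
    confidence intervals, and an overall likelihood-ratio p-value for
    the three quartile indicators jointly.
    """

    odds_ratios: dict[int, float]
    ci_low: dict[int, float]
    ci_high: dict[int, float]
    p_overall: float
    covariates: tuple[str, ...] = ()
    nobs: int = 0

    def __post_init__(self) -> None:
        for q, or_ in self.odds_ratios.items():
            if q == 1:
                continue
            if not self.ci_low[q] <= or_ <= self.ci_high[q]:
                raise ValidationError(f"Q{q}: OR outside its own confidence interval")


def fit_quartile_association(
    quartile: np.ndarray,
    outcome: np.ndarray,
    age: np.ndarray | None = None,
    energy: np.ndarray | None = None,
) -> AssociationResult:
    """Logistic regression of a binary outcome on intake quartiles.

    Quartiles enter as indicator variables with Q1 as reference;
    optional age and energy covariates adjust the model.  ORs are
    exponentiated coefficients with Wald 95% CIs; the overall p-value is
    the likelihood-ratio test of the three quartile indicators.
    """
    quartile = np.asarray(quartile, dtype=int)
    outcome = np.asarray(outcome, dtype=float)
    present = sorted(set(quartile.tolist()))
    if len(present) < 2:
        raise ValidationError("need at least 2 quartiles represented")
    if outcome.min() == outcome.max():
        raise DegenerateOutcomeError("outcome is constant")

    cols = {}
    q_cols = []
    for q in present:
        if q == min(present):
            continue  # reference
        name = f"Q{q}"
        cols[name] = (quartile == q).astype(float)
        q_cols.append(name)
    covariates = []
    if age is not None:
        cols["age"] = np.asarray(age, dtype=float)
        covariates.append("age")
    if energy is not None:
        cols["energy"] = np.asarray(energy, dtype=float)
        covariates.append("energy")
    X = sm.add_constant(pd.DataFrame(cols), has_constant="add")

    try:
        full = sm.Logit(outcome, X).fit(disp=0, maxiter=100)
    except Exception as exc:  # statsmodels raises PerfectSeparationError and friends
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(full.bse[q_cols])):
        raise SeparationError("non-finite standard errors; possible separation")

    reduced_cols = [c for c in X.columns if c not in q_cols]
    reduced = sm.Logit(outcome, X[reduced_cols]).fit(disp=0, maxiter=100)
    lr = 2.0 * (full.llf - reduced.llf)
    p_overall = float(stats.chi2.sf(max(lr, 0.0), df=len(q_cols)))

    odds = {min(present): 1.0}
    lo = {min(present): 1.0}
    hi = {min(present): 1.0}
    z = stats.norm.ppf(0.975)
    for q in present:
        if q == min(present):
            continue
        b = float(full.params[f"Q{q}"])
        se = float(full.bse[f"Q{q}"])
        odds[q] = math.exp(b)
        lo[q] = math.exp(b - z * se)
        hi[q] = math.exp(b + z * se)
    return AssociationResult(
        odds_ratios=odds,
        ci_low=lo,
        ci_high=hi,
        p_overall=p_overall,
        covariates=tuple(covariates),
        nobs=len(outcome),
    )


# ------------------------------------------------------ contribution


def group_contribution(group_amounts: pd.DataFrame) -> pd.Series:
    """Food-group shares of the population's intake of one analyte.

    ``group_amounts`` is a subject x food-group DataFrame of intakes
    (g/day).  The contribution of group g is 100 x (sum over subjects of
    the group's intake) / (sum over subjects of total intake) — the
    population-ratio attribution of Block-style contribution analyses.
    The returned percentages sum to 100.
    """
    totals = group_amounts.sum(axis=0)
    grand = float(totals.sum())
    if grand <= 0:
        raise UndefinedContributionError("population total intake is zero")
    return 100.0 * totals / grand


def contribution_table(intakes: pd.DataFrame) -> pd.DataFrame:
    """Per-analyte contribution table from a survey intake summary.

    One row per food subgroup, one column per analyte (total BCAA,
    isoleucine, leucine, valine); each column sums to 100.
    """
    from bcaadb.recall import group_columns

    out = {}
    for analyte, col in (
        ("BCAA", "total_bcaa"),
        ("Isoleucine", "isoleucine"),
        ("Leucine", "leucine"),
        ("Valine", "valine"),
    ):
        out[analyte] = group_contribution(group_columns(intakes, col))
    return pd.DataFrame(out)


# ----------------------------------------------------------- helpers


def percent_increase(higher: float, lower: float) -> int:
    """Whole-percent increase of ``higher`` over ``lower``.

    E.g. mean intakes of 13.84 vs 12.91 g/day give a 7% increase.
    """
    if lower <= 0:
        raise ValidationError("baseline must be > 0")
    return int(round(100.0 * (higher - lower) / lower))
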