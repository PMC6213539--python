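import numpy as np
import pandas as pd
import pytest

from bcaadb.errors import (
    DegenerateBreaksError,
    DegenerateOutcomeError,
    UndefinedContributionError,
    ValidationError,
)
from bcaadb.food_model import BCAATriple
from bcaadb.survey import (
    CategoryBreaks,
    GPAQAnswers,
    QuartileCuts,
    SubjectProfile,
    categorize_items,
    compute_breaks,
    exclude_misreporters,
    fit_quartile_association,
    gpaq_met_minutes,
    group_contribution,
    harris_benedict_bmr,
    percent_increase,
    quartile_assign,
)
from tests.conftest import make_item


# ---------------------------------------------------------------- BMR/GPAQ


def test_harris_benedict_male_example():
    assert harris_benedict_bmr("male", 70, 175, 30) == pytest.approx(1702.0, abs=0.1)


def test_harris_benedict_female_example():
    assert harris_benedict_bmr("female", 70, 175, 30) == pytest.approx(1507.9, abs=0.1)


def test_harris_benedict_monotone_in_weight_and_validates():
    assert harris_benedict_bmr("male", 140, 175, 30) > harris_benedict_bmr("male", 70, 175, 30)
    with pytest.raises(ValidationError):
        harris_benedict_bmr("male", 0, 175, 30)


def test_gpaq_null_activity_is_low():
    met, level = gpaq_met_minutes(GPAQAnswers())
    assert met == 0.0 and level == "low"


def test_gpaq_moderate_work_example():
    met, level = gpaq_met_minutes(GPAQAnswers(work_moderate=(5, 30.0)))
    assert met == pytest.approx(600.0) and level == "moderate"


def test_gpaq_vigorous_leisure_example():
    met, level = gpaq_met_minutes(GPAQAnswers(leisure_vigorous=(3, 60.0)))
    assert met == pytest.approx(1440.0)


def test_gpaq_high_levels():
    # vigorous on >= 3 days with >= 1500 MET-min/week
    _, level = gpaq_met_minutes(GPAQAnswers(leisure_vigorous=(4, 60.0)))
    assert level == "high"
    # 7 active days and >= 3000 MET-min/week
    _, level = gpaq_met_minutes(GPAQAnswers(work_moderate=(7, 120.0)))
    assert level == "high"


def test_gpaq_rejects_out_of_range_days():
    with pytest.raises(ValidationError):
        GPAQAnswers(work_vigorous=(8, 30.0))


# ------------------------------------------------------------- misreporters


def _profile(sid, energy=None, activity=None, **kw):
    return SubjectProfile(subject_id=sid, age=30, sex="male", weight=70, height=175,
                          activity_level=activity, energy_kcal=energy, **kw)


def _intakes(**energies):
    return pd.DataFrame({"energy_kcal": pd.Series(energies)})


def test_energy_outliers_excluded_when_activity_missing():
    profiles = [_profile("over"), _profile("under"), _profile("ok")]
    intakes = _intakes(over=4500.0, under=999.0, ok=2000.0)
    kept, excluded = exclude_misreporters(profiles, intakes)
    assert [p.subject_id for p in kept] == ["ok"]
    assert "over-reporter" in excluded["over"] and "under-reporter" in excluded["under"]


def test_energy_bounds_are_strict_inequalities():
    profiles = [_profile("hi"), _profile("lo")]
    kept, excluded = exclude_misreporters(profiles, _intakes(hi=4000.0, lo=1000.0))
    assert len(kept) == 2 and excluded == {}


def test_goldberg_ratio_screen_when_activity_present():
    # BMR for this profile is ~1702 kcal; low PAL 1.4 keeps EI/BMR in [0.84, 1.96]
    profiles = [_profile("plausible", activity="low"), _profile("implausible", activity="low")]
    kept, excluded = exclude_misreporters(
        profiles, _intakes(plausible=2000.0, implausible=4500.0))
    assert [p.subject_id for p in kept] == ["plausible"]
    assert "over-reporter" in excluded["implausible"]


def test_exclusion_partitions_the_cohort(pipeline_result):
    kept = {p.subject_id for p in pipeline_result["kept"]}
    excluded = set(pipeline_result["excluded"])
    everyone = {p.subject_id for p in pipeline_result["profiles"]}
    assert kept | excluded == everyone
    assert kept & excluded == set()


# ----------------------------------------------------------- categorization


@pytest.mark.parametrize("total, expected", [
    (0.0, "A"), (0.1, "B"), (0.232, "B"), (0.233, "C"), (1.083, "C"),
    (1.084, "D"), (2.658, "D"), (2.659, "E"), (4.168, "E"), (4.169, "F"),
])
def test_default_breaks_bin_edges(total, expected):
    assert CategoryBreaks().category(total) == expected


def test_categorize_partitions_items_and_columns_sum_to_100(pipeline_result):
    cats = pipeline_result["categories"]
    assert set(cats.unique()) <= set("ABCDEF")
    assert len(cats) == sum(1 for it in pipeline_result["compiled"] if it.bcaa is not None)
    comp = pipeline_result["composition"]
    for col in comp.columns:
        s = comp[col].sum()
        assert s == pytest.approx(100.0, abs=0.01) or s == 0.0


def test_categorize_rejects_uncompiled_items():
    with pytest.raises(ValidationError):
        categorize_items([make_item("x", 5.0)])


def test_compute_breaks_quantiles_of_1_to_100():
    breaks = compute_breaks(list(range(1, 101)), 5)
    assert breaks.thresholds == pytest.approx((20.8, 40.6, 60.4, 80.2))


def test_compute_breaks_sets_zeros_aside_and_scales_with_values():
    values = [0.0] * 10 + list(np.linspace(0.5, 8.0, 60))
    b1 = compute_breaks(values, 5)
    b2 = compute_breaks([v * 2 for v in values], 5)
    assert b2.thresholds == pytest.approx(tuple(2 * t for t in b1.thresholds), abs=2e-3)


def test_compute_breaks_degenerate_values():
    with pytest.raises(DegenerateBreaksError):
        compute_breaks([1.0] * 50, 5)


# ----------------------------------------------------------------- quartiles


def test_quartile_assignment_with_published_cuts():
    cuts = QuartileCuts(15.6, 18.2, 21.1)
    assert quartile_assign([16.0], cuts)[0] == 2
    # closed on the left cut: a value equal to q1 stays in Q1
    assert quartile_assign([15.6], cuts)[0] == 1
    assert quartile_assign([21.2], cuts)[0] == 4


def test_computed_quartiles_are_balanced_and_monotone():
    rng = np.random.default_rng(2)
    values = rng.uniform(5, 25, size=403)
    q = quartile_assign(values)
    sizes = np.bincount(q)[1:]
    assert sizes.max() - sizes.min() <= 1
    order = np.argsort(values)
    assert np.all(np.diff(q[order]) >= 0)


# --------------------------------------------------------------- association


def test_two_group_fit_matches_contingency_cross_product():
    # Q1: 30/100 obese, Q4: 60/100 -> OR = (60*70)/(40*30) = 3.5
    quartile = np.repeat([1, 4], 100)
    outcome = np.concatenate([np.repeat([1, 0], [30, 70]), np.repeat([1, 0], [60, 40])])
    res = fit_quartile_association(quartile, outcome)
    assert res.odds_ratios[4] == pytest.approx(3.5, rel=1e-4)
    assert res.ci_low[4] <= res.odds_ratios[4] <= res.ci_high[4]
    assert res.odds_ratios[1] == 1.0


def test_association_null_has_or_near_one():
    rng = np.random.default_rng(8)
    n = 4000
    quartile = rng.integers(1, 5, size=n)
    outcome = (rng.random(n) < 0.3).astype(float)
    age = rng.uniform(9, 18, size=n)
    energy = rng.normal(2000, 300, size=n)
    res = fit_quartile_association(quartile, outcome, age, energy)
    for q in (2, 3, 4):
        assert res.ci_low[q] <= 1.0 <= res.ci_high[q]
    assert res.covariates == ("age", "energy")


def test_association_degenerate_outcome_raises():
    with pytest.raises(DegenerateOutcomeError):
        fit_quartile_association(np.repeat([1, 4], 50), np.zeros(100))
    with pytest.raises(ValidationError):
        fit_quartile_association(np.ones(100, dtype=int), np.tile([0, 1], 50))


# -------------------------------------------------------------- contribution


def test_contribution_single_group_is_100():
    amounts = pd.DataFrame({"Cheese": [1.0, 2.0], "Drinks": [0.0, 0.0]})
    contrib = group_contribution(amounts)
    assert contrib["Cheese"] == pytest.approx(100.0)
    assert contrib["Drinks"] == 0.0


def test_contribution_equal_groups_split_50_50():
    amounts = pd.DataFrame({"Cheese": [1.0, 2.0], "Legumes": [2.0, 1.0]})
    contrib = group_contribution(amounts)
    assert contrib["Cheese"] == pytest.approx(50.0)


def test_contribution_matches_double_sum_oracle_and_is_scale_invariant():
    rng = np.random.default_rng(4)
    amounts = pd.DataFrame(rng.uniform(0, 5, size=(30, 6)),
                           columns=[f"g{k}" for k in range(6)])
    contrib = group_contribution(amounts)
    grand = amounts.to_numpy().sum()
    for k, col in enumerate(amounts.columns):
        assert contrib[col] == pytest.approx(
            100.0 * amounts[col].sum() / grand, rel=1e-12)
    assert contrib.sum() == pytest.approx(100.0, abs=0.01)
    scaled = group_contribution(amounts * 7.3)
    assert np.allclose(scaled.to_numpy(), contrib.to_numpy())


def test_contribution_zero_total_is_undefined():
    with pytest.raises(UndefinedContributionError):
        group_contribution(pd.DataFrame({"a": [0.0], "b": [0.0]}))


def test_contribution_table_columns_sum_to_100(pipeline_result):
    contrib = pipeline_result["contribution"]
    for col in contrib.columns:
        assert contrib[col].sum() == pytest.approx(100.0, abs=0.01)


# ------------------------------------------------------------------ helpers


def test_percent_increase_of_published_sex_means():
    assert percent_increase(13.84, 12.91) == 7
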