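"""Score construction, application and stratified mortality tables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirscore.cohort import AGE, MARKERS, CohortRecord
from mirscore.errors import DegenerateInputError, InputError
from mirscore.scoring import (
    HIGH_SCORES,
    LOW_SCORES,
    ScoreDefinition,
    ScoreItem,
    apply_score,
    apply_score_cohort,
    build_score,
    default_grouping,
    filter_significant,
    reference_icu_definition,
    reference_overall_definition,
    round_half_up_percent,
    select_markers,
    stratum_mortality,
)
from mirscore.stats import TwoGroupTest
from mirscore.synthetic import default_study_config, simulate_cohort


def _record(markers=None, age=50.0, **kwargs):
    defaults = dict(
        patient_id="X",
        age=age,
        sepsis=False,
        icu_death=False,
        icu_los=5.0,
        overall_event=False,
        followup_time=100.0,
    )
    defaults.update(kwargs)
    levels = {m: 1.0 for m in MARKERS}
    if markers:
        levels.update(markers)
    return CohortRecord(markers=levels, **defaults)


def _tgt(p, direction):
    return TwoGroupTest(
        statistic_u=1.0, p_value=p, n1=5, n2=5,
        median1=1.0, median2=2.0 if direction == "up" else 0.5,
        direction=direction,
    )


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_filter_significant_threshold():
    results = {
        "A": _tgt(0.01, "up"),
        "B": _tgt(0.2, "none"),
        "C": _tgt(0.03, "down"),
    }
    assert filter_significant(results, 0.05) == [
        ("A", HIGH_SCORES),
        ("C", LOW_SCORES),
    ]


def test_filter_significant_alpha_zero():
    assert filter_significant({"A": _tgt(0.0, "up")}, 0.0) == []


def test_select_markers_single_class_raises():
    cohort = [_record(patient_id=f"P{i}") for i in range(10)]
    with pytest.raises(DegenerateInputError):
        select_markers(cohort, "icu_death")


def test_select_markers_unknown_outcome():
    with pytest.raises(InputError):
        select_markers([_record()], "bogus")


def test_select_markers_recovers_configured_effects(default_cohort):
    selected = set(select_markers(default_cohort, "icu_death"))
    assert {("miR-133a", HIGH_SCORES), ("miR-143", LOW_SCORES),
            ("miR-223", LOW_SCORES)} <= selected
    selected = set(select_markers(default_cohort, "overall_event"))
    assert {("miR-133a", HIGH_SCORES), ("miR-150", LOW_SCORES)} <= selected


# ---------------------------------------------------------------------------
# build_score
# ---------------------------------------------------------------------------

def test_build_score_range_single_item(default_cohort):
    definition = build_score(
        default_cohort, [("miR-133a", HIGH_SCORES)], "icu_death", False
    )
    assert definition.max_score == 1
    scores = apply_score_cohort(definition, default_cohort)
    assert set(scores) <= {0, 1}


def test_build_score_empty_selection_raises(default_cohort):
    with pytest.raises(InputError):
        build_score(default_cohort, [], "icu_death", True)


def test_build_score_age_cutoff_recovery():
    """With near-separated age distributions the Youden age cut-off lands at
    the generative boundary (mid-way between the class means) to within the
    spacing of adjacent ages around it."""
    base = default_study_config()
    cfg = base.replace(
        age_mean_survivor=55.0, age_mean_nonsurvivor=82.0, age_sd=4.0
    )
    for seed in range(10):
        cohort = simulate_cohort(cfg.replace(seed=seed))
        definition = build_score(
            cohort, [("miR-133a", HIGH_SCORES)], "overall_event", True
        )
        age_item = definition.items[-1]
        assert age_item.marker == AGE
        flags = np.array([r.overall_event for r in cohort])
        ages = np.array([r.age for r in cohort])
        lo = ages[~flags].max()  # oldest survivor below a clean boundary
        hi = ages[flags].min()
        # generative boundary is 68.5; allow the adjacent-age spacing
        spacing = max(abs(lo - 68.5), abs(hi - 68.5), 1.0)
        assert abs(age_item.cutoff - 68.5) <= spacing + 1e-9


def test_reference_icu_definition_max_score():
    definition = reference_icu_definition(
        {"miR-133a": 4.0, "miR-143": 3.0, "miR-223": 30.0}, include_age=True
    )
    assert definition.max_score == 4
    assert definition.includes_age
    assert definition.items[-1] == ScoreItem(AGE, 72.5, HIGH_SCORES)


def test_reference_overall_definition_items():
    definition = reference_overall_definition(include_age=True)
    assert definition.items[0] == ScoreItem("miR-133a", 4.3, HIGH_SCORES)
    assert definition.items[1] == ScoreItem("miR-150", 22.7, LOW_SCORES)
    assert definition.items[2] == ScoreItem(AGE, 68.5, HIGH_SCORES)


def test_score_definition_json_round_trip():
    definition = reference_overall_definition()
    assert ScoreDefinition.from_json(definition.to_json()) == definition


# ---------------------------------------------------------------------------
# apply_score
# ---------------------------------------------------------------------------

def test_apply_overall_reference_three_points():
    definition = reference_overall_definition(include_age=True)
    record = _record({"miR-133a": 5.0, "miR-150": 10.0}, age=70.0)
    assert apply_score(definition, record) == 3


def test_apply_icu_reference_four_points():
    definition = reference_icu_definition(
        {"miR-133a": 4.0, "miR-143": 3.0, "miR-223": 30.0}
    )
    record = _record(
        {"miR-133a": 9.0, "miR-143": 1.0, "miR-223": 20.0}, age=80.0
    )
    assert apply_score(definition, record) == 4


def test_apply_score_strict_inequality_at_cutoffs():
    definition = reference_overall_definition(include_age=True)
    record = _record({"miR-133a": 4.3, "miR-150": 22.7}, age=68.5)
    assert apply_score(definition, record) == 0


def test_apply_score_missing_marker():
    definition = ScoreDefinition(
        name="x", items=(ScoreItem("not-a-marker", 1.0, HIGH_SCORES),)
    )
    with pytest.raises(InputError):
        apply_score(definition, _record())


@given(
    level=st.floats(min_value=0.1, max_value=100.0),
    bump=st.floats(min_value=0.0, max_value=50.0),
)
@settings(max_examples=100, deadline=None)
def test_apply_score_monotone_in_high_marker(level, bump):
    definition = reference_overall_definition(include_age=True)
    low = apply_score(definition, _record({"miR-133a": level}))
    high = apply_score(definition, _record({"miR-133a": level + bump}))
    assert high >= low


def test_score_range_extremes(default_cohort):
    definition = build_score(
        default_cohort,
        [("miR-133a", HIGH_SCORES), ("miR-143", LOW_SCORES)],
        "icu_death",
        True,
    )
    scores = apply_score_cohort(definition, default_cohort)
    assert min(scores) >= 0 and max(scores) <= definition.max_score


# ---------------------------------------------------------------------------
# stratum mortality
# ---------------------------------------------------------------------------

def test_stratum_mortality_direct_count():
    table = stratum_mortality(
        [0, 0, 1, 3, 3, 3],
        [False, False, False, True, True, False],
        [{0}, {1, 2}, {3}],
    )
    rows = {r["stratum"]: r for r in table.to_rows()}
    assert rows["3"]["n"] == 3
    assert rows["3"]["deaths"] == 2
    assert rows["3"]["mortality_percent"] == 66.7


def test_stratum_mortality_zero_deaths():
    table = stratum_mortality([0, 1, 2], [False] * 3, [{0}, {1, 2}])
    assert all(m == 0.0 for m in table.mortality_percent)


def test_stratum_mortality_uncovered_score_raises():
    with pytest.raises(InputError):
        stratum_mortality([0, 5], [False, True], [{0}, {1}])


def test_stratum_mortality_overlap_raises():
    with pytest.raises(InputError):
        stratum_mortality([0, 1], [False, True], [{0, 1}, {1}])


@given(st.data())
@settings(max_examples=100, deadline=None)
def test_stratum_conservation(data):
    n = data.draw(st.integers(min_value=1, max_value=40))
    scores = data.draw(
        st.lists(st.integers(min_value=0, max_value=4), min_size=n, max_size=n)
    )
    deaths = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
    table = stratum_mortality(scores, deaths, [{0}, {1, 2}, {3, 4}])
    assert sum(table.n) == n
    assert sum(table.deaths) == sum(deaths)


def test_round_half_up():
    assert round_half_up_percent(45, 204) == 22.1
    assert round_half_up_percent(1, 8) == 12.5
    assert round_half_up_percent(1, 16) == 6.3  # 6.25 rounds half-up
    assert round_half_up_percent(0, 5) == 0.0
    assert round_half_up_percent(5, 5) == 100.0


def test_default_grouping():
    assert default_grouping(3) == [{0}, {1, 2}, {3}]
    assert default_grouping(4) == [{0}, {1, 2, 3}, {4}]
    assert default_grouping(1) == [{0}, {1}]


def test_stratified_mortality_monotone_on_default_cohort(default_cohort):
    selected = select_markers(default_cohort, "icu_death")
    definition = build_score(default_cohort, selected, "icu_death", False)
    scores = apply_score_cohort(definition, default_cohort)
    table = stratum_mortality(
        scores,
        [r.icu_death for r in default_cohort],
        default_grouping(definition.max_score),
    )
    assert list(table.mortality_percent) == sorted(table.mortality_percent)
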