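"""Index finding, criterion application, batch execution, attrition."""

from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohortforge import (
    Criterion,
    DataMart,
    EhrDataset,
    IdentificationSpec,
    IndexRule,
    ObservationWindow,
    PopulationParams,
    age_at,
    apply_criterion,
    builtin_templates,
    find_index_dates,
    fracture_study_specs,
    generate_population,
    load_specs,
    normalize_pharmacy_durations,
    packaged_data_path,
    run_batch,
    run_identification,
)
from cohortforge.engine import EngineError

from _naive import dataset_rows, naive_age, naive_identify
from conftest import make_encounter, make_event, make_patient

WINDOW = ObservationWindow("2010-01-01", "2014-12-31")
RULE = IndexRule("osteoporotic_fracture", washout="first_ever")


# ---------------------------------------------------------------------------
# age


@pytest.mark.parametrize("birth,on,expected", [
    ("1960-03-01", "2010-02-28", 49),   # day before 50th birthday
    ("1960-03-01", "2010-03-01", 50),   # on the birthday
    ("1960-03-01", "2010-03-02", 50),
    ("2000-02-29", "2015-02-28", 14),   # leap-day birthday, non-leap year
    ("2000-02-29", "2015-03-01", 15),
])
def test_age_at_examples(birth, on, expected):
    assert age_at(birth, on) == expected


def test_age_at_rejects_reversed_dates():
    with pytest.raises(EngineError):
        age_at("2010-01-01", "2000-01-01")


@settings(derandomize=True, max_examples=300)
@given(
    birth=st.dates(date(1900, 1, 1), date(2010, 12, 31)),
    delta=st.integers(0, 40_000),
)
def test_age_at_matches_anniversary_walk_oracle(birth, delta):
    on = date.fromordinal(birth.toordinal() + delta)
    assert age_at(birth, on) == naive_age(birth, on)


# ---------------------------------------------------------------------------
# index dates


def _ds(patients, events, encounters=()):
    return EhrDataset.from_records(patients, events, encounters)


def test_index_is_earliest_in_window():
    ds = _ds([make_patient("P1", "1940-01-01")],
             [make_event("P1", "2011-05-01"), make_event("P1", "2012-01-01", code="805.4")])
    idx = find_index_dates(ds, RULE, WINDOW)
    assert idx == {"P1": pd.Timestamp("2011-05-01")}


def test_first_ever_washout_drops_prior_history():
    ds = _ds([make_patient("P1", "1940-01-01")],
             [make_event("P1", "2009-06-01"), make_event("P1", "2011-05-01")])
    assert find_index_dates(ds, RULE, WINDOW) == {}
    # without the first-ever washout the in-window first occurrence indexes
    relaxed = IndexRule("osteoporotic_fracture", washout="none")
    assert find_index_dates(ds, relaxed, WINDOW) == {"P1": pd.Timestamp("2011-05-01")}


def test_settings_filter_restricts_index_events():
    ds = _ds([make_patient("P1", "1940-01-01")],
             [make_event("P1", "2011-05-01", setting="emergency")])
    rule = IndexRule("osteoporotic_fracture", settings=frozenset({"outpatient"}))
    assert find_index_dates(ds, rule, WINDOW) == {}


def test_index_oracle_equivalence_on_random_dataset(library):
    ds = generate_population(PopulationParams(n_patients=500, yearly_incidence=0.3, seed=17))
    rows = dataset_rows(ds)
    for washout in ("first_ever", "none"):
        rule = IndexRule("osteoporotic_fracture", washout=washout)
        spec = IdentificationSpec("t", WINDOW, rule)
        engine = find_index_dates(ds, rule, WINDOW, library)
        naive, _ = naive_identify(rows, spec, library)
        assert {p: d.date() for p, d in engine.items()} == naive


# ---------------------------------------------------------------------------
# criteria


@pytest.fixture()
def aom_member_ds():
    return _ds(
        [make_patient("P1", "1940-01-01")],
        [make_event("P1", "2012-06-15"),
         make_event("P1", "2012-01-10", dimension="pharmacy", code="alendronate",
                    duration=30),
         make_event("P1", "2012-06-15", dimension="pharmacy", code="raloxifene",
                    duration=30)],
    )


def test_exclude_if_present_in_lookback(aom_member_ds):
    members = {"P1": pd.Timestamp("2012-06-15")}
    crit = Criterion("prior aom", "exclude_if_present", template="aom", window=(-365, -1))
    survivors, excluded = apply_criterion(aom_member_ds, members, crit)
    assert survivors == {} and excluded == 1


def test_index_day_event_outside_lookback():
    """A dispensing on the index date itself (offset 0) is not lookback."""
    ds = _ds([make_patient("P1", "1940-01-01")],
             [make_event("P1", "2012-06-15"),
              make_event("P1", "2012-06-15", dimension="pharmacy", code="alendronate",
                         duration=30)])
    members = {"P1": pd.Timestamp("2012-06-15")}
    crit = Criterion("prior aom", "exclude_if_present", template="aom", window=(-365, -1))
    survivors, excluded = apply_criterion(ds, members, crit)
    assert survivors == members and excluded == 0
    # ... nor does it count as post-index treatment
    crit2 = Criterion("treated", "require_presence", template="aom", window=(1, 365))
    survivors2, _ = apply_criterion(ds, members, crit2)
    assert survivors2 == {}


def test_age_minimum_criterion():
    ds = _ds([make_patient("P1", "1970-01-01"), make_patient("P2", "1930-01-01")],
             [make_event(p, "2012-06-15") for p in ("P1", "P2")])
    members = {"P1": pd.Timestamp("2012-06-15"), "P2": pd.Timestamp("2012-06-15")}
    survivors, excluded = apply_criterion(
        ds, members, Criterion("adults", "require_presence", age_minimum=50))
    assert set(survivors) == {"P2"} and excluded == 1


def test_unresolvable_template_is_fatal(aom_member_ds):
    from cohortforge.templates import TemplateError

    crit = Criterion("x", "exclude_if_present", template="nonesuch", window=(-1, 1))
    with pytest.raises(TemplateError, match="nonesuch"):
        apply_criterion(aom_member_ds, {"P1": pd.Timestamp("2012-06-15")}, crit)


def test_criterion_construction_rules():
    with pytest.raises(EngineError):
        Criterion("two targets", "require_presence", template="aom",
                  age_minimum=50, window=(0, 1))
    with pytest.raises(EngineError):
        Criterion("age with window", "require_presence", age_minimum=50, window=(0, 1))
    with pytest.raises(EngineError):
        Criterion("no window", "require_presence", template="aom")
    with pytest.raises(EngineError):
        Criterion("bad window", "require_presence", template="aom", window=(5, -5))


# ---------------------------------------------------------------------------
# full runs


def test_zero_criteria_spec_returns_index_mapping(small_fixture_ds):
    spec = IdentificationSpec("all indexed", WINDOW,
                              IndexRule("osteoporotic_fracture", washout="none"))
    plist = run_identification(small_fixture_ds, spec)
    idx = find_index_dates(small_fixture_ds,
                           IndexRule("osteoporotic_fracture", washout="none"), WINDOW)
    assert plist.members == idx
    assert plist.attrition.index_count == len(idx)
    assert plist.attrition.steps == []


def test_empty_index_set_is_a_valid_empty_list():
    ds = EhrDataset.from_records([make_patient("P1", "1950-01-01")], [], [])
    spec = IdentificationSpec("nobody", WINDOW, RULE,
                              criteria=(Criterion("adults", "require_presence",
                                                  age_minimum=50),))
    plist = run_identification(ds, spec)
    assert len(plist) == 0
    assert plist.attrition.index_count == 0
    assert [s.excluded for s in plist.attrition.steps] == [0]


def test_chained_spec_members_subset_and_traceable(small_fixture_ds):
    mart = DataMart()
    results = run_batch(fracture_study_specs(), small_fixture_ds, mart)
    index_list, followup, treated = results
    for child in (followup, treated):
        assert set(child.members) <= set(index_list.members)
        assert child.parent == index_list.case_number
        assert mart.get(child.parent) is index_list


def test_attrition_conservation_and_containment(small_fixture_ds):
    mart = DataMart()
    for plist in run_batch(fracture_study_specs(), small_fixture_ds, mart):
        att = plist.attrition
        att.check_conserved()
        assert att.index_count - sum(s.excluded for s in att.steps) == len(plist)
        if plist.parent is not None:
            assert set(plist.members) <= set(mart.get(plist.parent).members)


def test_batch_audit_log_order(small_fixture_ds):
    mart = DataMart()
    run_batch(fracture_study_specs(), small_fixture_ds, mart)
    assert len(mart.audit) == 3
    topics = [e["topic"] for e in mart.audit]
    assert topics == [s.topic for s in fracture_study_specs()]
    assert all(e["status"] == "ok" and "cost_seconds" in e for e in mart.audit)


def test_failing_spec_logged_and_skipped(small_fixture_ds):
    specs = fracture_study_specs()
    bad = IdentificationSpec("broken", WINDOW, IndexRule("nonesuch"))
    mart = DataMart()
    results = run_batch([specs[0], bad, specs[2]], small_fixture_ds, mart)
    assert len(results) == 2
    statuses = [e["status"] for e in mart.audit]
    assert statuses == ["ok", "failed", "ok"]


def test_rerun_is_deterministic_up_to_case_numbers(small_fixture_ds):
    runs = []
    for _ in range(2):
        mart = DataMart()
        runs.append(run_batch(fracture_study_specs(), small_fixture_ds, mart))
    for a, b in zip(*runs):
        assert a.members == b.members
        assert a.attrition == b.attrition
        assert a.case_number != b.case_number  # fresh UUIDs each run


def test_pipeline_oracle_equivalence(library, medium_population_ds):
    rows = dataset_rows(medium_population_ds)
    mart = DataMart()
    for spec in fracture_study_specs():
        plist = run_identification(medium_population_ds, spec, mart, library)
        source = None
        if spec.source_list is not None:
            parent = mart.resolve(spec.source_list)
            source = {p: d.date() for p, d in parent.members.items()}
        naive_members, naive_att = naive_identify(rows, spec, library, source)
        assert {p: d.date() for p, d in plist.members.items()} == naive_members
        assert [(s.label, s.excluded, s.remaining) for s in plist.attrition.steps] == naive_att


@settings(derandomize=True, max_examples=30, deadline=None)
@given(perm_seed=st.integers(0, 10_000))
def test_final_members_invariant_under_criteria_permutation(perm_seed, library,
                                                            medium_population_ds):
    """Criterion order moves only the per-step counts, never the final set."""
    base = fracture_study_specs()[0]
    rng = np.random.default_rng(perm_seed)
    order = rng.permutation(len(base.criteria))
    permuted = IdentificationSpec(base.topic, base.observation, base.index,
                                  tuple(base.criteria[i] for i in order))
    a = run_identification(medium_population_ds, base, library=library)
    b = run_identification(medium_population_ds, permuted, library=library)
    assert a.members == b.members


# ---------------------------------------------------------------------------
# mart persistence, packaged specs, duration normalisation


def test_mart_save_load_round_trip(small_fixture_ds, tmp_path):
    mart = DataMart()
    run_batch(fracture_study_specs(), small_fixture_ds, mart)
    mart.save(tmp_path)
    loaded = DataMart.load(tmp_path)
    assert len(loaded) == len(mart)
    for pl in mart.lists:
        other = loaded.get(pl.case_number)
        assert other.members == pl.members
        assert other.attrition == pl.attrition
        assert other.parent == pl.parent
    assert loaded.audit == mart.audit


def test_packaged_spec_file_matches_builders():
    loaded = load_specs(packaged_data_path("fracture_study.yaml"))
    built = fracture_study_specs()
    assert [s.topic for s in loaded] == [s.topic for s in built]
    for a, b in zip(loaded, built):
        assert a.observation == b.observation
        assert a.index == b.index
        assert a.criteria == b.criteria
        assert a.source_list == b.source_list


def test_normalize_pharmacy_durations_opt_in():
    ds = EhrDataset.from_records(
        [make_patient("P1", "1940-01-01")],
        [make_event("P1", "2012-01-01", dimension="pharmacy", code="zolendronate",
                    duration=1),
         make_event("P1", "2012-02-01", dimension="pharmacy", code="alendronate",
                    duration=1),
         make_event("P1", "2012-03-01", dimension="pharmacy", code="zolendronate",
                    duration=28)],
    )
    out = normalize_pharmacy_durations(ds)
    durs = dict(zip(out.events["code"] + "/" + out.events["event_date"].dt.strftime("%m"),
                    out.events["duration_days"]))
    assert durs["zolendronate/01"] == 365       # 1-day annual infusion corrected
    assert durs["alendronate/02"] == 1          # not in the duration table
    assert durs["zolendronate/03"] == 28        # plausible recorded value kept
    assert (ds.events["duration_days"] == pd.array([1, 1, 28], dtype="Int64")).all()
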