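"""Phecode construction: code normalization, the two-distinct-days case
rule, control exclusions, matrix building and composites."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from phewaskit.phenome_map import (MalformedIcd9Error, PhecodeEntry,
                                   PhecodeMap, Status, UnknownPhecodeError,
                                   assign_status, build_phenotype_matrix,
                                   make_composite, normalize_icd9)

from conftest import events_frame


# -- normalize_icd9 ----------------------------------------------------------

@pytest.mark.parametrize("raw, expected", [
    ("25000", "250.00"),
    ("250.00", "250.00"),
    (" v70 ", "V70"),
    ("v700", "V70.0"),
    ("E8120", "E812.0"),
    ("038", "038"),
])
def test_normalize_icd9_canonical_form(raw, expected):
    assert normalize_icd9(raw) == expected


@pytest.mark.parametrize("bad", ["", "  ", "25", "ABCD", "2500000", "V7"])
def test_normalize_icd9_rejects_malformed(bad):
    with pytest.raises(MalformedIcd9Error):
        normalize_icd9(bad)


@given(st.sampled_from(["25000", "401.9", "v700", "E8120", "038", "610.1"]))
def test_normalize_icd9_idempotent(raw):
    once = normalize_icd9(raw)
    assert normalize_icd9(once) == once


# -- phecode map -------------------------------------------------------------

def test_map_lookup_unmapped_code_is_empty(fixture_map):
    assert fixture_map.phecodes_for("999.99") == frozenset()
    assert fixture_map.phecodes_for("not-a-code") == frozenset()


def test_map_rejects_phecode_outside_own_interval():
    with pytest.raises(ValueError):
        PhecodeEntry("250.00", "250.2", "x", "y", 300.0, 310.0)


def test_map_rejects_inconsistent_metadata():
    rows = [
        PhecodeEntry("401.1", "401.1", "HTN", "circ", 401, 405, "none"),
        PhecodeEntry("401.9", "401.1", "HTN", "circ", 400, 406, "none"),
    ]
    with pytest.raises(ValueError):
        PhecodeMap(rows)


def test_map_csv_round_trip(fixture_map, tmp_path):
    path = tmp_path / "map.csv"
    fixture_map.to_csv(path)
    again = PhecodeMap.from_csv(path)
    assert again.phecodes == fixture_map.phecodes
    assert again.info("610.1") == fixture_map.info("610.1")


# -- assign_status: the case/control/exclusion rules -------------------------

def test_two_codes_on_different_days_is_case(fixture_map):
    ev = events_frame([("p", "2010-01-01", "278.00"), ("p", "2010-02-01", "278.00")])
    assert assign_status(ev, "278.1", fixture_map) == Status.CASE


def test_same_day_mentions_are_excluded_not_case(fixture_map):
    ev = events_frame([("p", "2010-01-01", "278.00"), ("p", "2010-01-01", "278.00")])
    assert assign_status(ev, "278.1", fixture_map) == Status.EXCLUDED


def test_single_mention_is_excluded(fixture_map):
    ev = events_frame([("p", "2010-01-01", "278.00")])
    assert assign_status(ev, "278.1", fixture_map) == Status.EXCLUDED


def test_no_related_codes_is_control(fixture_map):
    ev = events_frame([("p", "2010-01-01", "401.9"), ("p", "2010-02-01", "401.9")])
    assert assign_status(ev, "278.1", fixture_map) == Status.CONTROL


def test_exclusion_interval_removes_related_disease_from_controls(fixture_map):
    # morbid obesity mentions land inside the obesity exclusion range 270-279.99
    ev = events_frame([("p", "2010-01-01", "278.01"), ("p", "2010-02-01", "278.01")])
    assert assign_status(ev, "278.1", fixture_map) == Status.EXCLUDED


def test_two_different_codes_same_phecode_count_as_case(fixture_map):
    # distinct-date criterion applies at the phecode level
    ev = events_frame([("p", "2010-01-01", "250.00"), ("p", "2010-03-01", "250.02")])
    assert assign_status(ev, "250.2", fixture_map) == Status.CASE


def test_sex_restriction_excludes_conflicting_sex(fixture_map):
    ev = events_frame([("p", "2010-01-01", "401.9")])
    assert assign_status(ev, "610.1", fixture_map, sex="M") == Status.EXCLUDED
    assert assign_status(ev, "610.1", fixture_map, sex="F") == Status.CONTROL
    assert assign_status(ev, "610.1", fixture_map, sex="") == Status.CONTROL


def test_unknown_phecode_raises_named_error(fixture_map):
    with pytest.raises(UnknownPhecodeError, match="123.4"):
        assign_status(events_frame([]), "123.4", fixture_map)


@given(st.permutations(range(4)), st.integers(1, 3))
def test_status_invariant_under_reordering_and_duplication(fixture_map, order, dup):
    rows = [("p", "2010-01-01", "278.00"), ("p", "2010-01-15", "278.01"),
            ("p", "2010-02-01", "401.9"), ("p", "2010-01-01", "278.00")]
    shuffled = [rows[i] for i in order] * dup
    base = assign_status(events_frame(rows), "278.1", fixture_map)
    assert assign_status(events_frame(shuffled), "278.1", fixture_map) == base


# -- matrix building ---------------------------------------------------------

def _demo(ids, sex="F"):
    return pd.DataFrame({"person_id": ids, "sex": [sex] * len(ids)})


def test_min_cases_filter_drops_sparse_phenotypes(fixture_map):
    rows = []
    for i in range(25):  # 25 obesity cases
        rows += [(f"a{i}", "2010-01-01", "278.00"), (f"a{i}", "2010-02-01", "278.00")]
    for i in range(10):  # 10 T2D cases
        rows += [(f"b{i}", "2010-01-01", "250.00"), (f"b{i}", "2010-02-01", "250.00")]
    ids = [f"a{i}" for i in range(25)] + [f"b{i}" for i in range(10)]
    m = build_phenotype_matrix(events_frame(rows), _demo(ids), fixture_map, min_cases=20)
    assert m.phecodes == ["278.1"]
    assert m.case_counts["278.1"] == 25
    m1 = build_phenotype_matrix(events_frame(rows), _demo(ids), fixture_map, min_cases=1)
    assert set(m1.phecodes) == {"278.1", "250.2"}


def test_empty_event_table_gives_empty_matrix(fixture_map):
    m = build_phenotype_matrix(events_frame([]), _demo(["p1", "p2"]), fixture_map, 1)
    assert m.phecodes == []
    assert m.individuals == ["p1", "p2"]


def test_matrix_agrees_with_per_person_assignment(small_study):
    """The vectorized matrix builder must match the single-person rule
    implementation cell for cell."""
    from phewaskit.synthetic_data import build_sim_map

    bundle = small_study
    c = bundle.cohorts[0]
    pmap = bundle.pmap
    matrix = build_phenotype_matrix(c.events, c.demographics, pmap, min_cases=1)
    sexes = c.demographics.set_index("person_id")["sex"]
    rng = np.random.default_rng(0)
    people = rng.choice(matrix.individuals, 30, replace=False)
    by_person = dict(tuple(c.events.groupby("person_id")))
    empty = c.events.iloc[0:0]
    for person in people:
        ev = by_person.get(person, empty)
        for phe in matrix.phecodes:
            expected = assign_status(ev, phe, pmap, sex=sexes[person])
            assert matrix.status.loc[person, phe] == expected, (person, phe)


def test_controls_never_carry_codes_in_exclusion_interval(small_study):
    bundle = small_study
    c = bundle.cohorts[0]
    pmap = bundle.pmap
    matrix = build_phenotype_matrix(c.events, c.demographics, pmap, min_cases=1)
    ev = c.events.copy()
    ev["phecodes"] = ev["icd9"].map(pmap.phecodes_for)
    ev = ev.explode("phecodes").dropna(subset=["phecodes"])
    ev["value"] = ev["phecodes"].astype(float)
    carried = ev.groupby("person_id")["value"].agg(set)
    for phe in matrix.phecodes:
        info = pmap.info(phe)
        controls = matrix.status.index[matrix.status[phe] == Status.CONTROL]
        for person in controls:
            vals = carried.get(person, set())
            assert not any(info.exclusion_lo <= v <= info.exclusion_hi for v in vals)


def test_case_counts_match_planted_truth(small_study):
    """Retained phenotypes equal those whose planted case counts clear the
    threshold, and per-column case counts equal the brute-force truth."""
    bundle = small_study
    c = bundle.cohorts[0]
    matrix = build_phenotype_matrix(c.events, c.demographics, bundle.pmap, min_cases=20)
    truth_counts = c.truth_cases.sum()
    assert set(matrix.phecodes) == set(truth_counts.index[truth_counts >= 20])
    for phe in matrix.phecodes:
        assert matrix.case_counts[phe] == truth_counts[phe]


# -- composites --------------------------------------------------------------

def _matrix_from_dict(d):
    from phewaskit.phenome_map import PhenotypeMatrix

    return PhenotypeMatrix(pd.DataFrame(d, dtype="int8"))


def test_composite_rules():
    m = _matrix_from_dict({
        "041.1": [1, 0, -1, 0],
        "041.2": [0, 0, 0, 1],
    })
    comp = make_composite(["041.1", "041.2"], m)
    assert list(comp) == [Status.CASE, Status.CONTROL, Status.EXCLUDED, Status.CASE]


def test_composite_of_single_phenotype_is_identity():
    m = _matrix_from_dict({"041.1": [1, 0, -1]})
    assert list(make_composite(["041.1"], m)) == [1, 0, -1]


def test_composite_errors():
    m = _matrix_from_dict({"041.1": [1, 0]})
    with pytest.raises(ValueError):
        make_composite([], m)
    with pytest.raises(UnknownPhecodeError):
        make_composite(["041.1", "999.9"], m)
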