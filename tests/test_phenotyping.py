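import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from intgen.config import CidiConfig
from intgen.phenotyping import (
    CodeList,
    PhenotypeError,
    classify_definition,
    combine_internalising,
    derive_all,
    load_default_code_lists,
    normalise_code,
    score_cidi_sf,
    score_gad7,
    score_gad7_frame,
    apply_exclusions,
)
from intgen.simulate import PhenotypeRecords


@pytest.fixture(scope="module")
def code_lists():
    return load_default_code_lists()


def make_records(
    n=4,
    availability=None,
    touchscreen=None,
    interview_diag=(),
    interview_med=(),
    ehr=(),
    mhq_items=None,
    mhq_diag=(),
):
    ids = [f"P{i}" for i in range(n)]
    if availability is None:
        availability = {s: [True] * n for s in
                        ("touchscreen", "interview", "hospital", "primary_care", "mhq")}
    avail = pd.DataFrame({"id": ids, **availability})
    if touchscreen is None:
        touchscreen = pd.DataFrame(
            {"id": ids, "seen_gp": 0, "seen_psychiatrist": 0, "low_mood_2wk": 0}
        )
    if mhq_items is None:
        mhq_items = pd.DataFrame({"id": ids})
        for j in range(1, 8):
            mhq_items[f"gad7_i{j}"] = 0
        for c in ("dep_cardinal_mood", "dep_cardinal_anhedonia", "dep_symptom_count",
                  "dep_duration_weeks", "dep_impairment", "gad_worry",
                  "gad_duration_months", "gad_symptom_count"):
            mhq_items[c] = 0
    return PhenotypeRecords(
        availability=avail,
        touchscreen=touchscreen,
        interview_diag=pd.DataFrame(interview_diag, columns=["id", "code"]),
        interview_med=pd.DataFrame(interview_med, columns=["id", "code"]),
        ehr=pd.DataFrame(ehr, columns=["id", "code", "source", "system"]),
        mhq_items=mhq_items,
        mhq_diag=pd.DataFrame(mhq_diag, columns=["id", "code"]),
    )


# --- GAD-7 -----------------------------------------------------------------

def test_gad7_threshold_boundary():
    total, case = score_gad7([3, 3, 3, 1, 0, 0, 0])
    assert total == 10 and case is True
    total, case = score_gad7([3, 3, 3, 0, 0, 0, 0])
    assert total == 9 and case is False


def test_gad7_missing_item_is_missing():
    assert score_gad7([3, 3, np.nan, 0, 0, 0, 0]) == (None, None)


def test_gad7_invalid_values_raise():
    with pytest.raises(PhenotypeError):
        score_gad7([4, 0, 0, 0, 0, 0, 0])
    with pytest.raises(PhenotypeError):
        score_gad7([1.5, 0, 0, 0, 0, 0, 0])
    with pytest.raises(PhenotypeError):
        score_gad7([1, 2, 3])


@settings(max_examples=100, deadline=None)
@given(st.lists(st.integers(min_value=0, max_value=3), min_size=7, max_size=7))
def test_gad7_total_is_item_sum(items):
    total, case = score_gad7(items)
    assert total == sum(items)
    assert case == (sum(items) >= 10)


def test_gad7_frame_matches_scalar():
    rows = [[3, 3, 3, 1, 0, 0, 0], [0, 1, 0, 2, 0, 0, 1], [np.nan] * 7]
    df = pd.DataFrame(rows, columns=[f"gad7_i{j}" for j in range(1, 8)])
    out = score_gad7_frame(df)
    assert out["gad7_total"].tolist()[:2] == [10, 4]
    assert np.isnan(out["gad7_total"].iloc[2])
    assert out["gad7_case"].tolist() == [True, False, pd.NA]


# --- CIDI-SF ---------------------------------------------------------------

def _cidi_row(**kwargs):
    base = dict(
        dep_cardinal_mood=1, dep_cardinal_anhedonia=0, dep_symptom_count=5,
        dep_duration_weeks=2, dep_impairment=1,
        gad_worry=1, gad_duration_months=6, gad_symptom_count=3,
    )
    base.update(kwargs)
    return base


def test_cidi_mdd_full_criteria_case():
    out = score_cidi_sf(pd.DataFrame([_cidi_row()]))
    assert bool(out["cidi_mdd"].iloc[0]) and bool(out["cidi_gad"].iloc[0])


def test_cidi_cardinal_gate():
    # all non-cardinal criteria met but no cardinal symptom: non-case
    out = score_cidi_sf(pd.DataFrame(
        [_cidi_row(dep_cardinal_mood=0, dep_cardinal_anhedonia=0, dep_symptom_count=9)]
    ))
    assert not bool(out["cidi_mdd"].iloc[0])


def test_cidi_boundaries():
    assert not bool(score_cidi_sf(pd.DataFrame([_cidi_row(dep_symptom_count=4)]))["cidi_mdd"].iloc[0])
    assert not bool(score_cidi_sf(pd.DataFrame([_cidi_row(dep_duration_weeks=1)]))["cidi_mdd"].iloc[0])
    assert not bool(score_cidi_sf(pd.DataFrame([_cidi_row(dep_impairment=0)]))["cidi_mdd"].iloc[0])
    assert not bool(score_cidi_sf(pd.DataFrame([_cidi_row(gad_duration_months=5)]))["cidi_gad"].iloc[0])
    assert not bool(score_cidi_sf(pd.DataFrame([_cidi_row(gad_symptom_count=2)]))["cidi_gad"].iloc[0])


def test_cidi_impairment_optional_when_configured():
    row = _cidi_row(dep_impairment=0)
    relaxed = CidiConfig(mdd_require_impairment=False)
    assert bool(score_cidi_sf(pd.DataFrame([row]), relaxed)["cidi_mdd"].iloc[0])


def test_cidi_missing_item_is_missing_not_control():
    out = score_cidi_sf(pd.DataFrame([_cidi_row(dep_duration_weeks=np.nan)]))
    assert out["cidi_mdd"].isna().iloc[0]


# --- code lists ------------------------------------------------------------

def test_normalise_code_strips_dots_and_case():
    assert normalise_code(" f32.1 ") == "F321"


def test_duplicate_code_entries_raise():
    t = pd.DataFrame(
        {"code": ["X1", "x1."], "system": ["s", "s"],
         "disorder": ["mood", "mood"], "source": ["hospital", "hospital"]}
    )
    with pytest.raises(PhenotypeError):
        CodeList(t)


def test_prefix_matching_mode():
    t = pd.DataFrame(
        {"code": ["F32"], "system": ["icd"], "disorder": ["mood"], "source": ["hospital"]}
    )
    exact = CodeList(t)
    pref = CodeList(t, prefix=True)
    codes = pd.Series(["F32.4", "F33.0"])
    assert exact.match(codes, "mood", "hospital").tolist() == [False, False]
    assert pref.match(codes, "mood", "hospital").tolist() == [True, False]


# --- classification ---------------------------------------------------------

def test_unknown_definition_and_disorder_raise(code_lists):
    rec = make_records()
    with pytest.raises(PhenotypeError):
        classify_definition(rec, "not_a_definition", "mood", code_lists)
    with pytest.raises(PhenotypeError):
        classify_definition(rec, "hospital", "psychosis", code_lists)


def test_initial_self_report_case_control_missing(code_lists):
    rec = make_records(
        n=3,
        availability={"touchscreen": [True] * 3, "interview": [True, True, False],
                      "hospital": [True] * 3, "primary_care": [True] * 3,
                      "mhq": [True] * 3},
        interview_diag=[("P0", "SR_DEPRESSION")],
    )
    s = classify_definition(rec, "initial_self_report", "mood", code_lists)
    assert s["P0"] == "case" and s["P1"] == "control" and s["P2"] == "missing"


def test_temazepam_does_not_qualify_for_anxiety(code_lists):
    rec = make_records(
        n=3,
        interview_med=[("P0", "MED_TEMAZEPAM"), ("P1", "MED_DIAZEPAM")],
    )
    anx = classify_definition(rec, "medication_self_report", "anxiety", code_lists)
    assert anx["P0"] == "control"   # temazepam alone never qualifies
    assert anx["P1"] == "case"
    mood = classify_definition(rec, "medication_self_report", "mood", code_lists)
    assert mood["P1"] == "control"  # benzodiazepines do not define mood disorder


def test_help_seeking_identical_across_disorders(code_lists):
    ts = pd.DataFrame(
        {"id": ["P0", "P1", "P2", "P3"], "seen_gp": [1, 0, 0, 0],
         "seen_psychiatrist": [0, 1, 0, 0], "low_mood_2wk": [0, 0, 0, 0]}
    )
    rec = make_records(n=4, touchscreen=ts)
    s_mood = classify_definition(rec, "help_seeking", "mood", code_lists)
    s_anx = classify_definition(rec, "help_seeking", "anxiety", code_lists)
    s_int = classify_definition(rec, "help_seeking", "internalising", code_lists)
    assert s_mood.equals(s_anx) and s_mood.equals(s_int)
    assert s_mood.tolist() == ["case", "case", "control", "control"]


def test_minimal_mood_needs_help_seeking_and_low_mood(code_lists):
    ts = pd.DataFrame(
        {"id": ["P0", "P1", "P2"], "seen_gp": [1, 1, 0],
         "seen_psychiatrist": [0, 0, 0], "low_mood_2wk": [1, 0, 1]}
    )
    rec = make_records(n=3, touchscreen=ts)
    s = classify_definition(rec, "minimal", "mood", code_lists)
    assert s.tolist() == ["case", "control", "control"]


def test_hospital_code_match_and_source_separation(code_lists):
    rec = make_records(
        n=3,
        ehr=[("P0", "F32.1", "hospital", "icd10-like"),
             ("P1", "E112.", "primary_care", "read-like")],
    )
    hosp = classify_definition(rec, "hospital", "mood", code_lists)
    pc = classify_definition(rec, "primary_care", "mood", code_lists)
    assert hosp["P0"] == "case" and hosp["P1"] == "control"
    assert pc["P1"] == "case" and pc["P0"] == "control"


def test_union_combination_rules():
    idx = pd.Index(["a", "b", "c", "d", "e"], name="id")
    mood = pd.Series(["case", "control", "control", "missing", "missing"], index=idx)
    anx = pd.Series(["missing", "case", "control", "control", "missing"], index=idx)
    out = combine_internalising(mood, anx)
    assert out.tolist() == ["case", "case", "control", "missing", "missing"]


def test_exclusions_across_sources(code_lists):
    rec = make_records(
        n=4,
        interview_diag=[("P0", "SR_SCHIZOPHRENIA")],
        ehr=[("P1", "F20.0", "hospital", "icd10-like"),
             ("P2", "EU20.", "primary_care", "read-like")],
        mhq_diag=[("P3", "MHQ_BIPOLAR")],
    )
    assert apply_exclusions(rec, code_lists) == {"P0", "P1", "P2", "P3"}
    flags = derive_all(rec, code_lists)
    assert set(flags["id"]) == set()  # everyone excluded in this toy cohort


def test_derive_all_long_format(code_lists):
    rec = make_records(n=2)
    flags = derive_all(rec, code_lists)
    assert set(flags.columns) == {"id", "definition", "disorder", "status"}
    assert len(flags) == 2 * 8 * 3
    assert set(flags["status"]) <= {"case", "control", "missing"}
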