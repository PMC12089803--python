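"""Case/control/missing derivation for eight definitions of mood, anxiety and
internalising disorder from raw multi-source records.

The eight definitions:

1.  ``initial_self_report``   — diagnosis reported at the nurse interview
2.  ``medication_self_report``— current psychotropic medication at interview
    (any antidepressant for mood; antidepressant and/or benzodiazepine apart
    from temazepam for anxiety)
3.  ``help_seeking``          — ever seen a GP or a psychiatrist for
    depression, tension or nerves (asked once; identical for all disorders)
4.  ``minimal``               — broad probable mood disorder (help-seeking
    plus a two-week low-mood item) for mood; help-seeking plus GAD-7 >= 10
    for anxiety
5.  ``cidi_sf``               — short-form diagnostic interview criteria for
    lifetime major depression / lifetime generalised anxiety disorder
6.  ``mhq_self_report``       — self-reported diagnosis in the online
    mental-health questionnaire
7.  ``hospital``              — admission-record code-list match
8.  ``primary_care``          — primary-care code-list match

An individual is *control* for a definition only when its defining source is
available and no qualifying record exists; unavailable source means
*missing*.  Internalising disorder is the union: case if either component is
a case; control only when both components are observed controls.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .config import CidiConfig, DEFINITIONS, DISORDERS

STATUS = ("case", "control", "missing")

GAD7_ITEMS = [f"gad7_i{j}" for j in range(1, 8)]
GAD7_CASE_THRESHOLD = 10

CIDI_MDD_ITEMS = [
    "dep_cardinal_mood", "dep_cardinal_anhedonia", "dep_symptom_count",
    "dep_duration_weeks", "dep_impairment",
]
CIDI_GAD_ITEMS = ["gad_worry", "gad_duration_months", "gad_symptom_count"]


class PhenotypeError(ValueError):
    """Unknown definition/disorder or malformed inputs."""


def normalise_code(code: str) -> str:
    """Exact-match normal form: dots stripped, upper-cased."""
    return str(code).replace(".", "").strip().upper()


@dataclass
class CodeList:
    """Clinical code lists: (code, coding-system, disorder, source) entries.

    ``disorder`` is one of mood/anxiety/exclusion; ``source`` names the record
    stream the code appears in.  Matching is exact on the normalised code;
    ``prefix=True`` enables hierarchical prefix matching for ICD-like codes.
    """

    table: pd.DataFrame
    prefix: bool = False

    def __post_init__(self) -> None:
        t = self.table.copy()
        required = {"code", "system", "disorder", "source"}
        if not required.issubset(t.columns):
            raise PhenotypeError(f"code list missing columns {required - set(t.columns)}")
        t["norm"] = t["code"].map(normalise_code)
        dup = t.duplicated(subset=["norm", "system", "disorder", "source"])
        if dup.any():
            raise PhenotypeError(f"{dup.sum()} duplicate code-list entries")
        self.table = t

    def codes(self, disorder: str | None = None, source: str | None = None) -> frozenset[str]:
        t = self.table
        if disorder is not None:
            t = t[t["disorder"] == disorder]
        if source is not None:
            t = t[t["source"] == source]
        return frozenset(t["norm"])

    def match(self, codes: pd.Series, disorder: str, source: str) -> pd.Series:
        """Boolean mask over ``codes`` for membership in the selected list."""
        wanted = self.codes(disorder, source)
        norm = codes.map(normalise_code)
        hit = norm.isin(wanted)
        if self.prefix and wanted:
            prefixes = tuple(wanted)
            hit = hit | norm.map(lambda c: c.startswith(prefixes))
        return hit


def load_code_lists(path, prefix: bool = False) -> CodeList:
    return CodeList(pd.read_csv(path, keep_default_na=False), prefix=prefix)


def load_default_code_lists() -> CodeList:
    """Toy code lists shipped with the package (the licensed curated lists
    the field uses are not redistributable)."""
    with resources.files("intgen.data").joinpath("code_lists.csv").open() as fh:
        return CodeList(pd.read_csv(fh, keep_default_na=False))


# ---------------------------------------------------------------------------
# questionnaire scoring
# ---------------------------------------------------------------------------

def score_gad7(items) -> tuple[int | None, bool | None]:
    """Total of the seven 0-3 anxiety-severity items; case at >= 10.

    Any missing item makes the score (and case flag) missing.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (7,):
        raise PhenotypeError(f"GAD-7 needs exactly 7 items, got shape {arr.shape}")
    if np.isnan(arr).any():
        return None, None
    if ((arr < 0) | (arr > 3) | (arr != np.round(arr))).any():
        raise PhenotypeError("GAD-7 items must be integers in 0..3")
    total = int(arr.sum())
    return total, total >= GAD7_CASE_THRESHOLD


def score_gad7_frame(items: pd.DataFrame) -> pd.DataFrame:
    """Vectorised GAD-7 scoring over a DataFrame with columns gad7_i1..i7."""
    arr = items[GAD7_ITEMS].to_numpy(dtype=float)
    ok = ~np.isnan(arr).any(axis=1)
    valid = arr[ok]
    if valid.size and ((valid < 0) | (valid > 3) | (valid != np.round(valid))).any():
        raise PhenotypeError("GAD-7 items must be integers in 0..3")
    total = arr.sum(axis=1)
    out = pd.DataFrame(index=items.index)
    out["gad7_total"] = np.where(ok, total, np.nan)
    out["gad7_case"] = pd.array(
        np.where(ok, total >= GAD7_CASE_THRESHOLD, None), dtype="boolean"
    )
    return out


def score_cidi_sf(responses: pd.DataFrame, criteria: CidiConfig | None = None) -> pd.DataFrame:
    """Lifetime major-depression and generalised-anxiety flags from
    short-form diagnostic interview items.

    MDD: at least one cardinal symptom (depressed mood or anhedonia) AND
    symptom count >= ``mdd_min_symptoms`` AND episode duration >=
    ``mdd_min_duration_weeks`` weeks AND (optionally) impairment.
    GAD: excessive worry AND duration >= ``gad_min_duration_months`` months
    AND associated symptom count >= ``gad_min_symptoms``.

    Missing required items yield a missing flag (never a control).
    """
    c = criteria or CidiConfig()

    def _flag(cols: list[str], rule) -> pd.array:
        sub = responses.reindex(columns=cols)
        arr = sub.to_numpy(dtype=float)
        complete = ~np.isnan(arr).any(axis=1)
        vals = rule(sub.fillna(0))
        return pd.array(np.where(complete, vals, None), dtype="boolean")

    def _mdd(sub: pd.DataFrame) -> np.ndarray:
        cardinal = (sub["dep_cardinal_mood"] > 0) | (sub["dep_cardinal_anhedonia"] > 0)
        ok = (
            cardinal
            & (sub["dep_symptom_count"] >= c.mdd_min_symptoms)
            & (sub["dep_duration_weeks"] >= c.mdd_min_duration_weeks)
        )
        if c.mdd_require_impairment:
            ok &= sub["dep_impairment"] > 0
        return ok.to_numpy()

    def _gad(sub: pd.DataFrame) -> np.ndarray:
        return (
            (sub["gad_worry"] > 0)
            & (sub["gad_duration_months"] >= c.gad_min_duration_months)
            & (sub["gad_symptom_count"] >= c.gad_min_symptoms)
        ).to_numpy()

    out = pd.DataFrame(index=responses.index)
    out["cidi_mdd"] = _flag(CIDI_MDD_ITEMS, _mdd)
    out["cidi_gad"] = _flag(CIDI_GAD_ITEMS, _gad)
    return out


# ---------------------------------------------------------------------------
# definition classification
# ---------------------------------------------------------------------------

def _status_series(ids: np.ndarray, case: np.ndarray, available: np.ndarray) -> pd.Series:
    status = np.where(available, np.where(case, "case", "control"), "missing")
    return pd.Series(status, index=pd.Index(ids, name="id"), name="status")


def _ids_with_code_match(
    records, table_name: str, code_lists: CodeList, disorder: str, source: str,
    source_filter: str | None = None, exclude_codes: frozenset[str] = frozenset(),
) -> set:
    table = getattr(records, table_name)
    if table.empty:
        return set()
    t = table
    if source_filter is not None:
        t = t[t["source"] == source_filter]
    hit = code_lists.match(t["code"], disorder, source)
    if exclude_codes:
        hit &= ~t["code"].map(normalise_code).isin(exclude_codes)
    return set(t.loc[hit, "id"])


def _help_seeking_case(records) -> pd.Series:
    ts = records.touchscreen.set_index("id")
    return (ts["seen_gp"] > 0) | (ts["seen_psychiatrist"] > 0)


def classify_definition(
    records,
    definition: str,
    disorder: str,
    code_lists: CodeList,
    cidi_config: CidiConfig | None = None,
) -> pd.Series:
    """Status (case/control/missing) for one definition and disorder across
    the whole cohort.  See the module docstring for the eight rules."""
    if definition not in DEFINITIONS:
        raise PhenotypeError(f"unknown definition {definition!r}")
    if disorder not in DISORDERS:
        raise PhenotypeError(f"unknown disorder {disorder!r}")

    avail = records.availability.set_index("id")
    ids = avail.index.to_numpy()

    if definition == "help_seeking":
        # asked once about either disorder; identical for mood/anxiety/internalising
        a = avail["touchscreen"].to_numpy()
        hs = _help_seeking_case(records).reindex(avail.index).fillna(False).to_numpy()
        return _status_series(ids, hs, a)

    if disorder == "internalising":
        mood = classify_definition(records, definition, "mood", code_lists, cidi_config)
        anx = classify_definition(records, definition, "anxiety", code_lists, cidi_config)
        return combine_internalising(mood, anx)

    if definition == "initial_self_report":
        a = avail["interview"].to_numpy()
        case_ids = _ids_with_code_match(records, "interview_diag", code_lists, disorder, "interview")
        case = np.isin(ids, list(case_ids))
        return _status_series(ids, case, a)

    if definition == "medication_self_report":
        a = avail["interview"].to_numpy()
        # the temazepam exception: a temazepam-only prescription never
        # qualifies for the anxiety definition
        excl = frozenset({"MED_TEMAZEPAM"}) if disorder == "anxiety" else frozenset()
        case_ids = _ids_with_code_match(
            records, "interview_med", code_lists, disorder, "medication", exclude_codes=excl
        )
        case = np.isin(ids, list(case_ids))
        return _status_series(ids, case, a)

    if definition == "minimal":
        hs = _help_seeking_case(records).reindex(avail.index).fillna(False).to_numpy()
        if disorder == "mood":
            # broad probable-mood-disorder rule: help-seeking plus a
            # two-week low-mood/anhedonia touchscreen item
            a = avail["touchscreen"].to_numpy()
            ts = records.touchscreen.set_index("id")
            low = (ts["low_mood_2wk"] > 0).reindex(avail.index).fillna(False).to_numpy()
            return _status_series(ids, hs & low, a)
        scored = score_gad7_frame(records.mhq_items.set_index("id"))
        gcase = scored["gad7_case"].reindex(avail.index)
        a = (
            avail["touchscreen"].to_numpy()
            & avail["mhq"].to_numpy()
            & gcase.notna().to_numpy()
        )
        case = hs & gcase.fillna(False).to_numpy()
        return _status_series(ids, case, a)

    if definition == "cidi_sf":
        scored = score_cidi_sf(records.mhq_items.set_index("id"), cidi_config)
        col = "cidi_mdd" if disorder == "mood" else "cidi_gad"
        flag = scored[col].reindex(avail.index)
        a = avail["mhq"].to_numpy() & flag.notna().to_numpy()
        return _status_series(ids, flag.fillna(False).to_numpy(), a)

    if definition == "mhq_self_report":
        a = avail["mhq"].to_numpy()
        case_ids = _ids_with_code_match(records, "mhq_diag", code_lists, disorder, "mhq")
        case = np.isin(ids, list(case_ids))
        return _status_series(ids, case, a)

    if definition in ("hospital", "primary_care"):
        a = avail[definition].to_numpy()
        case_ids = _ids_with_code_match(
            records, "ehr", code_lists, disorder, definition, source_filter=definition
        )
        case = np.isin(ids, list(case_ids))
        return _status_series(ids, case, a)

    raise PhenotypeError(f"unhandled definition {definition!r}")  # pragma: no cover


def combine_internalising(mood: pd.Series, anxiety: pd.Series) -> pd.Series:
    """Union phenotype: case if either component is a case; control only when
    both components are observed controls; otherwise missing.

    A (control, missing) pair is missing, not control — the unavailable
    source could harbour the qualifying record.
    """
    if not mood.index.equals(anxiety.index):
        anxiety = anxiety.reindex(mood.index)
    m = mood.to_numpy()
    a = anxiety.to_numpy()
    out = np.where(
        (m == "case") | (a == "case"),
        "case",
        np.where((m == "control") & (a == "control"), "control", "missing"),
    )
    return pd.Series(out, index=mood.index, name="status")


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(records, code_lists: CodeList) -> set:
    """Ids with a schizophrenia/bipolar exclusion code in the EHR, at the
    nurse interview, or in the online questionnaire."""
    excluded: set = set()
    for source in ("hospital", "primary_care"):
        excluded |= _ids_with_code_match(
            records, "ehr", code_lists, "exclusion", source, source_filter=source
        )
    excluded |= _ids_with_code_match(records, "interview_diag", code_lists, "exclusion", "interview")
    excluded |= _ids_with_code_match(records, "mhq_diag", code_lists, "exclusion", "mhq")
    return excluded


# ---------------------------------------------------------------------------
# cohort-level derivation and reporting
# ---------------------------------------------------------------------------

def derive_all(
    records,
    code_lists: CodeList | None = None,
    definitions=DEFINITIONS,
    cidi_config: CidiConfig | None = None,
    exclude: bool = True,
) -> pd.DataFrame:
    """Long-format flags (id, definition, disorder, status) for every
    definition and disorder, with excluded individuals removed."""
    code_lists = code_lists or load_default_code_lists()
    excluded = apply_exclusions(records, code_lists) if exclude else set()
    frames = []
    for definition in definitions:
        for disorder in DISORDERS:
            s = classify_definition(records, definition, disorder, code_lists, cidi_config)
            if excluded:
                s = s[~s.index.isin(excluded)]
            frames.append(
                pd.DataFrame(
                    {
                        "id": s.index,
                        "definition": definition,
                        "disorder": disorder,
                        "status": s.to_numpy(),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def prevalence_report(flags: pd.DataFrame, gender: pd.Series | None = None) -> pd.DataFrame:
    """Cases, controls and prevalence per (definition, disorder); missing
    individuals are excluded from the denominator.  With a gender series
    (1=female, indexed by id), female/male prevalences are added."""
    rows = []
    for (definition, disorder), grp in flags.groupby(["definition", "disorder"], sort=False):
        n_case = int((grp["status"] == "case").sum())
        n_control = int((grp["status"] == "control").sum())
        n_missing = int((grp["status"] == "missing").sum())
        denom = n_case + n_control
        row = {
            "definition": definition,
            "disorder": disorder,
            "n_case": n_case,
            "n_control": n_control,
            "n_missing": n_missing,
            "prevalence_pct": 100.0 * n_case / denom if denom else np.nan,
        }
        if gender is not None:
            g = gender.reindex(grp["id"]).to_numpy()
            for label, sel in (("female", g == 1), ("male", g == 0)):
                st = grp["status"].to_numpy()[sel]
                nc, nk = int((st == "case").sum()), int((st == "control").sum())
                row[f"prevalence_{label}_pct"] = 100.0 * nc / (nc + nk) if nc + nk else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
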