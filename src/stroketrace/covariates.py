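"""Covariate derivation for index strokes.

All covariates are strictly pre-index: condition flags use records from
birth to the day before the index stroke, measurements use primary-care
values from 2 years to 1 day before the index and inside configured valid
ranges, and demographics take the most recent non-missing value across
primary and secondary care with primary care breaking date ties.
"""

from __future__ import annotations

import importlib.resources
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

MEASUREMENT_WINDOW_DAYS = 730  # 2 years
CHARLSON_CATEGORIES = ("0", "1-2", "3-4", "5+")

#: coarse age bands used for reporting and home-time stratification
REPORT_BANDS = ((15, 59, "15-59"), (60, 69, "60-69"), (70, 79, "70-79"),
                (80, 89, "80-89"), (90, 200, "90+"))


def _data_path(name):
    return importlib.resources.files("stroketrace.data") / name


def condition_codes() -> dict:
    """Per-condition (snomed, icd10-or-None) toy codes from the shipped codelist."""
    df = pd.read_csv(_data_path("codelist_conditions.csv"), dtype=str)
    out = {}
    for cond, grp in df.groupby("condition"):
        snomed = grp.loc[grp["coding_system"] == "snomed", "code"]
        icd10 = grp.loc[grp["coding_system"] == "icd10", "code"]
        out[cond] = (snomed.iloc[0] if len(snomed) else None,
                     icd10.iloc[0] if len(icd10) else None)
    return out


def load_condition_codelist(path=None) -> pd.DataFrame:
    path = path or _data_path("codelist_conditions.csv")
    return pd.read_csv(path, dtype=str)


def load_measurement_ranges(path=None) -> dict:
    path = path or _data_path("measurement_ranges.yaml")
    with open(path) as fh:
        return yaml.safe_load(fh)


def report_age_band(age: int) -> str:
    for lo, hi, label in REPORT_BANDS:
        if lo <= age <= hi:
            return label
    return "15-59"  # adults under 18 do not occur in the cohort


# ----------------------------------------------------------------------


def resolve_demographic(candidates) -> object:
    """Most recent non-missing value across sources; primary care wins ties.

    ``candidates`` is an iterable of (record_date, source, value); missing
    values are None/NaN/"".  Returns "unknown" when nothing usable exists.
    Order of the input never matters.
    """
    def usable(v):
        return v is not None and v == v and v != ""

    best = None
    for rec_date, source, value in candidates:
        if not usable(value):
            continue
        primary = 1 if source == "gdppr" else 0
        key = (rec_date, primary)
        if best is None or key > best[0]:
            best = (key, value)
    return best[1] if best is not None else "unknown"


def imd_quintile(lsoa: str, lookup: dict) -> object:
    """Deprivation quintile (1 = most deprived) from the LSOA lookup."""
    return lookup.get(lsoa, "unknown")


def comorbidity_flags(gdppr: pd.DataFrame, hes: pd.DataFrame,
                      index_dates: pd.Series,
                      codelist: pd.DataFrame | None = None) -> pd.DataFrame:
    """Prevalent-condition flags per person, one column per condition.

    A flag is true iff a matching code is dated in [birth, index - 1 day].
    GDPPR matches SNOMED exactly; HES matches ICD-10 by prefix on the
    primary diagnosis.  Hypercholesterolaemia is defined from GDPPR alone.
    """
    codelist = codelist if codelist is not None else load_condition_codelist()
    conditions = sorted(codelist["condition"].unique())
    idx = index_dates  # Series person_id -> Timestamp

    g = gdppr[gdppr["person_id"].isin(idx.index)].copy()
    g["date"] = pd.to_datetime(g["record_date"])
    g = g[g["date"] < g["person_id"].map(idx)]  # strictly before index day

    h = hes[hes["person_id"].isin(idx.index)].copy()
    h["date"] = pd.to_datetime(h["admission_date"])
    h = h[h["date"] < h["person_id"].map(idx)]

    out = pd.DataFrame(False, index=idx.index, columns=conditions)
    out.index.name = "person_id"
    for cond in conditions:
        rows = codelist[codelist["condition"] == cond]
        snomed = set(rows.loc[rows["coding_system"] == "snomed", "code"])
        icd10 = tuple(rows.loc[rows["coding_system"] == "icd10", "code"])
        hit = set()
        if snomed:
            hit |= set(g.loc[g["snomed_code"].astype(str).isin(snomed), "person_id"])
        if icd10 and cond != "hypercholesterolaemia":
            mask = h["primary_icd10"].astype(str).str.startswith(icd10)
            hit |= set(h.loc[mask, "person_id"])
        out.loc[out.index.isin(hit), cond] = True
    return out


# ----------------------------------------------------------------------
# Charlson comorbidity index (Quan 2005 ICD-10 mapping, original weights)

_EXCLUSIVE = {  # the severe form supersedes the mild one
    "severe_liver": "mild_liver",
    "diabetes_complicated": "diabetes_uncomplicated",
    "metastatic": "malignancy",
}


def load_charlson_map(path=None) -> pd.DataFrame:
    path = path or _data_path("charlson_quan2005.csv")
    return pd.read_csv(path, dtype={"icd10_prefix": str})


def charlson_score(icd10_codes, mapping: pd.DataFrame | None = None) -> int:
    """Weighted Charlson score from a person's ICD-10 history.

    Each comorbidity category counts once; hierarchical pairs (mild vs
    severe liver disease, un/complicated diabetes, malignancy vs
    metastases) count only the severe form.
    """
    mapping = mapping if mapping is not None else load_charlson_map()
    cats = set()
    codes = [str(c).replace(".", "") for c in icd10_codes]
    for row in mapping.itertuples():
        if any(c.startswith(row.icd10_prefix) for c in codes):
            cats.add((row.category, row.weight))
    present = {c for c, _ in cats}
    total = 0
    for cat, w in cats:
        # skip the mild member when its severe counterpart is present
        if cat in _EXCLUSIVE.values():
            severe = next(k for k, v in _EXCLUSIVE.items() if v == cat)
            if severe in present:
                continue
        total += w
    return total


def charlson_category(icd10_codes, mapping: pd.DataFrame | None = None) -> str:
    """Charlson score binned to the reporting categories 0 / 1-2 / 3-4 / 5+."""
    s = charlson_score(icd10_codes, mapping)
    if s == 0:
        return "0"
    if s <= 2:
        return "1-2"
    if s <= 4:
        return "3-4"
    return "5+"


def charlson_categories_frame(hes: pd.DataFrame, index_dates: pd.Series,
                              mapping: pd.DataFrame | None = None) -> pd.Series:
    """Vectorised Charlson category per person from pre-index HES diagnoses."""
    mapping = mapping if mapping is not None else load_charlson_map()
    h = hes[hes["person_id"].isin(index_dates.index)].copy()
    h["date"] = pd.to_datetime(h["admission_date"])
    h = h[h["date"] < h["person_id"].map(index_dates)]
    codes = h.groupby("person_id")["primary_icd10"].agg(list)
    out = pd.Series("0", index=index_dates.index, name="charlson_category")
    for pid, lst in codes.items():
        out.loc[pid] = charlson_category(lst, mapping)
    return out


# ----------------------------------------------------------------------


def extract_measurement(records: pd.DataFrame, name: str, index_date,
                        valid_range: dict | None):
    """Most recent in-window, in-range value of one measurement, or NaN.

    Window is [index - 2 years, index - 1 day]; out-of-range values are
    skipped entirely, never truncated.
    """
    index_date = pd.Timestamp(index_date)
    lo = index_date - pd.Timedelta(days=MEASUREMENT_WINDOW_DAYS)
    r = records[records["name"] == name].copy()
    r["date"] = pd.to_datetime(r["date"])
    r = r[(r["date"] >= lo) & (r["date"] < index_date)]
    if valid_range is not None:
        vals = pd.to_numeric(r["value"], errors="coerce")
        r = r[(vals >= valid_range["min"]) & (vals <= valid_range["max"])]
    if r.empty:
        return np.nan
    return r.sort_values("date").iloc[-1]["value"]


def measurements_frame(measurements: pd.DataFrame, index_dates: pd.Series,
                       ranges: dict | None = None) -> pd.DataFrame:
    """Vectorised most-recent in-window, in-range value per person and name."""
    ranges = ranges if ranges is not None else load_measurement_ranges()
    m = measurements[measurements["person_id"].isin(index_dates.index)].copy()
    m["date"] = pd.to_datetime(m["date"])
    idx = m["person_id"].map(index_dates)
    m = m[(m["date"] < idx) & (m["date"] >= idx - pd.Timedelta(days=MEASUREMENT_WINDOW_DAYS))]
    numeric = pd.to_numeric(m["value"], errors="coerce")
    keep = pd.Series(True, index=m.index)
    for name, rng in ranges.items():
        sel = (m["name"] == name).to_numpy()
        ok = ((numeric >= rng["min"]) & (numeric <= rng["max"])).to_numpy()
        keep.iloc[sel] = ok[sel]
    m = m[keep]
    m = m.sort_values("date").groupby(["person_id", "name"]).last()["value"]
    return m.unstack("name").reindex(index_dates.index)


# ----------------------------------------------------------------------


def build_covariates(tables: dict, index_strokes: pd.DataFrame,
                     condition_codelist: pd.DataFrame | None = None,
                     ranges: dict | None = None) -> pd.DataFrame:
    """Full covariate table for the index-stroke cohort."""
    idx = index_strokes.set_index("person_id")["index_date"]
    idx = pd.to_datetime(idx)

    persons = tables["persons"].set_index("person_id").reindex(idx.index)
    age = idx.dt.year - persons["birth_year"] - 0.5  # mid-year convention
    age = age.round().astype(int).clip(lower=18)

    lookup = tables["lsoa_imd"].set_index("lsoa")["imd_quintile"].to_dict()
    imd = persons["lsoa"].map(lambda x: imd_quintile(x, lookup) if isinstance(x, str) and x else "unknown")

    eth = persons["ethnicity"].fillna("").replace("", "unknown")

    flags = comorbidity_flags(tables["gdppr"], tables["hes_apc"], idx, condition_codelist)
    charlson = charlson_categories_frame(tables["hes_apc"], idx)
    meas = measurements_frame(tables.get("measurements", pd.DataFrame(
        columns=["person_id", "date", "name", "value"])), idx, ranges)

    covid = tables.get("covid", pd.DataFrame(columns=["person_id", "date"])).copy()
    if len(covid):
        covid["date"] = pd.to_datetime(covid["date"])
        cd = covid.merge(idx.rename("index_date"), left_on="person_id", right_index=True)
        delta = (cd["index_date"] - cd["date"]).dt.days
        recent_ids = set(cd.loc[(delta >= 1) & (delta <= 14), "person_id"])
        hist_ids = set(cd.loc[delta > 14, "person_id"])
    else:
        recent_ids, hist_ids = set(), set()

    out = pd.DataFrame({
        "person_id": idx.index,
        "age": age.values,
        "age_band": [report_age_band(a) for a in age],
        "sex": persons["sex"].values,
        "ethnicity": eth.values,
        "imd_quintile": imd.values,
        "charlson_category": charlson.values,
        "covid_14d": [pid in recent_ids for pid in idx.index],
        "covid_history": [pid in hist_ids for pid in idx.index],
    })
    out = out.merge(flags.reset_index(), on="person_id")
    out = out.merge(meas.reset_index(), on="person_id", how="left")
    return out
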