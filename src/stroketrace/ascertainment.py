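"""Multi-source index-stroke ascertainment.

A person's index stroke is the earliest stroke-coded record across primary
care, hospital admissions, the stroke audit and death registrations.
Records from different sources are treated as the same event when they fall
within a 30-day window *after* the index date (anchored, not transitively
chained).  Persons with any stroke record before the study start are
excluded as prevalent cases.  The index event is fatal when death from any
cause occurs within 30 days (inclusive) of the index date.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .harmonisation import CodeList, map_code, resolve_types_frame

MERGE_WINDOW_DAYS = 30
FATALITY_WINDOW_DAYS = 30

SOURCES = ("gdppr", "hes_apc", "ssnap", "ons")


class DataIntegrityError(ValueError):
    """Raised when linked records are mutually inconsistent (e.g. death before stroke)."""


@dataclass(frozen=True)
class SourceRecord:
    person_id: int
    source: str
    event_date: date
    subtype: str
    raw_code: str = ""


@dataclass
class IndexStroke:
    person_id: int
    index_date: date
    sources: frozenset
    merged_records: list = field(default_factory=list)
    stroke_type: str = "unknown"
    fatal: bool = False


# ----------------------------------------------------------------------
# per-person reference operations


def screen_prevalent(records_by_person: dict, study_start: date) -> set:
    """Persons with any stroke record dated before ``study_start`` are excluded."""
    return {pid for pid, recs in records_by_person.items()
            if not any(r.event_date < study_start for r in recs)}


def find_index_stroke(person_records, window_days: int = MERGE_WINDOW_DAYS):
    """Merge one person's records into their index stroke, or None.

    The index date is the earliest record date; records within
    ``window_days`` days after it (inclusive) merge into the event, one
    record per source per date.  Later records are dropped (no recurrent
    events).  Input order never matters.
    """
    records = sorted(person_records, key=lambda r: (r.event_date, r.source))
    if not records:
        return None
    index_date = records[0].event_date
    merged, seen = [], set()
    for rec in records:
        delta = (rec.event_date - index_date).days
        if 0 <= delta <= window_days:
            key = (rec.source, rec.event_date)
            if key not in seen:  # same-source duplicates collapse
                seen.add(key)
                merged.append(rec)
    return IndexStroke(
        person_id=records[0].person_id,
        index_date=index_date,
        sources=frozenset(r.source for r in merged),
        merged_records=merged,
    )


def classify_fatality(index: IndexStroke, death_date: date | None,
                      window_days: int = FATALITY_WINDOW_DAYS) -> bool:
    """Fatal iff death (any cause) within ``window_days`` days of index, inclusive."""
    if death_date is None:
        return False
    delta = (death_date - index.index_date).days
    if delta < 0:
        raise DataIntegrityError(
            f"person {index.person_id}: death {death_date} precedes index {index.index_date}")
    return delta <= window_days


def attach_death_only_strokes(deaths: pd.DataFrame, eligible: set,
                              persons_with_records: set) -> list:
    """Index strokes for persons whose only stroke evidence is the death record.

    ``deaths`` needs columns person_id, death_date, subtype (already mapped;
    non-stroke causes filtered out).  The index date is the death date and
    the event is fatal by construction.
    """
    out = []
    for row in deaths.itertuples():
        if row.person_id in eligible and row.person_id not in persons_with_records:
            rec = SourceRecord(row.person_id, "ons", row.death_date, row.subtype)
            out.append(IndexStroke(
                person_id=row.person_id, index_date=row.death_date,
                sources=frozenset({"ons"}), merged_records=[rec], fatal=True))
    return out


# ----------------------------------------------------------------------
# table-level pipeline


def extract_stroke_records(tables: dict, codelist: CodeList | None = None) -> pd.DataFrame:
    """Pull stroke-coded records from the raw source tables.

    Returns one row per (person, source, date) with the mapped subtype.
    Death registrations contribute a record dated at death when the
    underlying cause is stroke-coded.
    """
    codelist = codelist or CodeList.default()
    frames = []

    g = tables["gdppr"].copy()
    g["subtype"] = [map_code(c, "snomed", codelist) for c in g["snomed_code"]]
    g = g.dropna(subset=["subtype"])
    frames.append(pd.DataFrame({
        "person_id": g["person_id"], "source": "gdppr",
        "event_date": pd.to_datetime(g["record_date"]),
        "subtype": g["subtype"], "raw_code": g["snomed_code"].astype(str)}))

    h = tables["hes_apc"].copy()
    h["subtype"] = [map_code(c, "icd10", codelist) for c in h["primary_icd10"]]
    h = h.dropna(subset=["subtype"])
    frames.append(pd.DataFrame({
        "person_id": h["person_id"], "source": "hes_apc",
        "event_date": pd.to_datetime(h["admission_date"]),
        "subtype": h["subtype"], "raw_code": h["primary_icd10"].astype(str)}))

    s = tables["ssnap"].copy()
    s["subtype"] = [map_code(c, "ssnap_s2", codelist) for c in s["s2_stroke_type"]]
    s = s.dropna(subset=["subtype"])
    frames.append(pd.DataFrame({
        "person_id": s["person_id"], "source": "ssnap",
        "event_date": pd.to_datetime(s["onset_date"]),
        "subtype": s["subtype"], "raw_code": s["s2_stroke_type"].astype(str)}))

    d = tables["ons_deaths"].copy()
    d["subtype"] = [map_code(c, "icd10", codelist) for c in d["underlying_cause_icd10"]]
    d = d.dropna(subset=["subtype"])
    frames.append(pd.DataFrame({
        "person_id": d["person_id"], "source": "ons",
        "event_date": pd.to_datetime(d["death_date"]),
        "subtype": d["subtype"], "raw_code": d["underlying_cause_icd10"].astype(str)}))

    rec = pd.concat(frames, ignore_index=True)
    rec = rec.drop_duplicates(subset=["person_id", "source", "event_date"])
    return rec.sort_values(["person_id", "event_date", "source"], kind="mergesort").reset_index(drop=True)


def build_index_strokes(records: pd.DataFrame, deaths: pd.DataFrame,
                        study_start: date, study_end: date,
                        window_days: int = MERGE_WINDOW_DAYS):
    """Vectorised end-to-end ascertainment over a stroke-record table.

    ``records`` comes from :func:`extract_stroke_records`; ``deaths`` is the
    raw death table (person_id, death_date) used for fatality regardless of
    cause.  Returns ``(index_strokes, merged_records)`` DataFrames; the
    former has one row per person with columns person_id, index_date,
    sources (pipe-joined), stroke_type, fatal.
    """
    start, end = pd.Timestamp(study_start), pd.Timestamp(study_end)
    prevalent = set(records.loc[records["event_date"] < start, "person_id"])
    rec = records[~records["person_id"].isin(prevalent)]
    rec = rec[(rec["event_date"] >= start) & (rec["event_date"] <= end)]
    if rec.empty:
        empty = pd.DataFrame(columns=["person_id", "index_date", "sources", "stroke_type", "fatal"])
        return empty, rec.copy()

    idx_date = rec.groupby("person_id")["event_date"].transform("min")
    keep = (rec["event_date"] - idx_date).dt.days <= window_days
    merged = rec[keep].copy()
    merged["index_date"] = idx_date[keep]

    strokes = merged.groupby("person_id").agg(
        index_date=("index_date", "first"),
        sources=("source", lambda s: "|".join(sorted(set(s)))),
    ).reset_index()

    strokes["stroke_type"] = strokes["person_id"].map(resolve_types_frame(merged))

    dd = deaths.drop_duplicates("person_id").set_index("person_id")["death_date"]
    dd = pd.to_datetime(dd)
    death_for = strokes["person_id"].map(dd)
    delta = (death_for - strokes["index_date"]).dt.days
    if (delta < 0).any():
        bad = strokes.loc[delta < 0, "person_id"].tolist()[:5]
        raise DataIntegrityError(f"death precedes index stroke for persons {bad}")
    strokes["fatal"] = delta.le(FATALITY_WINDOW_DAYS).fillna(False)
    return strokes, merged
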