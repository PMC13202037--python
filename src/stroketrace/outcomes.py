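"""Post-stroke outcomes: 180-day home-time and 30-day mortality.

Home-time is the number of days alive and out of hospital in the 180 days
from the index stroke.  Day-count conventions are half-open: a spell
occupies [admission, discharge), so a same-day admission-discharge
contributes no hospital days, and the day of death and every later day in
the window count as dead days (in-hospital death days count once, as
dead).  By construction home + hospital + dead = 180 for every person.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .ascertainment import classify_fatality, DataIntegrityError, IndexStroke

HORIZON_DAYS = 180


@dataclass
class HomeTimeResult:
    person_id: int
    home_days: int
    hospital_days: int
    dead_days: int


def merge_intervals(intervals):
    """Union of half-open integer intervals [a, b); returns sorted disjoint list.

    Raises :class:`DataIntegrityError` when any b < a.  Touching intervals
    ([0,5) and [5,8)) coalesce.
    """
    for a, b in intervals:
        if b < a:
            raise DataIntegrityError(f"discharge {b} before admission {a}")
    ivs = sorted((a, b) for a, b in intervals if b > a)
    out = []
    for a, b in ivs:
        if out and a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _interval_length(intervals, lo, hi):
    """Total length of (already disjoint) intervals clipped to [lo, hi)."""
    return sum(max(0, min(b, hi) - max(a, lo)) for a, b in intervals)


def home_time(index_date, spells, death_date=None,
              horizon_days: int = HORIZON_DAYS, data_end=None) -> HomeTimeResult:
    """Partition the ``horizon_days`` window into home / hospital / dead days.

    ``spells`` is an iterable of (admission_date, discharge_date_or_None);
    open discharges are closed at min(death, data_end).  Dates may be
    ``datetime.date`` or anything pandas parses.
    """
    idx = pd.Timestamp(index_date)
    death = pd.Timestamp(death_date) if death_date is not None else None
    end = pd.Timestamp(data_end) if data_end is not None else None
    if death is not None and death < idx:
        raise DataIntegrityError(f"death {death.date()} precedes index {idx.date()}")

    close_candidates = [d for d in (death, end) if d is not None]
    close_at = min(close_candidates) if close_candidates else idx + pd.Timedelta(days=horizon_days)

    offsets = []
    for adm, dis in spells:
        a = (pd.Timestamp(adm) - idx).days
        if dis is not None and dis == dis:
            b = (pd.Timestamp(dis) - idx).days
        else:
            b = max(a, (close_at - idx).days)  # open spell; closure never precedes admission
        offsets.append((a, b))
    union = merge_intervals(offsets)

    if death is not None:
        dead_start = (death - idx).days
        dead_days = max(0, horizon_days - min(dead_start, horizon_days))
    else:
        dead_start = horizon_days
        dead_days = 0
    hospital_days = _interval_length(union, 0, min(horizon_days, dead_start))
    home_days = horizon_days - hospital_days - dead_days
    person_id = getattr(index_date, "person_id", 0)
    return HomeTimeResult(person_id, home_days, hospital_days, dead_days)


def mortality_30d(index_date, death_date) -> bool:
    """Death of any cause within 30 days (inclusive) of the index stroke."""
    stub = IndexStroke(person_id=0, index_date=pd.Timestamp(index_date),
                       sources=frozenset())
    d = pd.Timestamp(death_date) if death_date is not None and death_date == death_date else None
    return classify_fatality(stub, d)


def build_outcomes(index_strokes: pd.DataFrame, hes: pd.DataFrame,
                   deaths: pd.DataFrame, data_end) -> pd.DataFrame:
    """Outcome table (home/hospital/dead days + 30-day mortality) per person."""
    deaths = deaths.drop_duplicates("person_id")
    dd = pd.to_datetime(deaths.set_index("person_id")["death_date"])
    spells = hes.copy()
    spells["admission_date"] = pd.to_datetime(spells["admission_date"])
    spells["discharge_date"] = pd.to_datetime(spells["discharge_date"])
    by_person = {pid: list(zip(g["admission_date"], g["discharge_date"]))
                 for pid, g in spells.groupby("person_id")}

    rows = []
    for row in index_strokes.itertuples():
        idx = pd.Timestamp(row.index_date)
        death = dd.get(row.person_id)
        death = death if death is not None and death == death else None
        sp = [(a, b) for a, b in by_person.get(row.person_id, [])
              if b >= idx]  # spells ending before index are irrelevant
        ht = home_time(idx, sp, death, data_end=data_end)
        rows.append({
            "person_id": row.person_id,
            "home_days": ht.home_days,
            "hospital_days": ht.hospital_days,
            "dead_days": ht.dead_days,
            "death_30d": mortality_30d(idx, death),
        })
    return pd.DataFrame(rows)
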