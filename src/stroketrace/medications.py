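"""Secondary-prevention medication ascertainment.

Prior use: any dispensing of a class in the year before the index stroke.
Incident use: the first dispensing from 1 month (30 days) after the anchor
— hospital discharge for hospitalised strokes, otherwise the index date —
up to 1 year (365 days) after the index date.  The washout discards
discharge prescriptions so that genuinely incident community dispensing is
counted.  Event times for the competing-risk analysis run from the end of
the washout; persons dying inside the washout are excluded from the
at-risk set.
"""

from __future__ import annotations

import logging
from datetime import date

import numpy as np
import pandas as pd

from .ascertainment import DataIntegrityError
from .config import DRUG_CLASSES

WASHOUT_DAYS = 30
HORIZON_DAYS = 365

log = logging.getLogger(__name__)


def prior_medication(dispense_dates, index_date) -> bool:
    """True iff any dispensing in [index - 365, index - 1] days."""
    idx = pd.Timestamp(index_date)
    for d in dispense_dates:
        delta = (idx - pd.Timestamp(d)).days
        if 1 <= delta <= 365:
            return True
    return False


def incident_dispensing(dispense_dates, index_date, discharge_date=None,
                        washout_days: int = WASHOUT_DAYS,
                        horizon_days: int = HORIZON_DAYS):
    """Earliest qualifying dispensing date, or None.

    Qualifying: on/after anchor + washout and on/before index + horizon,
    where anchor is the discharge date for hospitalised strokes, else the
    index date.  A discharge later than index + horizon - washout leaves an
    empty eligibility window (logged, not an error).
    """
    idx = pd.Timestamp(index_date)
    if discharge_date is not None and discharge_date == discharge_date:
        anchor = pd.Timestamp(discharge_date)
        if anchor < idx:
            raise DataIntegrityError(f"discharge {anchor.date()} precedes index {idx.date()}")
    else:
        anchor = idx
    earliest = anchor + pd.Timedelta(days=washout_days)
    latest = idx + pd.Timedelta(days=horizon_days)
    if earliest > latest:
        log.info("empty dispensing eligibility window (discharge %s, index %s)",
                 anchor.date(), idx.date())
        return None
    qualifying = [pd.Timestamp(d) for d in dispense_dates
                  if earliest <= pd.Timestamp(d) <= latest]
    return min(qualifying) if qualifying else None


def to_event_time(incident_date, index_date, discharge_date, death_date,
                  washout_days: int = WASHOUT_DAYS,
                  horizon_days: int = HORIZON_DAYS):
    """(time, event) from the end of the washout, or None if not at risk.

    event is "dispensed", "death" or "censored"; time is in days from
    anchor + washout.  Persons dying on or before the end of the washout
    are not at risk and return None.
    """
    idx = pd.Timestamp(index_date)
    anchor = pd.Timestamp(discharge_date) if discharge_date is not None and discharge_date == discharge_date else idx
    origin = anchor + pd.Timedelta(days=washout_days)
    horizon_end = idx + pd.Timedelta(days=horizon_days)
    if origin > horizon_end:
        return None
    death = pd.Timestamp(death_date) if death_date is not None and death_date == death_date else None
    if death is not None and death <= origin:
        return None
    if incident_date is not None:
        return ((pd.Timestamp(incident_date) - origin).days, "dispensed")
    if death is not None and death <= horizon_end:
        return ((death - origin).days, "death")
    return ((horizon_end - origin).days, "censored")


def build_medications(index_strokes: pd.DataFrame, dispensing: pd.DataFrame,
                      hes: pd.DataFrame, deaths: pd.DataFrame) -> pd.DataFrame:
    """Per-person, per-class medication ascertainment table.

    Columns: person_id, drug_class, prior, incident_date, time, event
    (time/event empty for persons not at risk after the washout).  The
    anchor uses the discharge of the index hospital spell: the earliest
    spell overlapping the index date, if any.
    """
    idx = pd.to_datetime(index_strokes.set_index("person_id")["index_date"])
    dd = pd.to_datetime(deaths.drop_duplicates("person_id").set_index("person_id")["death_date"])

    spells = hes.copy()
    spells["admission_date"] = pd.to_datetime(spells["admission_date"])
    spells["discharge_date"] = pd.to_datetime(spells["discharge_date"])
    spells = spells.merge(idx.rename("index_date"), left_on="person_id", right_index=True)
    # index spell: admission within the 30-day merge window around index
    is_index = ((spells["admission_date"] >= spells["index_date"] - pd.Timedelta(days=1)) &
                (spells["admission_date"] <= spells["index_date"] + pd.Timedelta(days=30)))
    discharge = (spells[is_index].sort_values("admission_date")
                 .groupby("person_id")["discharge_date"].first())

    disp = dispensing.copy()
    disp["dispense_date"] = pd.to_datetime(disp["dispense_date"])
    grouped = {k: g["dispense_date"].tolist()
               for k, g in disp.groupby(["person_id", "drug_class"])}

    rows = []
    for pid, index_date in idx.items():
        dis = discharge.get(pid)
        death = dd.get(pid)
        for cls in DRUG_CLASSES:
            dates = grouped.get((pid, cls), [])
            prior = prior_medication(dates, index_date)
            inc = incident_dispensing(dates, index_date, dis)
            te = to_event_time(inc, index_date, dis, death)
            rows.append({
                "person_id": pid, "drug_class": cls, "prior": prior,
                "incident_date": inc,
                "time": te[0] if te else np.nan,
                "event": te[1] if te else "",
            })
    return pd.DataFrame(rows)
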