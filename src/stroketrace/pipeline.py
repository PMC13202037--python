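"""End-to-end pipeline: simulate -> ascertain -> covariates/outcomes ->
medications -> estimators.

Each stage is a thin orchestration over the module functions, operating on
the in-memory table dictionary produced by the generator (or loaded from
the CSV interface).  Per-stage record counts are logged to stderr as a
consort-style attrition trail.
"""

from __future__ import annotations

import json
import logging
import os
import numpy as np
import pandas as pd

from .ascertainment import build_index_strokes, extract_stroke_records
from .config import AGE_BANDS, DRUG_CLASSES, SimConfig, band_of_age
from .covariates import build_covariates
from .estimators import (CifCurve, aalen_johansen,
                         adult_esp_weights, direct_standardised_rate)
from .medications import build_medications
from .outcomes import build_outcomes
from .synthetic import generate_cohort, write_tables

log = logging.getLogger("stroketrace")


def load_tables(indir) -> dict:
    """Read the CSV table set written by :func:`stroketrace.synthetic.write_tables`."""
    names = ["persons", "gdppr", "hes_apc", "ssnap", "ons_deaths",
             "dispensing", "measurements", "covid", "lsoa_imd"]
    return {n: pd.read_csv(os.path.join(indir, f"{n}.csv"))
            for n in names if os.path.exists(os.path.join(indir, f"{n}.csv"))}


def ascertain(tables: dict, config: SimConfig):
    """Index strokes + merged records from the raw tables."""
    records = extract_stroke_records(tables)
    strokes, merged = build_index_strokes(
        records, tables["ons_deaths"], config.study_start, config.study_end)
    log.info("ascertainment: %d stroke-coded records -> %d index strokes",
             len(records), len(strokes))
    return strokes, merged


def person_time_by_stratum(tables: dict, index_strokes: pd.DataFrame,
                           config: SimConfig, period_start, period_end) -> pd.DataFrame:
    """Stroke-free person-years by ESP age band and sex within a period.

    Persons contribute from the period start until their index stroke (or
    the period end).  Ages are taken at study start (integer-year cohort
    convention).  Prevalent-excluded persons still appear in the persons
    table but never in ``index_strokes``; their full time counts, matching
    a registered-population denominator.
    """
    persons = tables["persons"]
    idx = index_strokes.set_index("person_id")["index_date"]
    idx = pd.to_datetime(idx)
    p0, p1 = pd.Timestamp(period_start), pd.Timestamp(period_end) + pd.Timedelta(days=1)
    stop = persons["person_id"].map(idx).fillna(p1).clip(upper=p1)
    days = (stop - p0).dt.days.clip(lower=0)
    age = config.study_start.year - persons["birth_year"]
    df = pd.DataFrame({
        "age_band": [band_of_age(int(a)) for a in age],
        "sex": persons["sex"],
        "person_years": days / 365.25,
    })
    return df.groupby(["age_band", "sex"], observed=True)["person_years"].sum().reset_index()


def incidence_series(tables: dict, index_strokes: pd.DataFrame, config: SimConfig,
                     freq: str = "YS") -> pd.DataFrame:
    """Directly standardised incidence per 100 000 person-years by period.

    ``freq`` is a pandas offset alias ("YS" for annual, "MS" for monthly).
    Denominators are the stroke-free person-time of the registered adult
    population; rates are age-sex standardised to the adult ESP.
    """
    weights = adult_esp_weights(AGE_BANDS)
    persons = tables["persons"]
    age = config.study_start.year - persons["birth_year"]
    bands = pd.Series([band_of_age(int(a)) for a in age], index=persons.index)
    strokes = index_strokes.merge(persons[["person_id", "sex"]], on="person_id")
    strokes["age_band"] = strokes["person_id"].map(
        persons.set_index("person_id").index.to_series())  # placeholder replaced below
    band_by_pid = pd.Series(bands.values, index=persons["person_id"].values)
    strokes["age_band"] = strokes["person_id"].map(band_by_pid)
    strokes["index_date"] = pd.to_datetime(strokes["index_date"])

    periods = pd.date_range(pd.Timestamp(config.study_start), pd.Timestamp(config.study_end), freq=freq)
    rows = []
    for p0 in periods:
        p1 = (p0 + (pd.offsets.YearEnd(0) if freq.startswith("Y") else pd.offsets.MonthEnd(0)))
        if p1 < p0:
            p1 = p0 + (pd.offsets.YearEnd(1) if freq.startswith("Y") else pd.offsets.MonthEnd(1))
        pt = person_time_by_stratum(tables, index_strokes, config, p0, p1)
        ev = strokes[(strokes["index_date"] >= p0) & (strokes["index_date"] <= p1)]
        counts = ev.groupby(["age_band", "sex"], observed=True).size().rename("events").reset_index()
        strata = pt.merge(counts, on=["age_band", "sex"], how="left").fillna({"events": 0})
        strata = strata[strata["person_years"] > 0]
        rp = direct_standardised_rate(strata, weights)
        rows.append({"period": p0.strftime("%Y-%m") if freq.startswith("M") else p0.strftime("%Y"),
                     "rate": rp.rate, "ci_low": rp.ci_low, "ci_high": rp.ci_high,
                     "crude_rate": rp.crude_rate, "events": rp.events,
                     "person_years": rp.person_years})
    return pd.DataFrame(rows)


def dispensing_cif(medications: pd.DataFrame, drug_class) -> CifCurve:
    """Aalen-Johansen CIF of first dispensing for one class (or a union).

    ``drug_class`` may be a single class or a tuple of classes, in which
    case the union event (earliest qualifying record of either class, with
    the person censored/dying once) is analysed.
    """
    classes = (drug_class,) if isinstance(drug_class, str) else tuple(drug_class)
    med = medications[medications["drug_class"].isin(classes)]
    med = med[med["event"] != ""].dropna(subset=["time"])
    if len(classes) == 1:
        return aalen_johansen(med["time"], med["event"])
    # union event: take the earliest dispensing across the classes
    def fuse(grp):
        disp = grp[grp["event"] == "dispensed"]
        if len(disp):
            row = disp.loc[disp["time"].idxmin()]
        else:
            row = grp.loc[grp["time"].idxmax()]
        return pd.Series({"time": row["time"], "event": row["event"]})
    fused = med.groupby("person_id").apply(fuse, include_groups=False)
    return aalen_johansen(fused["time"], fused["event"])


def run_all(config: SimConfig, outdir=None) -> dict:
    """Simulate and run every analysis stage; optionally write CSV outputs.

    Returns a dict with the generated tables, ground truth, index strokes,
    covariates, outcomes, medications and annual standardised incidence.
    """
    tables, ground_truth = generate_cohort(config)
    log.info("simulated %d persons, %d true strokes",
             config.n_persons, int(ground_truth["has_stroke"].sum()))
    strokes, merged = ascertain(tables, config)
    covs = build_covariates(tables, strokes)
    outcomes = build_outcomes(strokes, tables["hes_apc"], tables["ons_deaths"],
                              config.data_end)
    meds = build_medications(strokes, tables["dispensing"], tables["hes_apc"],
                             tables["ons_deaths"])
    rates = incidence_series(tables, strokes, config, freq="YS")

    result = {"tables": tables, "ground_truth": ground_truth,
              "index_strokes": strokes, "merged_records": merged,
              "covariates": covs, "outcomes": outcomes,
              "medications": meds, "annual_rates": rates}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_tables(tables, os.path.join(outdir, "sources"))
        ground_truth.to_csv(os.path.join(outdir, "sources", "ground_truth.csv"), index=False)
        for name in ("index_strokes", "covariates", "outcomes", "medications", "annual_rates"):
            result[name].to_csv(os.path.join(outdir, f"{name}.csv"), index=False)
        meta = {"seed": config.seed, "n_persons": config.n_persons,
                "study_start": str(config.study_start), "study_end": str(config.study_end)}
        with open(os.path.join(outdir, "run_metadata.json"), "w") as fh:
            json.dump(meta, fh, indent=2)
    return result
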