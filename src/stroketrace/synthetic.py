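"""Synthetic linked-EHR cohort generator with known ground truth.

Emulates five linked record sources for a whole-population stroke study —
primary-care diagnoses (GDPPR-like), hospital admitted-patient spells
(HES-APC-like), a hospital stroke audit (SSNAP-like), death registrations
(ONS-like) and community dispensing (NHSBSA-like) — plus a demographics
table and an LSOA-to-deprivation-quintile lookup.  Every emitted record is
tied to a ground-truth event table so that downstream ascertainment,
outcome and estimator code can be tested for parameter recovery.

The model, per person:

* one potential first stroke, with exponential waiting time from study
  start at the configured age-sex incidence rate;
* a true subtype drawn from the ischaemic / haemorrhagic / unknown mix and
  30-day case fatality drawn per subtype (deaths beyond 30 days are not
  simulated);
* independent capture of the event by each source given fatality status,
  with integer Gaussian jitter on recorded dates (death dates are
  registry-exact) and source-specific probability of coding the subtype
  as "unknown";
* a log-normal index hospital spell (plus optional readmission) when the
  event is captured in hospital data;
* first post-stroke dispensing per drug class with constant daily hazard,
  competing with death; prior-year dispensing per class prevalence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (AGE_BANDS, DRUG_CLASSES, SEXES, SimConfig, band_bounds)

# toy SNOMED concepts for stroke subtypes (cerebral infarction, cerebral
# haemorrhage, CVA unspecified) and ICD-10 three-character parents
SNOMED_BY_SUBTYPE = {"ischaemic": "422504002", "haemorrhagic": "274100004",
                     "unknown": "230690007"}
ICD10_BY_SUBTYPE = {"ischaemic": "I63", "haemorrhagic": "I61", "unknown": "I64"}
S2_BY_SUBTYPE = {"ischaemic": "infarction", "haemorrhagic": "haemorrhage"}
NON_STROKE_CAUSES = ("C349", "J189", "I219", "F019")

ETHNICITIES = ("white", "asian", "black", "mixed", "other")
ETHNICITY_P = (0.894, 0.055, 0.029, 0.008, 0.014)

_MEAS_DISTS = {  # name -> (mean, sd) of a plausible adult distribution
    "bmi": (27.5, 5.0), "sbp": (137.0, 17.0), "egfr": (68.0, 20.0),
    "hba1c": (43.0, 10.0), "total_cholesterol": (3.5, 1.1),
    "hdl_cholesterol": (1.35, 0.4),
}

N_LSOA = 200


def _days(cfg: SimConfig) -> int:
    return (cfg.study_end - cfg.study_start).days + 1


def _to_dates(cfg: SimConfig, offsets) -> pd.Series:
    return pd.Timestamp(cfg.study_start) + pd.to_timedelta(np.asarray(offsets, dtype="int64"), unit="D")


def generate_ground_truth(config: SimConfig, rng: np.random.Generator | None = None):
    """Draw persons and true stroke events; returns (persons, ground_truth)."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_persons

    strata = [(b, s) for b in AGE_BANDS for s in SEXES]
    probs = np.array([config.age_sex_structure[b][s] for b, s in strata])
    probs = probs / probs.sum()
    stratum_idx = rng.choice(len(strata), size=n, p=probs)
    band = np.array([strata[i][0] for i in stratum_idx])
    sex = np.array([strata[i][1] for i in stratum_idx])
    lo = np.array([band_bounds(strata[i][0])[0] for i in stratum_idx])
    hi = np.array([band_bounds(strata[i][0])[1] for i in stratum_idx])
    age = rng.integers(lo, hi + 1)
    birth_year = config.study_start.year - age

    ethnicity = rng.choice(ETHNICITIES, size=n, p=ETHNICITY_P)
    lsoa = np.array([f"E{1_000_000 + i:08d}" for i in rng.integers(1, N_LSOA + 1, size=n)])

    # exponential waiting time to first stroke from study start
    rate_day = np.array([config.annual_incidence[strata[i][0]][strata[i][1]]
                         for i in stratum_idx]) / 100_000.0 / 365.25
    with np.errstate(divide="ignore"):
        wait = np.where(rate_day > 0, rng.exponential(1.0, size=n) / np.where(rate_day > 0, rate_day, 1.0), np.inf)
    study_days = _days(config)
    has_stroke = wait < study_days
    stroke_offset = np.where(has_stroke, np.floor(wait), -1).astype("int64")

    subtype = rng.choice(["ischaemic", "haemorrhagic", "unknown"], size=n,
                         p=np.asarray(config.subtype_mix))
    fatal_p = np.array([config.fatality_prob[s] for s in subtype])
    fatal = has_stroke & (rng.random(n) < fatal_p)
    death_delay = rng.integers(0, 31, size=n)  # death within 30 days, inclusive
    death_offset = np.where(fatal, stroke_offset + death_delay, -1)

    prevalent = rng.random(n) < config.prior_stroke_prob
    prior_offset = -rng.integers(30, 1000, size=n)  # days before study start

    # independent per-source capture given fatality status; audit never
    # captures true-unknown strokes (its type field has no unknown level)
    status = np.where(fatal, "fatal", "nonfatal")
    caps = {}
    for src in ("gdppr", "hes_apc", "ssnap", "ons"):
        p = np.array([config.capture_prob[(src, st)] for st in status])
        if src == "ssnap":
            p = np.where(subtype == "unknown", 0.0, p)
        caps[src] = has_stroke & (rng.random(n) < p)
    caps["ons"] &= fatal  # only deaths reach the register

    persons = pd.DataFrame({
        "person_id": np.arange(1, n + 1),
        "birth_year": birth_year,
        "sex": sex,
        "ethnicity": ethnicity,
        "lsoa": lsoa,
        "age_band": band,
    })
    # field-level missingness in demographics
    miss = rng.random(n) < config.missing_rate
    persons.loc[miss, "ethnicity"] = ""
    miss_lsoa = rng.random(n) < config.missing_rate / 2
    persons.loc[miss_lsoa, "lsoa"] = ""

    gt = pd.DataFrame({
        "person_id": persons["person_id"],
        "prevalent": prevalent,
        "has_stroke": has_stroke,
        "stroke_offset": stroke_offset,
        "subtype": np.where(has_stroke, subtype, ""),
        "fatal": fatal,
        "death_offset": death_offset,
        "prior_offset": np.where(prevalent, prior_offset, 0),
        "cap_gdppr": caps["gdppr"],
        "cap_hes_apc": caps["hes_apc"],
        "cap_ssnap": caps["ssnap"],
        "cap_ons": caps["ons"],
    })
    gt["hospitalised"] = gt["cap_hes_apc"]
    return persons, gt


def _jitter(rng, n, sd, prob=1.0):
    """Zero-inflated integer date jitter: most records carry the exact date."""
    if sd == 0 or prob == 0:
        return np.zeros(n, dtype="int64")
    jit = np.rint(rng.normal(0.0, sd, size=n)).astype("int64")
    jit[rng.random(n) >= prob] = 0
    return jit


def _clamped_record_offset(cfg, true_offset, jit, death_offset, fatal):
    """Recorded date = true + jitter, kept inside the study window and, for
    fatal events, not after the death date (a record cannot postdate death)."""
    off = true_offset + jit
    off = np.clip(off, 0, _days(cfg) - 1)
    cap = np.where(fatal, death_offset, np.iinfo("int64").max)
    return np.minimum(off, cap)


def generate_spells(config: SimConfig, ground_truth: pd.DataFrame,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Hospital spell table for strokes captured in hospital data.

    The index spell starts at the (jittered) admission date with log-normal
    length of stay; a configurable fraction get one later readmission.
    Discharge is always >= admission.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    gt = ground_truth
    hosp = gt[gt["hospitalised"] & gt["has_stroke"]]
    n = len(hosp)
    los = np.rint(np.exp(rng.normal(config.los_log_mean, config.los_log_sd, size=n))).astype("int64")
    los = np.maximum(los, 1)
    jit = _jitter(rng, n, config.date_jitter_sd, config.date_jitter_prob)
    adm = _clamped_record_offset(config, hosp["stroke_offset"].to_numpy(), jit,
                                 hosp["death_offset"].to_numpy(), hosp["fatal"].to_numpy())
    data_span = (config.data_end - config.study_start).days
    dis = np.minimum(adm + los, data_span)
    dis = np.where(hosp["fatal"].to_numpy(),
                   np.minimum(dis, hosp["death_offset"].to_numpy()), dis)
    dis = np.maximum(dis, adm)

    frames = [pd.DataFrame({
        "person_id": hosp["person_id"].to_numpy(),
        "admission_offset": adm,
        "discharge_offset": dis,
        "primary_subtype": hosp["subtype"].to_numpy(),
        "is_index": True,
    })]
    readmit = rng.random(n) < config.readmission_prob
    if readmit.any():
        m = int(readmit.sum())
        gap = rng.integers(5, 61, size=m)
        los2 = np.maximum(np.rint(np.exp(rng.normal(config.los_log_mean, config.los_log_sd, size=m))).astype("int64"), 1)
        adm2 = dis[readmit] + gap
        dis2 = adm2 + los2
        alive_cap = np.where(hosp["fatal"].to_numpy()[readmit],
                             hosp["death_offset"].to_numpy()[readmit], data_span)
        keep = adm2 <= alive_cap
        frames.append(pd.DataFrame({
            "person_id": hosp["person_id"].to_numpy()[readmit][keep],
            "admission_offset": adm2[keep],
            "discharge_offset": np.minimum(dis2, alive_cap)[keep],
            "primary_subtype": "",
            "is_index": False,
        }))
    spells = pd.concat(frames, ignore_index=True)
    spells = spells.sort_values(["person_id", "admission_offset"], kind="mergesort").reset_index(drop=True)
    return spells


def generate_dispensings(config: SimConfig, ground_truth: pd.DataFrame,
                         spells: pd.DataFrame | None = None,
                         rng: np.random.Generator | None = None):
    """Dispensing table plus per-class true first post-stroke dispensing.

    Prior-year use is drawn per class prevalence (1-2 records in the year
    before the stroke); the first post-stroke dispensing time per class is
    exponential at the configured (class, subtype) daily hazard and emitted
    only if it lands strictly before death and within the data window.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    gt = ground_truth
    idx = gt[gt["has_stroke"]]
    n = len(idx)
    data_span = (config.data_end - config.study_start).days
    rows = []
    truth_cols = {"person_id": idx["person_id"].to_numpy()}
    death = np.where(idx["fatal"].to_numpy(), idx["death_offset"].to_numpy(), np.iinfo("int64").max)
    onset = idx["stroke_offset"].to_numpy()
    for cls in DRUG_CLASSES:
        prior = rng.random(n) < config.prior_med_prev[cls]
        n_rec = np.where(prior, rng.integers(1, 3, size=n), 0)
        for k in (1, 2):
            sel = n_rec >= k
            if sel.any():
                back = rng.integers(1, 366, size=int(sel.sum()))
                rows.append(pd.DataFrame({
                    "person_id": idx["person_id"].to_numpy()[sel],
                    "offset": onset[sel] - back,
                    "drug_class": cls,
                }))
        h = np.array([config.dispensing_hazard[(cls, st)] for st in idx["subtype"]])
        with np.errstate(divide="ignore"):
            t = np.where(h > 0, np.ceil(rng.exponential(1.0, size=n) / np.where(h > 0, h, 1.0)), np.inf)
        first = np.where(np.isfinite(t), onset + t, -1).astype("int64")
        truth_cols[f"disp_true_{cls}"] = first
        emit = (first >= 0) & (first < death) & (first <= data_span)
        rows.append(pd.DataFrame({
            "person_id": idx["person_id"].to_numpy()[emit],
            "offset": first[emit],
            "drug_class": cls,
        }))
        # repeat dispensings (refills) roughly monthly-to-quarterly after the
        # first, while alive and within the data window
        m = int(emit.sum())
        if m:
            gaps = rng.integers(25, 81, size=(m, 8)).cumsum(axis=1)
            refill = first[emit][:, None] + gaps
            cap = np.minimum(death[emit] - 1, data_span)
            keep = refill <= np.minimum(cap, onset[emit] + 430)[:, None]
            pid_rep = np.repeat(idx["person_id"].to_numpy()[emit], keep.sum(axis=1))
            rows.append(pd.DataFrame({
                "person_id": pid_rep,
                "offset": refill[keep],
                "drug_class": cls,
            }))
    disp = (pd.concat(rows, ignore_index=True) if rows else
            pd.DataFrame(columns=["person_id", "offset", "drug_class"]))
    disp = disp.sort_values(["person_id", "offset", "drug_class"], kind="mergesort").reset_index(drop=True)
    return disp, pd.DataFrame(truth_cols)


def generate_cohort(config: SimConfig):
    """Generate the full set of linked tables plus ground truth.

    Returns ``(tables, ground_truth)`` where ``tables`` maps table name to
    DataFrame with the external CSV schemas (ISO dates).  Deterministic
    given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    persons, gt = generate_ground_truth(config, rng)
    n = config.n_persons
    pid = gt["person_id"].to_numpy()
    onset = gt["stroke_offset"].to_numpy()
    death_off = gt["death_offset"].to_numpy()
    fatal = gt["fatal"].to_numpy()

    # ---- GDPPR: stroke diagnosis records + prevalent history + comorbidities
    gdppr_rows = []
    cap = gt["cap_gdppr"].to_numpy()
    m = int(cap.sum())
    jit = _jitter(rng, m, config.date_jitter_sd, config.date_jitter_prob)
    rec_off = _clamped_record_offset(config, onset[cap], jit, death_off[cap], fatal[cap])
    mis = rng.random(m) < config.subtype_unknown_prob["gdppr"]
    sub = np.where(mis, "unknown", gt["subtype"].to_numpy()[cap])
    gdppr_rows.append(pd.DataFrame({
        "person_id": pid[cap], "offset": rec_off,
        "snomed_code": [SNOMED_BY_SUBTYPE[s] for s in sub]}))
    prev = gt["prevalent"].to_numpy()
    if prev.any():
        gdppr_rows.append(pd.DataFrame({
            "person_id": pid[prev], "offset": gt["prior_offset"].to_numpy()[prev],
            "snomed_code": SNOMED_BY_SUBTYPE["ischaemic"]}))

    # ---- comorbidity history: GDPPR (SNOMED) or prior HES spell (ICD-10)
    from .covariates import condition_codes  # local import avoids cycle at import time
    cond_codes = condition_codes()
    hes_prior_rows = []
    stroke_mask = gt["has_stroke"].to_numpy()
    for cond, p in config.comorbidity_prev.items():
        hasit = stroke_mask & (rng.random(n) < p)
        k = int(hasit.sum())
        if k == 0:
            continue
        back = rng.integers(60, 3600, size=k)
        off = onset[hasit] - back
        snomed, icd10 = cond_codes[cond]
        via_gdppr = (rng.random(k) < 0.7) | (icd10 is None)
        gdppr_rows.append(pd.DataFrame({
            "person_id": pid[hasit][via_gdppr], "offset": off[via_gdppr],
            "snomed_code": snomed}))
        via_hes = ~via_gdppr
        if via_hes.any():
            hes_prior_rows.append(pd.DataFrame({
                "person_id": pid[hasit][via_hes],
                "admission_offset": off[via_hes],
                "discharge_offset": off[via_hes] + 1,
                "primary_icd10": icd10}))
    gdppr = pd.concat(gdppr_rows, ignore_index=True)

    # ---- HES-APC: index (and readmission) spells + prior comorbidity spells
    spells = generate_spells(config, gt, rng)
    mis = rng.random(len(spells)) < config.subtype_unknown_prob["hes_apc"]
    spell_code = [
        ICD10_BY_SUBTYPE["unknown"] if (s and m) else (ICD10_BY_SUBTYPE[s] if s else "Z501")
        for s, m in zip(spells["primary_subtype"], mis)
    ]
    hes = pd.DataFrame({
        "person_id": spells["person_id"],
        "admission_offset": spells["admission_offset"],
        "discharge_offset": spells["discharge_offset"],
        "primary_icd10": spell_code,
    })
    if hes_prior_rows:
        hes = pd.concat([hes] + hes_prior_rows, ignore_index=True)
    hes = hes.sort_values(["person_id", "admission_offset"], kind="mergesort").reset_index(drop=True)
    hes.insert(1, "spell_id", np.arange(1, len(hes) + 1))

    # ---- SSNAP audit records
    cap = gt["cap_ssnap"].to_numpy()
    m = int(cap.sum())
    jit = _jitter(rng, m, config.date_jitter_sd, config.date_jitter_prob)
    rec_off = _clamped_record_offset(config, onset[cap], jit, death_off[cap], fatal[cap])
    nihss = np.minimum(np.rint(rng.gamma(1.2, 5.0, size=m)).astype("int64"), 42)
    rankin = rng.choice([0, 1, 2, 3, 4, 5, 6], size=m,
                        p=[0.14, 0.22, 0.17, 0.14, 0.12, 0.06, 0.15])
    rankin = rankin.astype(object)
    rankin[rng.random(m) < 0.34] = ""
    ssnap = pd.DataFrame({
        "person_id": pid[cap], "offset": rec_off,
        "s2_stroke_type": [S2_BY_SUBTYPE[s] for s in gt["subtype"].to_numpy()[cap]],
        "nihss_arrival": nihss, "rankin_discharge": rankin,
    })

    # ---- ONS death registrations (all fatal strokes; stroke-coded or not)
    dead = fatal
    m = int(dead.sum())
    coded = gt["cap_ons"].to_numpy()[dead]
    mis = rng.random(m) < config.subtype_unknown_prob["ons"]
    sub = np.where(mis, "unknown", gt["subtype"].to_numpy()[dead])
    other = rng.choice(NON_STROKE_CAUSES, size=m)
    cause = np.where(coded, [ICD10_BY_SUBTYPE[s] for s in sub], other)
    ons = pd.DataFrame({
        "person_id": pid[dead], "offset": death_off[dead],
        "underlying_cause_icd10": cause,
    })

    # ---- dispensing
    disp, disp_truth = generate_dispensings(config, gt, spells, rng)

    # ---- pre-stroke measurements (primary care)
    meas_rows = []
    stroke_ids = pid[stroke_mask]
    k = len(stroke_ids)
    for name, (mu, sd) in _MEAS_DISTS.items():
        have = rng.random(k) < config.measurement_coverage
        j = int(have.sum())
        back = rng.integers(1, 721, size=j)
        meas_rows.append(pd.DataFrame({
            "person_id": stroke_ids[have],
            "offset": onset[stroke_mask][have] - back,
            "name": name,
            "value": np.round(rng.normal(mu, sd, size=j), 1)}))
    smoking = rng.choice(["current", "ex", "never"], size=k, p=[0.18, 0.37, 0.45])
    have = rng.random(k) < config.measurement_coverage
    meas_rows.append(pd.DataFrame({
        "person_id": stroke_ids[have],
        "offset": onset[stroke_mask][have] - rng.integers(1, 721, size=int(have.sum())),
        "name": "smoking", "value": smoking[have]}))
    measurements = pd.concat(meas_rows, ignore_index=True)

    # ---- COVID exposure flags
    covid_rows = []
    recent = stroke_mask & (rng.random(n) < config.covid_recent_prob)
    if recent.any():
        covid_rows.append(pd.DataFrame({
            "person_id": pid[recent],
            "offset": onset[recent] - rng.integers(1, 15, size=int(recent.sum()))}))
    hist = stroke_mask & (rng.random(n) < config.covid_history_prob)
    if hist.any():
        covid_rows.append(pd.DataFrame({
            "person_id": pid[hist],
            "offset": onset[hist] - rng.integers(15, 700, size=int(hist.sum()))}))
    covid = (pd.concat(covid_rows, ignore_index=True) if covid_rows
             else pd.DataFrame(columns=["person_id", "offset"]))

    # ---- LSOA -> IMD quintile lookup
    lsoas = [f"E{1_000_000 + i:08d}" for i in range(1, N_LSOA + 1)]
    lsoa_imd = pd.DataFrame({"lsoa": lsoas,
                             "imd_quintile": rng.integers(1, 6, size=N_LSOA)})

    tables = {
        "persons": persons.drop(columns=["age_band"]),
        "gdppr": gdppr.assign(record_date=_to_dates(config, gdppr["offset"]).strftime("%Y-%m-%d"))
                      .drop(columns=["offset"])[["person_id", "record_date", "snomed_code"]]
                      .sort_values(["person_id", "record_date", "snomed_code"], kind="mergesort")
                      .reset_index(drop=True),
        "hes_apc": hes.assign(
            admission_date=_to_dates(config, hes["admission_offset"]).strftime("%Y-%m-%d"),
            discharge_date=_to_dates(config, hes["discharge_offset"]).strftime("%Y-%m-%d"))
            [["person_id", "spell_id", "admission_date", "discharge_date", "primary_icd10"]],
        "ssnap": ssnap.assign(onset_date=_to_dates(config, ssnap["offset"]).strftime("%Y-%m-%d"))
                      [["person_id", "onset_date", "s2_stroke_type", "nihss_arrival", "rankin_discharge"]]
                      .sort_values("person_id", kind="mergesort").reset_index(drop=True),
        "ons_deaths": ons.assign(death_date=_to_dates(config, ons["offset"]).strftime("%Y-%m-%d"))
                         [["person_id", "death_date", "underlying_cause_icd10"]]
                         .sort_values("person_id", kind="mergesort").reset_index(drop=True),
        "dispensing": disp.assign(dispense_date=_to_dates(config, disp["offset"]).strftime("%Y-%m-%d"))
                          [["person_id", "dispense_date", "drug_class"]],
        "measurements": measurements.assign(date=_to_dates(config, measurements["offset"]).strftime("%Y-%m-%d"))
                                    [["person_id", "date", "name", "value"]]
                                    .sort_values(["person_id", "name", "date"], kind="mergesort")
                                    .reset_index(drop=True),
        "covid": covid.assign(date=_to_dates(config, covid["offset"]).strftime("%Y-%m-%d"))
                      [["person_id", "date"]].sort_values(["person_id", "date"], kind="mergesort")
                      .reset_index(drop=True),
        "lsoa_imd": lsoa_imd,
    }

    gt_out = gt.merge(disp_truth, on="person_id", how="left")
    gt_out = gt_out.merge(persons[["person_id", "age_band", "sex"]], on="person_id")
    # index-spell bounds for convenience in recovery tests
    index_spells = spells[spells["is_index"]].drop_duplicates("person_id")
    gt_out = gt_out.merge(
        index_spells[["person_id", "admission_offset", "discharge_offset"]],
        on="person_id", how="left")
    return tables, gt_out


def write_tables(tables: dict, outdir) -> None:
    """Write every table as CSV (ISO-8601 dates, header row)."""
    import os
    os.makedirs(outdir, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(f"{outdir}/{name}.csv", index=False)
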