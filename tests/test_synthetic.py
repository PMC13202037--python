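"""Generator contracts: determinism, capture recovery, spell and dispensing
distributions, and absence of anachronistic records."""

import io

import numpy as np
import pandas as pd
import pytest

from stroketrace import ConfigError, SimConfig, generate_cohort
from stroketrace.synthetic import generate_dispensings, generate_ground_truth, generate_spells

from conftest import make_flat_incidence


def _csv_bytes(tables):
    out = {}
    for name, df in tables.items():
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        out[name] = buf.getvalue()
    return out


def test_same_seed_gives_byte_identical_tables(small_cfg):
    t1, g1 = generate_cohort(small_cfg)
    t2, g2 = generate_cohort(small_cfg)
    assert _csv_bytes(t1) == _csv_bytes(t2)
    pd.testing.assert_frame_equal(g1, g2)


def test_different_seed_changes_output(small_cfg):
    t1, _ = generate_cohort(small_cfg)
    cfg2 = SimConfig(n_persons=small_cfg.n_persons, seed=small_cfg.seed + 1)
    t2, _ = generate_cohort(cfg2)
    assert _csv_bytes(t1) != _csv_bytes(t2)


def test_full_capture_no_jitter_puts_every_event_in_every_source(clean_capture_cfg):
    tables, gt = generate_cohort(clean_capture_cfg)
    ev = gt[gt["has_stroke"]]
    start = pd.Timestamp(clean_capture_cfg.study_start)
    true_date = {r.person_id: start + pd.Timedelta(days=int(r.stroke_offset))
                 for r in ev.itertuples()}
    for name, datecol in [("gdppr", "record_date"), ("ssnap", "onset_date")]:
        df = tables[name]
        stroke_rows = df[df["person_id"].isin(true_date)]
        if name == "gdppr":
            stroke_rows = stroke_rows[stroke_rows["snomed_code"].isin(
                ["422504002", "274100004", "230690007"])]
        by_person = stroke_rows.groupby("person_id")[datecol].min()
        assert set(by_person.index) == set(true_date)
        for pid, d in by_person.items():
            assert pd.Timestamp(d) == true_date[pid], (name, pid)
    # fatal events all reach the death register with a stroke-coded cause
    fatal = ev[ev["fatal"]]
    ons = tables["ons_deaths"].set_index("person_id")
    assert set(fatal["person_id"]).issubset(set(ons.index))
    assert ons.loc[fatal["person_id"], "underlying_cause_icd10"].isin(["I63", "I61", "I64"]).all()


def test_capture_fraction_recovers_configured_probability():
    cfg = SimConfig(n_persons=60_000, seed=3)
    cfg.annual_incidence = make_flat_incidence(5000)  # many events, fast test
    cfg.subtype_mix = (0.8, 0.2, 0.0)
    p = 0.5
    cfg.capture_prob = dict(cfg.capture_prob)
    cfg.capture_prob[("ssnap", "nonfatal")] = p
    cfg.capture_prob[("ssnap", "fatal")] = p
    _, gt = generate_cohort(cfg)
    ev = gt[gt["has_stroke"]]
    n = len(ev)
    assert n >= 10_000
    frac = ev["cap_ssnap"].mean()
    se = np.sqrt(p * (1 - p) / n)
    assert abs(frac - p) <= 3 * se


def test_zero_los_variance_gives_identical_spell_durations():
    cfg = SimConfig(n_persons=20_000, seed=5)
    cfg.los_log_sd = 0.0
    cfg.readmission_prob = 0.0
    cfg.fatality_prob = {k: 0.0 for k in cfg.fatality_prob}  # no death truncation
    _, gt = generate_ground_truth(cfg)
    spells = generate_spells(cfg, gt)
    dur = spells["discharge_offset"] - spells["admission_offset"]
    assert dur.nunique() == 1
    assert dur.iloc[0] == round(np.exp(cfg.los_log_mean))


def test_no_readmissions_means_one_spell_per_hospitalised_stroke(clean_capture_cfg):
    cfg = SimConfig(n_persons=10_000, seed=5)
    cfg.readmission_prob = 0.0
    _, gt = generate_ground_truth(cfg)
    spells = generate_spells(cfg, gt)
    assert spells["person_id"].is_unique
    assert set(spells["person_id"]) == set(gt.loc[gt["hospitalised"] & gt["has_stroke"], "person_id"])


def test_median_los_matches_lognormal_median():
    cfg = SimConfig(n_persons=200_000, seed=13)
    cfg.fatality_prob = {k: 0.0 for k in cfg.fatality_prob}
    cfg.readmission_prob = 0.0
    _, gt = generate_ground_truth(cfg)
    spells = generate_spells(cfg, gt)
    dur = (spells["discharge_offset"] - spells["admission_offset"]).to_numpy()
    n = len(dur)
    m = np.exp(cfg.los_log_mean)
    # SE of a lognormal sample median, plus half a day of integer rounding
    se = m * cfg.los_log_sd * np.sqrt(np.pi / (2 * n))
    assert abs(np.median(dur) - m) <= 3 * se + 0.5


def test_zero_hazard_means_no_poststroke_dispensing():
    cfg = SimConfig(n_persons=5_000, seed=2)
    cfg.dispensing_hazard = {k: 0.0 for k in cfg.dispensing_hazard}
    cfg.prior_med_prev = {k: 0.0 for k in cfg.prior_med_prev}
    tables, _ = generate_cohort(cfg)
    assert len(tables["dispensing"]) == 0


def test_first_dispensing_fraction_matches_exponential_cdf():
    cfg = SimConfig(n_persons=100_000, seed=17)
    cfg.fatality_prob = {k: 0.0 for k in cfg.fatality_prob}  # no competing death
    h = 0.003
    cfg.dispensing_hazard = {k: h for k in cfg.dispensing_hazard}
    _, gt = generate_ground_truth(cfg)
    disp, truth = generate_dispensings(cfg, gt)
    ev = gt[gt["has_stroke"]].merge(truth, on="person_id")
    t = ev["disp_true_antiplatelet"] - ev["stroke_offset"]
    frac = (t <= 365).mean()
    p = 1 - np.exp(-365 * h)
    se = np.sqrt(p * (1 - p) / len(ev))
    assert abs(frac - p) <= 3 * se


def test_full_prior_prevalence_gives_everyone_a_prior_record():
    cfg = SimConfig(n_persons=5_000, seed=2)
    cfg.prior_med_prev = dict(cfg.prior_med_prev, antiplatelet=1.0)
    tables, gt = generate_cohort(cfg)
    stroke_ids = set(gt.loc[gt["has_stroke"], "person_id"])
    disp = tables["dispensing"]
    prior = disp.merge(gt[["person_id", "stroke_offset"]], on="person_id")
    prior["offset"] = (pd.to_datetime(prior["dispense_date"])
                       - pd.Timestamp(cfg.study_start)).dt.days
    prior = prior[(prior["drug_class"] == "antiplatelet")
                  & (prior["offset"] < prior["stroke_offset"])]
    assert stroke_ids == set(prior["person_id"])


def test_no_record_postdates_death(small_cfg):
    tables, gt = generate_cohort(small_cfg)
    dead = gt[gt["fatal"]].set_index("person_id")["death_offset"]
    start = pd.Timestamp(small_cfg.study_start)
    for name, col in [("gdppr", "record_date"), ("ssnap", "onset_date"),
                      ("dispensing", "dispense_date")]:
        df = tables[name]
        df = df[df["person_id"].isin(dead.index)]
        off = (pd.to_datetime(df[col]) - start).dt.days
        assert (off.to_numpy() <= df["person_id"].map(dead).to_numpy()).all(), name
    hes = tables["hes_apc"]
    hes = hes[hes["person_id"].isin(dead.index)]
    off = (pd.to_datetime(hes["discharge_date"]) - start).dt.days
    assert (off.to_numpy() <= hes["person_id"].map(dead).to_numpy()).all()


@pytest.mark.parametrize("mutate, field", [
    (lambda c: setattr(c, "n_persons", 0), "n_persons"),
    (lambda c: setattr(c, "subtype_mix", (0.5, 0.5, 0.5)), "subtype_mix"),
    (lambda c: c.capture_prob.update({("gdppr", "fatal"): 1.5}), "capture_prob"),
    (lambda c: setattr(c, "date_jitter_sd", -1.0), "date_jitter_sd"),
    (lambda c: setattr(c, "study_end", c.study_start), "study_"),
])
def test_invalid_config_raises_naming_the_field(mutate, field):
    cfg = SimConfig(n_persons=10, seed=0)
    cfg.capture_prob = dict(cfg.capture_prob)
    mutate(cfg)
    with pytest.raises(ConfigError, match=field):
        cfg.validate()


def test_yaml_config_roundtrip(tmp_path):
    import yaml
    cfg = SimConfig(n_persons=123, seed=9)
    path = tmp_path / "config.yaml"
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh)
    loaded = SimConfig.from_yaml(path)
    assert loaded.n_persons == 123
    assert loaded.study_start == cfg.study_start
    assert loaded.capture_prob == cfg.capture_prob
    assert loaded.subtype_mix == cfg.subtype_mix


def test_unknown_yaml_field_is_a_config_error(tmp_path):
    path = tmp_path / "config.yaml"
    path.write_text("n_people: 5\n")
    with pytest.raises(ConfigError, match="n_people"):
        SimConfig.from_yaml(path)
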