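"""Simulation configuration for the synthetic linked-EHR generator.

The configuration pins down the data-generating assumptions of the synthetic
cohort: adult age-sex structure, stroke incidence per 100 000 person-years,
the ischaemic / haemorrhagic / unknown subtype mix, 30-day case fatality,
per-source capture probabilities, recording-date jitter, hospital length of
stay and post-stroke dispensing hazards.  Defaults are chosen to be
qualitatively realistic for an English whole-population stroke cohort; they
are design choices of this package, not measured quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import date
from typing import Mapping

import yaml

SOURCES = ("gdppr", "hes_apc", "ssnap", "ons")
SUBTYPES = ("ischaemic", "haemorrhagic", "unknown")
DRUG_CLASSES = ("anticoagulant", "antiplatelet", "antihypertensive", "lipid_lowering")
SEXES = ("F", "M")

#: 5-year adult age bands; 18-19 is a sliver of the standard 15-19 band.
AGE_BANDS = (
    "18-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84",
    "85-89", "90+",
)


class ConfigError(ValueError):
    """Raised when a simulation configuration field is invalid."""


def band_bounds(band: str) -> tuple[int, int]:
    """Inclusive (low, high) ages for a 5-year band; '90+' caps at 99."""
    if band.endswith("+"):
        return int(band[:-1]), 99
    lo, hi = band.split("-")
    return int(lo), int(hi)


def band_of_age(age: int) -> str:
    for band in AGE_BANDS:
        lo, hi = band_bounds(band)
        if lo <= age <= hi:
            return band
    raise ValueError(f"age {age} outside the adult band range")


def _default_structure() -> dict[str, dict[str, float]]:
    # Roughly the shape of the adult population of England (ONS mid-year
    # style): broad working-age plateau, tapering above 70.
    shares = {
        "18-19": 0.028, "20-24": 0.075, "25-29": 0.082, "30-34": 0.083,
        "35-39": 0.080, "40-44": 0.077, "45-49": 0.078, "50-54": 0.082,
        "55-59": 0.080, "60-64": 0.070, "65-69": 0.060, "70-74": 0.057,
        "75-79": 0.048, "80-84": 0.035, "85-89": 0.025, "90+": 0.013,
    }
    mass = sum(shares.values()) * 2.0
    return {b: {"F": shares[b] / mass, "M": shares[b] / mass} for b in AGE_BANDS}


def _default_incidence() -> dict[str, dict[str, float]]:
    # Events per 100 000 person-years; steep age gradient, slight male excess
    # below 85, reversing at the oldest ages.
    base = {
        "18-19": 5, "20-24": 7, "25-29": 10, "30-34": 15, "35-39": 25,
        "40-44": 40, "45-49": 70, "50-54": 115, "55-59": 185, "60-64": 290,
        "65-69": 450, "70-74": 690, "75-79": 1050, "80-84": 1600,
        "85-89": 2300, "90+": 3100,
    }
    out: dict[str, dict[str, float]] = {}
    for b, r in base.items():
        male_excess = 1.25 if band_bounds(b)[0] < 85 else 0.95
        out[b] = {"F": r / ((1 + male_excess) / 2), "M": r * male_excess / ((1 + male_excess) / 2)}
    return out


@dataclass
class SimConfig:
    """All knobs of the synthetic linked-EHR cohort generator."""

    n_persons: int = 50_000
    seed: int = 0
    study_start: date = date(2020, 1, 1)
    study_end: date = date(2023, 12, 31)
    #: records (deaths, spells, dispensings) are observed up to this date so
    #: that 180-day home-time and 1-year dispensing follow-up are complete.
    data_end: date = date(2025, 2, 28)

    age_sex_structure: dict = field(default_factory=_default_structure)
    annual_incidence: dict = field(default_factory=_default_incidence)

    subtype_mix: tuple[float, float, float] = (0.70, 0.13, 0.17)
    fatality_prob: dict = field(default_factory=lambda: {
        "ischaemic": 0.12, "haemorrhagic": 0.35, "unknown": 0.18})

    # capture probability by (source, fatality status); ons is the probability
    # that a death registration carries a stroke-coded underlying cause.
    capture_prob: dict = field(default_factory=lambda: {
        ("gdppr", "nonfatal"): 0.70, ("gdppr", "fatal"): 0.45,
        ("hes_apc", "nonfatal"): 0.64, ("hes_apc", "fatal"): 0.50,
        ("ssnap", "nonfatal"): 0.52, ("ssnap", "fatal"): 0.25,
        ("ons", "nonfatal"): 0.0, ("ons", "fatal"): 0.90,
    })
    date_jitter_sd: float = 2.0
    #: fraction of records whose date is jittered at all; most sources agree
    #: on the exact date, with occasional tail disagreement
    date_jitter_prob: float = 0.35
    # probability that a captured record carries "unknown" instead of the
    # true subtype, by source (echoes source-specific coding quality).
    subtype_unknown_prob: dict = field(default_factory=lambda: {
        "gdppr": 0.19, "hes_apc": 0.012, "ssnap": 0.0, "ons": 0.26})

    prior_stroke_prob: float = 0.04
    los_log_mean: float = 1.609  # log-days; median exp(1.609) ~ 5 days
    los_log_sd: float = 1.0
    readmission_prob: float = 0.15

    # constant daily hazard of first post-stroke dispensing by (class, subtype)
    dispensing_hazard: dict = field(default_factory=lambda: {
        ("anticoagulant", "ischaemic"): 0.00086,
        ("anticoagulant", "haemorrhagic"): 0.00040,
        ("anticoagulant", "unknown"): 0.00070,
        ("antiplatelet", "ischaemic"): 0.00320,
        ("antiplatelet", "haemorrhagic"): 0.00039,
        ("antiplatelet", "unknown"): 0.00220,
        ("antihypertensive", "ischaemic"): 0.00161,
        ("antihypertensive", "haemorrhagic"): 0.00172,
        ("antihypertensive", "unknown"): 0.00150,
        ("lipid_lowering", "ischaemic"): 0.00448,
        ("lipid_lowering", "haemorrhagic"): 0.00145,
        ("lipid_lowering", "unknown"): 0.00300,
    })
    prior_med_prev: dict = field(default_factory=lambda: {
        "anticoagulant": 0.17, "antiplatelet": 0.32,
        "antihypertensive": 0.40, "lipid_lowering": 0.50})

    comorbidity_prev: dict = field(default_factory=lambda: {
        "af_mi": 0.33, "diabetes": 0.30, "hypertension": 0.70, "ckd": 0.33,
        "dementia": 0.10, "cancer": 0.25, "copd": 0.14, "depression": 0.27,
        "dvt": 0.03, "angina": 0.17, "obesity": 0.20, "liver_disease": 0.016,
        "hypercholesterolaemia": 0.088, "arrhythmia": 0.02})

    measurement_coverage: float = 0.7
    covid_recent_prob: float = 0.035
    covid_history_prob: float = 0.16
    missing_rate: float = 0.05

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_persons < 1:
            raise ConfigError("n_persons must be >= 1")
        if self.study_start >= self.study_end:
            raise ConfigError("study_start must precede study_end")
        if self.data_end < self.study_end:
            raise ConfigError("data_end must be on or after study_end")
        if abs(sum(self.subtype_mix) - 1.0) > 1e-9:
            raise ConfigError("subtype_mix must sum to 1")
        struct_total = sum(p for by_sex in self.age_sex_structure.values()
                           for p in by_sex.values())
        if abs(struct_total - 1.0) > 1e-6:
            raise ConfigError("age_sex_structure must sum to 1")
        for name, mapping in [("capture_prob", self.capture_prob),
                              ("fatality_prob", self.fatality_prob),
                              ("prior_med_prev", self.prior_med_prev),
                              ("comorbidity_prev", self.comorbidity_prev),
                              ("subtype_unknown_prob", self.subtype_unknown_prob)]:
            for key, p in mapping.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(f"{name}[{key}] = {p} outside [0, 1]")
        for scalar in ("prior_stroke_prob", "readmission_prob", "missing_rate",
                       "measurement_coverage", "covid_recent_prob",
                       "covid_history_prob", "date_jitter_prob"):
            v = getattr(self, scalar)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{scalar} = {v} outside [0, 1]")
        if self.date_jitter_sd < 0:
            raise ConfigError("date_jitter_sd must be >= 0")
        if self.los_log_sd < 0:
            raise ConfigError("los_log_sd must be >= 0")
        for key, h in self.dispensing_hazard.items():
            if h < 0:
                raise ConfigError(f"dispensing_hazard[{key}] = {h} negative")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        """Load a configuration from YAML, filling unspecified fields with defaults."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config field: {key}")
            current = getattr(cfg, key)
            if isinstance(current, date) and isinstance(value, str):
                value = date.fromisoformat(value)
            if key in ("capture_prob", "dispensing_hazard") and isinstance(value, dict):
                value = {tuple(k.split(",")): v for k, v in value.items()}
            if key == "subtype_mix":
                value = tuple(value)
            setattr(cfg, key, value)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("capture_prob", "dispensing_hazard"):
            d[key] = {",".join(k): v for k, v in d[key].items()}
        for key in ("study_start", "study_end", "data_end"):
            d[key] = d[key].isoformat()
        return d
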