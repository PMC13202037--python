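import numpy as np
import pandas as pd
import pytest

from stroketrace import SimConfig


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_persons=2000, seed=7)


@pytest.fixture(scope="session")
def clean_capture_cfg():
    """Every event captured everywhere, no jitter, no miscoding, no prevalent
    history: observed tables mirror ground truth exactly."""
    cfg = SimConfig(n_persons=30_000, seed=11)
    cfg.capture_prob = {(s, f): 1.0 for s in ("gdppr", "hes_apc", "ssnap", "ons")
                        for f in ("fatal", "nonfatal")}
    cfg.capture_prob[("ons", "nonfatal")] = 0.0
    cfg.date_jitter_sd = 0.0
    cfg.subtype_unknown_prob = {s: 0.0 for s in ("gdppr", "hes_apc", "ssnap", "ons")}
    cfg.prior_stroke_prob = 0.0
    cfg.subtype_mix = (0.75, 0.25, 0.0)  # audit has no "unknown" level
    return cfg


def make_flat_incidence(rate_per_100k: float) -> dict:
    from stroketrace.config import AGE_BANDS
    return {b: {"F": rate_per_100k, "M": rate_per_100k} for b in AGE_BANDS}
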