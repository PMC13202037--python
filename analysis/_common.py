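"""Shared setup for the analysis scripts: one fixed study configuration and
a single cached pipeline run per interpreter invocation."""

import os
import sys

from stroketrace import SimConfig, run_all

RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")

#: the default study conditions: 300 000 adults followed 2020-2023, giving
#: roughly 3 500 index strokes — large enough for stable percentages while
#: keeping each script under half a minute
CONFIG = SimConfig(n_persons=300_000, seed=20)

_cache = {}


def get_results():
    if "res" not in _cache:
        print(f"running pipeline: {CONFIG.n_persons} persons, seed {CONFIG.seed} ...",
              file=sys.stderr)
        _cache["res"] = run_all(CONFIG)
    return _cache["res"]


def save(df, name):
    os.makedirs(RESULTS, exist_ok=True)
    path = os.path.join(RESULTS, name)
    df.to_csv(path, index=False)
    print(f"wrote {os.path.relpath(path)}")
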